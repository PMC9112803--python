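"""Phi-value analysis: mutational free-energy changes and their normalization.

For each point mutant relative to wild type the three-state chevron
parameters give four free-energy differences (kcal/mol):

    ddG_D-TS1  = RT ln(kf_wt / kf_mut)          (early-barrier change)
    ddG_TS1-N  = RT ln(ku_mut / ku_wt)          (early barrier from the native side)
    ddG_TS2-N  = RT ln[(ku/Kpart)_mut / (ku/Kpart)_wt]   (late barrier)
    ddG_eq     = RT ln[(kf/ku)_wt / (kf/ku)_mut]         (stability change)

with the convention that a destabilizing mutation gives positive ddG_eq.
Phi values normalize the transition-state changes by the stability change:

    Phi_TS1 = ddG_D-TS1 / ddG_eq
    Phi_TS2 = 1 - ddG_TS2-N / ddG_eq

Phi ~ 1 means the mutated side chain is in a native-like environment in the
probed transition state, Phi ~ 0 a denatured-like one; values outside [0, 1]
are "non-canonical" and can flag transient non-native interactions.  Mutants
whose |ddG_eq| falls below a threshold (default 0.4 kcal/mol) are excluded:
the normalization is numerically meaningless for near-neutral mutations.

Uncertainties are propagated to first order (delta method) from the standard
errors of the rate constants, treating inputs as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .exceptions import DataError, InvalidParameterError, StateError
from .kinetics import KineticParameters

__all__ = [
    "DEFAULT_EXCLUSION_THRESHOLD",
    "DdgTerms",
    "VariantThermo",
    "ddg_terms",
    "ddg_errors",
    "phi_values",
    "classify_phi",
    "phi_table",
]

#: Mutants with |ddG_eq| below this (kcal/mol) are excluded from Phi values.
DEFAULT_EXCLUSION_THRESHOLD = 0.4

CATEGORIES = ("low", "intermediate", "high", "non_canonical", "excluded")


class DdgTerms(NamedTuple):
    ddG_D_TS1: float
    ddG_TS1_N: float
    ddG_TS2_N: float
    ddG_eq: float


@dataclass(frozen=True)
class VariantThermo:
    """Free-energy terms, Phi values and categories of one mutant."""

    variant_id: str
    ddG_D_TS1: float
    ddG_TS1_N: float
    ddG_TS2_N: float
    ddG_eq: float
    phi_ts1: Optional[float]
    phi_ts2: Optional[float]
    category_ts1: str
    category_ts2: str
    errors: Mapping[str, float] = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return self.category_ts1 == "excluded"


def ddg_terms(wt: KineticParameters, mut: KineticParameters) -> DdgTerms:
    """Mutational free-energy differences between a mutant and wild type.

    Requires ``Kpart > 0`` on both sides for the TS2 term (the late barrier
    is undefined in the two-state limit).  Swapping wt and mut negates every
    term.
    """
    if wt.Kpart <= 0 or mut.Kpart <= 0:
        raise InvalidParameterError(
            "ddG_TS2-N undefined with Kpart = 0 (two-state limit has no late barrier)"
        )
    rt = wt.RT
    d_dts1 = rt * math.log(wt.kf0 / mut.kf0)
    d_ts1n = rt * math.log(mut.ku0 / wt.ku0)
    d_ts2n = rt * math.log((mut.ku0 / mut.Kpart) / (wt.ku0 / wt.Kpart))
    d_eq = rt * math.log((wt.kf0 / wt.ku0) / (mut.kf0 / mut.ku0))
    return DdgTerms(d_dts1, d_ts1n, d_ts2n, d_eq)


def ddg_errors(
    wt: KineticParameters,
    mut: KineticParameters,
    wt_se: Mapping[str, float],
    mut_se: Mapping[str, float],
) -> dict[str, float]:
    """First-order uncertainties of the ddG terms from rate-constant SEs.

    ``wt_se``/``mut_se`` map ``kf0``, ``ku0``, ``Kpart`` to standard errors;
    missing entries count as zero.  RT ln(x/y) has variance
    RT^2 [(sx/x)^2 + (sy/y)^2] for independent x, y.
    """

    def rel(se: Mapping[str, float], p: KineticParameters, name: str) -> float:
        value = getattr(p, name)
        return float(se.get(name, 0.0)) / value if value > 0 else 0.0

    rt = wt.RT
    r_kfw, r_kfm = rel(wt_se, wt, "kf0"), rel(mut_se, mut, "kf0")
    r_kuw, r_kum = rel(wt_se, wt, "ku0"), rel(mut_se, mut, "ku0")
    r_kpw, r_kpm = rel(wt_se, wt, "Kpart"), rel(mut_se, mut, "Kpart")
    return {
        "ddG_D_TS1": rt * math.hypot(r_kfw, r_kfm),
        "ddG_TS1_N": rt * math.hypot(r_kuw, r_kum),
        "ddG_TS2_N": rt * math.sqrt(r_kuw**2 + r_kum**2 + r_kpw**2 + r_kpm**2),
        "ddG_eq": rt * math.sqrt(r_kfw**2 + r_kfm**2 + r_kuw**2 + r_kum**2),
    }


def phi_values(
    terms: DdgTerms,
    errors: Optional[Mapping[str, float]] = None,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> Optional[tuple[float, float, dict[str, float]]]:
    """Phi values for both transition states, or ``None`` when excluded.

    Exclusion compares |ddG_eq| to the threshold, so near-neutral mutants
    are dropped regardless of sign.  Returned errors propagate the ddG
    uncertainties (independence assumed; the shared-denominator covariance
    is neglected).
    """
    if abs(terms.ddG_eq) < exclusion_threshold:
        return None
    if terms.ddG_eq == 0.0:
        raise ZeroDivisionError("ddG_eq is exactly zero; Phi undefined")
    phi1 = terms.ddG_D_TS1 / terms.ddG_eq
    phi2 = 1.0 - terms.ddG_TS2_N / terms.ddG_eq
    se1 = se2 = 0.0
    if errors:
        g, sg = terms.ddG_eq, float(errors.get("ddG_eq", 0.0))
        s1 = float(errors.get("ddG_D_TS1", 0.0))
        s2 = float(errors.get("ddG_TS2_N", 0.0))
        # d(x/g)/dx = 1/g, d(x/g)/dg = -x/g^2
        se1 = math.hypot(s1 / g, terms.ddG_D_TS1 * sg / g**2)
        se2 = math.hypot(s2 / g, terms.ddG_TS2_N * sg / g**2)
    return phi1, phi2, {"phi_ts1": se1, "phi_ts2": se2}


def classify_phi(phi: float) -> str:
    """Map a Phi value to its structural category.

    Boundaries: [0, 0.3) low, [0.3, 0.7) intermediate, [0.7, 1] high,
    anything outside [0, 1] non-canonical.
    """
    if not math.isfinite(phi):
        raise InvalidParameterError(f"Phi must be finite, got {phi}")
    if phi < 0.0 or phi > 1.0:
        return "non_canonical"
    if phi < 0.3:
        return "low"
    if phi < 0.7:
        return "intermediate"
    return "high"


def phi_table(
    result,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    wt_id: str = "wt",
) -> list[VariantThermo]:
    """One :class:`VariantThermo` row per non-wild-type variant of a global fit.

    ``result`` is a :class:`~foldkin.fitting.GlobalFitResult`; row order
    follows the fit's variant order.  Raises :class:`StateError` when the
    wild type is absent.
    """
    ids = {v.lower(): v for v in result.per_variant}
    if wt_id.lower() not in ids:
        raise StateError(f"wild-type variant {wt_id!r} missing from fit result")
    wt_key = ids[wt_id.lower()]
    wt = result.per_variant[wt_key]
    wt_se = result.standard_errors.get(wt_key, {})
    rows: list[VariantThermo] = []
    for vid, params in result.per_variant.items():
        if vid == wt_key:
            continue
        terms = ddg_terms(wt, params)
        errs = ddg_errors(wt, params, wt_se, result.standard_errors.get(vid, {}))
        phis = phi_values(terms, errs, exclusion_threshold)
        if phis is None:
            phi1 = phi2 = None
            cat1 = cat2 = "excluded"
        else:
            phi1, phi2, phi_err = phis
            errs.update(phi_err)
            cat1, cat2 = classify_phi(phi1), classify_phi(phi2)
        rows.append(
            VariantThermo(
                variant_id=vid,
                ddG_D_TS1=terms.ddG_D_TS1,
                ddG_TS1_N=terms.ddG_TS1_N,
                ddG_TS2_N=terms.ddG_TS2_N,
                ddG_eq=terms.ddG_eq,
                phi_ts1=phi1,
                phi_ts2=phi2,
                category_ts1=cat1,
                category_ts2=cat2,
                errors=errs,
            )
        )
    return rows
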
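"""Downstream regressions: LFER alpha slopes, Hammond trend, Phi-vs-Phi.

* **LFER**: ordinary least squares of the transition-state free-energy
  change against the stability change across variants.  The slope (alpha,
  nominally between 0 and 1) measures how native-like the transition state
  is globally; the late transition state of a stepwise folder should give
  the larger alpha.
* **Hammond**: ordinary least squares of per-variant Tanford beta against
  stability.  A negative slope (transition states drifting toward the
  native state as the protein is destabilized) is the Hammond-consistent
  outcome; the sign is reported, never enforced.
* **Phi vs Phi**: pairwise comparison of Phi values at structurally
  equivalent positions of two homologous domains, given an externally
  supplied residue mapping.  Summaries are the Pearson correlation, the
  RMS deviation from the identity line, and the mean offset (B minus A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import DataError
from .kinetics import TanfordBetas
from .phi import VariantThermo

__all__ = [
    "LferResult",
    "HammondResult",
    "PhiPair",
    "PhiPhiSummary",
    "lfer_fit",
    "hammond_fit",
    "phi_vs_phi",
]

WhichTS = Literal["TS1", "TS2"]


@dataclass(frozen=True)
class LferResult:
    which_ts: str
    alpha: float
    intercept: float
    se_alpha: float
    se_intercept: float
    r_value: float
    n_variants: int
    included_ids: tuple[str, ...]


@dataclass(frozen=True)
class HammondResult:
    which_ts: str
    slope: float  # d(beta) / d(dG_DN), per kcal/mol
    intercept: float
    se_slope: float
    r_value: float
    n_variants: int


@dataclass(frozen=True)
class PhiPair:
    pos_a: int
    pos_b: int
    phi_a: float
    phi_b: float
    stage: str


@dataclass(frozen=True)
class PhiPhiSummary:
    rms_identity: float  # RMS deviation from the phi_b = phi_a line
    pearson_r: float
    mean_offset: float  # mean(phi_b - phi_a)
    n_pairs: int
    n_dropped: int


def _check_ts(which_ts: str) -> str:
    if which_ts not in ("TS1", "TS2"):
        raise DataError(f"which_ts must be 'TS1' or 'TS2', got {which_ts!r}")
    return which_ts


def lfer_fit(
    thermo: Sequence[VariantThermo],
    which_ts: WhichTS,
    extra_exclude: Sequence[str] = (),
) -> LferResult:
    """LFER regression over non-excluded variants.

    x is ddG_eq; y is ddG_D-TS1 for TS1 or (ddG_eq - ddG_TS2-N) for TS2,
    i.e. the destabilization of the barrier measured from the denatured
    side, so a slope of 1 means a fully native-like transition state.
    Variants failing the Phi exclusion rule, and any ids in
    ``extra_exclude``, are dropped.
    """
    _check_ts(which_ts)
    drop = {v.lower() for v in extra_exclude}
    x, y, ids = [], [], []
    for row in thermo:
        if row.excluded or row.variant_id.lower() in drop:
            continue
        x.append(row.ddG_eq)
        y.append(row.ddG_D_TS1 if which_ts == "TS1" else row.ddG_eq - row.ddG_TS2_N)
        ids.append(row.variant_id)
    if len(x) < 3:
        raise DataError(f"LFER needs >= 3 usable variants, got {len(x)}")
    fit = stats.linregress(x, y)
    return LferResult(
        which_ts=which_ts,
        alpha=float(fit.slope),
        intercept=float(fit.intercept),
        se_alpha=float(fit.stderr),
        se_intercept=float(fit.intercept_stderr),
        r_value=float(fit.rvalue),
        n_variants=len(x),
        included_ids=tuple(ids),
    )


def hammond_fit(
    betas: Mapping[str, TanfordBetas],
    stabilities: Mapping[str, float],
    which_ts: WhichTS,
) -> HammondResult:
    """Linear fit of Tanford beta against stability dG_D-N across variants."""
    _check_ts(which_ts)
    common = [v for v in betas if v in stabilities]
    if len(common) < 3:
        raise DataError(f"Hammond fit needs >= 3 variants with both values, got {len(common)}")
    x = np.array([stabilities[v] for v in common])
    y = np.array(
        [betas[v].beta_ts1 if which_ts == "TS1" else betas[v].beta_ts2 for v in common]
    )
    if np.allclose(y, y[0]):
        # constant beta: slope 0 exactly, linregress SE undefined
        return HammondResult(which_ts, 0.0, float(y[0]), 0.0, 0.0, len(common))
    fit = stats.linregress(x, y)
    return HammondResult(
        which_ts=which_ts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        se_slope=float(fit.stderr),
        r_value=float(fit.rvalue),
        n_variants=len(common),
    )


def phi_vs_phi(
    mapping: Sequence[tuple[int, int]],
    phis_a: Mapping[int, Optional[float]],
    phis_b: Mapping[int, Optional[float]],
    stage: str = "early",
) -> tuple[list[PhiPair], PhiPhiSummary]:
    """Compare Phi values of two homologous domains position by position.

    ``mapping`` pairs residue positions (domain A, domain B) that occupy the
    same structural position; only the mapping decides comparability, never
    the package (alignment is an input).  Pairs are retained only when both
    sides carry a non-excluded Phi value (``None`` marks exclusion); the
    dropped count is reported in the summary.
    """
    pairs: list[PhiPair] = []
    dropped = 0
    for pos_a, pos_b in mapping:
        pa = phis_a.get(pos_a)
        pb = phis_b.get(pos_b)
        if pa is None or pb is None:
            dropped += 1
            continue
        pairs.append(PhiPair(int(pos_a), int(pos_b), float(pa), float(pb), stage))
    if not pairs:
        raise DataError("no residue pairs with Phi values on both sides")
    a = np.array([p.phi_a for p in pairs])
    b = np.array([p.phi_b for p in pairs])
    if len(pairs) >= 2 and np.std(a) > 0 and np.std(b) > 0:
        r = float(stats.pearsonr(a, b).statistic)
    else:
        r = float("nan")
    summary = PhiPhiSummary(
        rms_identity=float(np.sqrt(np.mean((b - a) ** 2))),
        pearson_r=r,
        mean_offset=float(np.mean(b - a)),
        n_pairs=len(pairs),
        n_dropped=dropped,
    )
    return pairs, summary
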
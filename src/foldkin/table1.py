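"""Packaged reference dataset: fitted parameters of the 29-variant study.

The package ships a verbatim transcription of the published per-variant
table for the C-terminal SH2 domain of SHP2 (wild type plus 29 conservative
point mutants): rate constants in water, partitioning constants, the four
free-energy columns and the Phi values, each with its printed uncertainty.
Rows footnoted as excluded (|ddG_eq| < 0.4 kcal/mol) carry no Phi values.

``validate_table1`` re-derives every derivable column from the printed rate
constants alone and compares against the printed numbers.  Because the
printed rates carry only 1-2 significant figures, a recomputed cell can
drift outside the printed error bar even when the underlying fit was
self-consistent; the validator therefore reports two comparisons per cell:
the strict one (printed error with a small floor) and one that also allows
for the first-order uncertainty propagated from the printed rate errors.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DataError, IntegrityError, StateError
from .kinetics import RT_25C, KineticParameters
from .phi import DEFAULT_EXCLUSION_THRESHOLD, DdgTerms, classify_phi, ddg_errors, ddg_terms
from .synthetic import WT_PARAMS

__all__ = [
    "Table1Fixture",
    "load_table1",
    "fixture_thermo",
    "recompute_table1",
    "validate_table1",
]

_SHA256 = "86d8c090a97f0127e1bb2088cf8c16682497887e633db694e988e52d73941a19"

#: Floors on the comparison tolerances (printed values are rounded).
PHI_TOL_FLOOR = 0.05
DDG_TOL_FLOOR = 0.1


@dataclass(frozen=True)
class Table1Fixture:
    """The transcribed reference table: one wt row plus 29 mutant rows."""

    data: pd.DataFrame

    @property
    def mutants(self) -> pd.DataFrame:
        return self.data[self.data["variant"] != "wt"].reset_index(drop=True)

    @property
    def wt(self) -> pd.Series:
        return self.data[self.data["variant"] == "wt"].iloc[0]

    @property
    def excluded_ids(self) -> tuple[str, ...]:
        """Variants footnoted as excluded (those with no printed Phi)."""
        m = self.mutants
        return tuple(m.loc[m["phi_ts1"].isna(), "variant"])

    def row(self, variant: str) -> pd.Series:
        hit = self.data[self.data["variant"] == variant]
        if hit.empty:
            raise StateError(f"variant {variant!r} not in the packaged table")
        return hit.iloc[0]

    def params(self, variant: str, template: KineticParameters = WT_PARAMS) -> KineticParameters:
        """Printed rate constants as a parameter set.

        The table prints no per-variant m-values (they were shared in the
        fit), so m-values are taken from ``template``.
        """
        r = self.row(variant)
        return KineticParameters(
            kf0=float(r["kf_s1"]),
            ku0=float(r["ku_s1"]),
            Kpart=float(r["kpart"]),
            mf=template.mf,
            mu=template.mu,
            mpart=template.mpart,
            RT=template.RT,
        )

    def errors(self, variant: str) -> dict[str, float]:
        r = self.row(variant)
        return {"kf0": float(r["kf_err"]), "ku0": float(r["ku_err"]), "Kpart": float(r["kpart_err"])}


def load_table1(check_integrity: bool = True) -> Table1Fixture:
    """Load the packaged reference table.

    Raises :class:`IntegrityError` if the packaged CSV does not match its
    recorded checksum.
    """
    ref = resources.files("foldkin.data").joinpath("table1.csv")
    raw = ref.read_bytes()
    if check_integrity and hashlib.sha256(raw).hexdigest() != _SHA256:
        raise IntegrityError("packaged table1.csv does not match its recorded checksum")
    df = pd.read_csv(ref)
    # normalize any unicode minus signs that survive transcription
    for col in df.columns[1:]:
        if df[col].dtype == object:
            df[col] = pd.to_numeric(df[col].astype(str).str.replace("−", "-"), errors="coerce")
    n_mut = int((df["variant"] != "wt").sum())
    if n_mut != 29 or "wt" not in set(df["variant"]):
        raise IntegrityError(f"expected wt + 29 mutant rows, found {n_mut} mutants")
    return Table1Fixture(df)


def fixture_thermo(
    fixture: Optional[Table1Fixture] = None,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> list:
    """Per-variant thermodynamics derived purely from the printed rates.

    Runs the package's own ddG/Phi pipeline on the fixture's rate columns
    (so ddG_eq here is the kinetic one), suitable as input to the LFER and
    downstream regressions.  Returns a list of
    :class:`~foldkin.phi.VariantThermo`.
    """
    from .phi import VariantThermo, phi_values

    fx = fixture or load_table1()
    wt = fx.params("wt")
    wt_se = fx.errors("wt")
    rows = []
    for _, r in fx.mutants.iterrows():
        vid = r["variant"]
        mut = fx.params(vid)
        terms = ddg_terms(wt, mut)
        errs = ddg_errors(wt, mut, wt_se, fx.errors(vid))
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


def recompute_table1(
    fixture: Optional[Table1Fixture] = None,
    rt: float = RT_25C,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> pd.DataFrame:
    """Re-derive the free-energy and Phi columns from the printed rates.

    For each mutant row the barrier terms are recomputed from kf, ku and
    Kpart; Phi values use the printed ddG_eq as denominator (the printed
    stability is the better-determined number, and it defines the published
    exclusion rule).  Columns ``*_rec`` hold recomputed values, ``*_prop``
    their first-order propagated uncertainties from the printed rate errors.
    """
    fx = fixture or load_table1()
    wt = fx.params("wt")
    wt = KineticParameters(kf0=wt.kf0, ku0=wt.ku0, Kpart=wt.Kpart, mf=wt.mf, mu=wt.mu,
                           mpart=wt.mpart, RT=rt)
    wt_se = fx.errors("wt")
    rows = []
    for _, r in fx.mutants.iterrows():
        mut = fx.params(r["variant"])
        terms = ddg_terms(wt, mut)
        prop = ddg_errors(wt, mut, wt_se, fx.errors(r["variant"]))
        g_print = float(r["ddG_eq"])
        excluded = abs(g_print) < exclusion_threshold
        rec = {
            "variant": r["variant"],
            "ddG_TS1N_rec": terms.ddG_TS1_N,
            "ddG_TS2N_rec": terms.ddG_TS2_N,
            "ddG_eq_rec": terms.ddG_eq,
            "ddG_TS1N_prop": prop["ddG_TS1_N"],
            "ddG_TS2N_prop": prop["ddG_TS2_N"],
            "ddG_eq_prop": prop["ddG_eq"],
            "excluded": excluded,
        }
        if not excluded:
            phi1 = terms.ddG_D_TS1 / g_print
            phi2 = 1.0 - terms.ddG_TS2_N / g_print
            sg = float(r["ddG_eq_err"])
            rec.update(
                phi_ts1_rec=phi1,
                phi_ts2_rec=phi2,
                phi_ts1_prop=math.hypot(prop["ddG_D_TS1"] / g_print,
                                        terms.ddG_D_TS1 * sg / g_print**2),
                phi_ts2_prop=math.hypot(prop["ddG_TS2_N"] / g_print,
                                        terms.ddG_TS2_N * sg / g_print**2),
                category_ts1=classify_phi(phi1),
                category_ts2=classify_phi(phi2),
            )
        else:
            rec.update(phi_ts1_rec=np.nan, phi_ts2_rec=np.nan,
                       phi_ts1_prop=np.nan, phi_ts2_prop=np.nan,
                       category_ts1="excluded", category_ts2="excluded")
        rows.append(rec)
    return pd.DataFrame(rows)


_CHECKS = (
    # (recomputed column, printed column, printed error column, floor)
    ("ddG_TS1N_rec", "ddG_TS1N", "ddG_TS1N_err", DDG_TOL_FLOOR),
    ("ddG_TS2N_rec", "ddG_TS2N", "ddG_TS2N_err", DDG_TOL_FLOOR),
    ("phi_ts1_rec", "phi_ts1", "phi_ts1_err", PHI_TOL_FLOOR),
    ("phi_ts2_rec", "phi_ts2", "phi_ts2_err", PHI_TOL_FLOOR),
)


def validate_table1(
    fixture: Optional[Table1Fixture] = None,
    rt: float = RT_25C,
) -> pd.DataFrame:
    """Compare recomputed columns with the printed ones, cell by cell.

    Returns one row per (variant, column) with the recomputed value, the
    printed value, the absolute difference and two verdicts:

    * ``ok_strict`` - |diff| within the printed error (floored at
      +-0.05 for Phi, +-0.1 kcal/mol for ddG);
    * ``ok_propagated`` - |diff| within the strict tolerance combined in
      quadrature with the uncertainty propagated from the printed rates.
    """
    fx = fixture or load_table1()
    rec = recompute_table1(fx, rt=rt).set_index("variant")
    printed = fx.mutants.set_index("variant")
    out = []
    for vid in printed.index:
        for rec_col, col, err_col, floor in _CHECKS:
            target = printed.loc[vid, col]
            value = rec.loc[vid, rec_col]
            if pd.isna(target) or pd.isna(value):
                continue
            tol = max(float(printed.loc[vid, err_col]), floor)
            prop = float(rec.loc[vid, rec_col.replace("_rec", "_prop")])
            diff = abs(float(value) - float(target))
            out.append(
                {
                    "variant": vid,
                    "column": col,
                    "recomputed": float(value),
                    "printed": float(target),
                    "diff": diff,
                    "tol_strict": tol,
                    "ok_strict": diff <= tol,
                    "tol_propagated": math.hypot(tol, prop),
                    "ok_propagated": diff <= math.hypot(tol, prop),
                }
            )
    return pd.DataFrame(out)
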
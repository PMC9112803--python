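"""Synthetic stopped-flow and chevron data with known ground truth.

Emulates the experimental design the analysis assumes: for each variant a
chevron of observed rates on a urea grid, each rate obtainable from a
single-exponential fluorescence time course.  Mutants are constructed by
inverting the Phi formulas, so the true (ddG_eq, Phi_TS1, Phi_TS2) of every
variant is known exactly and can be scored after the full pipeline runs.

Noise model: multiplicative lognormal on k_obs (additive Gaussian in log10,
default sd 0.02 decades), matching least-squares fitting in log space;
additive Gaussian noise on fluorescence traces.

The default wild type reproduces the fitted C-SH2 chevron: kf0 = 300/s,
ku0 = 0.06/s, Kpart = 0.017, with mu = 0.52 and mpart = 0.45 kcal/mol/M and
mf = 0.81 kcal/mol/M chosen so that beta_TS1 = mf/(mf+mu) = 0.61.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidParameterError
from .kinetics import ChevronDataset, KineticParameters, stability, three_state_rate
from .traces import TraceRecord

__all__ = [
    "WT_PARAMS",
    "EnsembleSpec",
    "make_mutant",
    "simulate_chevron",
    "simulate_trace",
    "simulate_ensemble",
]

#: Wild-type three-state parameters used as the synthetic ground truth.
WT_PARAMS = KineticParameters(
    kf0=300.0, mf=0.81, ku0=0.06, mu=0.52, Kpart=0.017, mpart=0.45
)

#: Default urea grid: 0-9 M in 0.25 M steps, wide enough to expose the
#: change of rate-limiting step in the unfolding arm.
DEFAULT_UREA_GRID = np.arange(0.0, 9.0 + 1e-9, 0.25)


def make_mutant(
    wt: KineticParameters,
    ddG_eq: float,
    phi_ts1: float,
    phi_ts2: float,
) -> KineticParameters:
    """Invert the Phi formulas: build a mutant with prescribed truth values.

    The mutant keeps the wild-type m-values (shared-m world) and satisfies

        kf  = kf_wt  exp(-phi_ts1 ddG_eq / RT)
        ku  = ku_wt  exp((1 - phi_ts1) ddG_eq / RT)
        Kp  = Kp_wt  exp((phi_ts2 - phi_ts1) ddG_eq / RT)

    so that ddG_D-TS1 = phi_ts1*ddG_eq, ddG_TS2-N = (1-phi_ts2)*ddG_eq and
    ddG_eq comes out exactly as requested.  ``ddG_eq = 0`` returns the wild
    type unchanged.
    """
    rt = wt.RT
    kf = wt.kf0 * np.exp(-phi_ts1 * ddG_eq / rt)
    ku = wt.ku0 * np.exp((1.0 - phi_ts1) * ddG_eq / rt)
    kp = wt.Kpart * np.exp((phi_ts2 - phi_ts1) * ddG_eq / rt)
    return replace(wt, kf0=float(kf), ku0=float(ku), Kpart=float(kp))


def simulate_chevron(
    params: KineticParameters,
    urea_grid: Sequence[float] = DEFAULT_UREA_GRID,
    noise_sd_log: float = 0.02,
    seed: Optional[int] = None,
    variant_id: str = "sim",
) -> ChevronDataset:
    """Chevron observations: k_obs = three_state_rate * 10^eps, eps ~ N(0, sd)."""
    u = np.asarray(urea_grid, dtype=float)
    k = three_state_rate(params, u)
    if noise_sd_log > 0:
        if seed is None:
            raise InvalidParameterError("a seed is required for noisy simulation")
        rng = np.random.default_rng(seed)
        k = k * 10.0 ** rng.normal(0.0, noise_sd_log, size=u.shape)
    return ChevronDataset(variant_id=variant_id, urea=u, kobs=np.asarray(k))


def simulate_trace(
    params: KineticParameters,
    urea: float,
    direction: Literal["folding", "unfolding"] = "folding",
    n_points: int = 1000,
    trace_noise_sd: float = 0.0,
    seed: Optional[int] = None,
    variant_id: str = "sim",
    amplitude: float = 0.5,
    offset: float = 1.0,
) -> TraceRecord:
    """Single-exponential fluorescence time course at one urea concentration.

    The decay rate is ``three_state_rate(params, urea)``; the time window
    spans 10/k_obs (1000 points by default).  Refolding traces rise
    (negative amplitude), unfolding traces decay.
    """
    if direction not in ("folding", "unfolding"):
        raise InvalidParameterError(f"unknown direction {direction!r}")
    kobs = three_state_rate(params, float(urea))
    t = np.linspace(0.0, 10.0 / kobs, int(n_points))
    amp = abs(amplitude) if direction == "unfolding" else -abs(amplitude)
    f = offset + amp * np.exp(-kobs * t)
    if trace_noise_sd > 0:
        if seed is None:
            raise InvalidParameterError("a seed is required for noisy simulation")
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, trace_noise_sd, size=t.shape)
    return TraceRecord(variant_id=variant_id, urea=float(urea), times=t, fluorescence=f)


@dataclass(frozen=True)
class EnsembleSpec:
    """Design of a synthetic mutant ensemble.

    Truth values are drawn uniformly: ddG_eq over ``ddG_eq_range``
    (kcal/mol; the experimental ensemble spans about -1.3 to +3.3) and the
    Phi values over their ranges.  ``hammond_slope`` (kcal/mol)^-1, when
    non-zero, shifts per-variant mf/mu linearly with stability at constant
    m_DN to manufacture a Hammond-behaving ensemble (beta decreasing with
    increasing stability for a negative slope).
    """

    n_variants: int = 29
    wt_params: KineticParameters = WT_PARAMS
    ddG_eq_range: tuple[float, float] = (-1.3, 3.3)
    phi_ts1_range: tuple[float, float] = (0.1, 0.9)
    phi_ts2_range: tuple[float, float] = (0.3, 1.0)
    urea_grid: Sequence[float] = field(default_factory=lambda: DEFAULT_UREA_GRID.copy())
    noise_sd_log: float = 0.02
    trace_noise_sd: float = 0.01
    seed: int = 0
    hammond_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise InvalidParameterError("n_variants must be >= 0")
        for lo, hi in (self.ddG_eq_range, self.phi_ts1_range, self.phi_ts2_range):
            if not lo <= hi:
                raise InvalidParameterError(f"ill-ordered range ({lo}, {hi})")


def simulate_ensemble(spec: EnsembleSpec) -> tuple[list[ChevronDataset], pd.DataFrame]:
    """Wild type plus ``n_variants`` mutant chevrons and their truth table.

    Returns ``(datasets, truth)`` where ``truth`` has one row per dataset
    with the true parameters, ddG_eq and Phi values used to generate it.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    wt = spec.wt_params
    variants: list[tuple[str, KineticParameters, float, float, float]] = [
        ("wt", wt, 0.0, np.nan, np.nan)
    ]
    for i in range(spec.n_variants):
        g = rng.uniform(*spec.ddG_eq_range)
        p1 = rng.uniform(*spec.phi_ts1_range)
        p2 = rng.uniform(*spec.phi_ts2_range)
        mut = make_mutant(wt, g, p1, p2)
        if spec.hammond_slope != 0.0:
            # shift beta_TS1 linearly in stability at constant m_DN
            m_dn = wt.mf + wt.mu
            beta1 = wt.mf / m_dn + spec.hammond_slope * (-g)
            beta1 = float(np.clip(beta1, 0.05, 0.95))
            mut = replace(mut, mf=beta1 * m_dn, mu=(1.0 - beta1) * m_dn)
        variants.append((f"m{i + 1:02d}", mut, g, p1, p2))

    datasets: list[ChevronDataset] = []
    rows = []
    for vid, params, g, p1, p2 in variants:
        ds = simulate_chevron(
            params,
            spec.urea_grid,
            spec.noise_sd_log,
            seed=int(rng.integers(2**31 - 1)) if spec.noise_sd_log > 0 else None,
            variant_id=vid,
        )
        datasets.append(ds)
        rows.append(
            {
                "variant": vid,
                "kf0": params.kf0,
                "ku0": params.ku0,
                "Kpart": params.Kpart,
                "mf": params.mf,
                "mu": params.mu,
                "mpart": params.mpart,
                "ddG_eq": g,
                "phi_ts1": p1,
                "phi_ts2": p2,
                "dG_DN": stability(params)[0],
            }
        )
    return datasets, pd.DataFrame(rows)
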
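"""Three-state folding rate laws and derived thermodynamic quantities.

The model is a linear folding pathway D <-> I <-> N in which the intermediate
I is a high-energy (never populated) species, so the observed relaxation is
single-exponential at every denaturant concentration.  The rate-limiting
barrier switches from the early transition state TS1 to the late transition
state TS2 as urea increases, which shows up as a kink in the unfolding arm
of the chevron plot.  The observed rate constant is

    k_obs(u) = [kf0 exp(-mf u / RT) + ku0 exp(mu u / RT)]
               / [1 + Kpart exp(mpart u / RT)]

where ``Kpart`` is the partitioning constant between TS1 and TS2 and
``mpart`` its denaturant dependence.  ``Kpart = 0`` collapses the expression
to the classical two-state chevron.

Units: free energies in kcal/mol, m-values in kcal/mol/M, urea in M, rate
constants in 1/s.  ``RT`` defaults to 0.5925 kcal/mol (25 degrees C).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    BetaRangeWarning,
    DataError,
    DegenerateGeometryError,
    InvalidParameterError,
)

#: R*T in kcal/mol at 298.15 K (R = 1.987e-3 kcal/mol/K, T = 25 C).
RT_25C = 0.5925

__all__ = [
    "RT_25C",
    "KineticParameters",
    "TanfordBetas",
    "ChevronDataset",
    "two_state_rate",
    "three_state_rate",
    "stability",
    "beta_tanford",
]


@dataclass(frozen=True)
class KineticParameters:
    """Microscopic rate constants and m-values of one variant.

    Parameters
    ----------
    kf0, ku0 : float
        Folding / unfolding rate constants in water (1/s), strictly positive.
    mf, mu : float
        Kinetic m-values of the folding and unfolding limbs (kcal/mol/M),
        non-negative.
    Kpart : float
        Partitioning constant between the early and late transition state
        (dimensionless, >= 0).  Zero is the degenerate two-state case.
    mpart : float
        Denaturant dependence of the partitioning (kcal/mol/M, >= 0).
    RT : float
        Gas constant times temperature (kcal/mol).
    """

    kf0: float
    mf: float
    ku0: float
    mu: float
    Kpart: float = 0.0
    mpart: float = 0.0
    RT: float = RT_25C

    def __post_init__(self) -> None:
        vals = (self.kf0, self.mf, self.ku0, self.mu, self.Kpart, self.mpart, self.RT)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite kinetic parameter in {vals}")
        if self.kf0 <= 0 or self.ku0 <= 0:
            raise InvalidParameterError(
                f"rate constants must be strictly positive (kf0={self.kf0}, ku0={self.ku0})"
            )
        if self.mf < 0 or self.mu < 0 or self.mpart < 0:
            raise InvalidParameterError(
                f"m-values must be non-negative (mf={self.mf}, mu={self.mu}, mpart={self.mpart})"
            )
        if self.Kpart < 0:
            raise InvalidParameterError(f"Kpart must be >= 0, got {self.Kpart}")
        if self.RT <= 0:
            raise InvalidParameterError(f"RT must be positive, got {self.RT}")


@dataclass(frozen=True)
class TanfordBetas:
    """Fractional positions of TS1 and TS2 along the m-value reaction coordinate.

    ``beta = 0`` is denatured-like compactness, ``beta = 1`` native-like.
    Values outside [0, 1] are reported as-is with ``out_of_range=True``;
    the Hammond analysis needs the raw trend, so nothing is clamped.
    """

    beta_ts1: float
    beta_ts2: float
    out_of_range: bool = False


@dataclass(frozen=True)
class ChevronDataset:
    """Observed relaxation rates of one variant versus urea.

    Replicate urea values are allowed.  ``sigma`` (optional) holds one
    standard error per point, in 1/s.
    """

    variant_id: str
    urea: np.ndarray
    kobs: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        u = np.asarray(self.urea, dtype=float)
        k = np.asarray(self.kobs, dtype=float)
        object.__setattr__(self, "urea", u)
        object.__setattr__(self, "kobs", k)
        if u.ndim != 1 or k.shape != u.shape:
            raise DataError("urea and kobs must be 1-D arrays of equal length")
        if not (np.isfinite(u).all() and np.isfinite(k).all()):
            raise DataError(f"non-finite chevron data for {self.variant_id!r}")
        if (u < 0).any():
            raise DataError(f"negative urea concentration for {self.variant_id!r}")
        if (k <= 0).any():
            raise DataError(f"non-positive kobs for {self.variant_id!r}")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != u.shape or (s <= 0).any():
                raise DataError("sigma must be positive and match the data length")

    @property
    def n_points(self) -> int:
        return int(self.urea.size)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_points


def _as_urea(urea) -> np.ndarray:
    u = np.asarray(urea, dtype=float)
    if not np.isfinite(u).all():
        raise InvalidParameterError("urea must be finite")
    if (u < 0).any():
        raise InvalidParameterError("negative urea concentration rejected")
    return u


def two_state_rate(params: KineticParameters, urea):
    """Observed rate of a two-state folder: V-shaped (linear-limb) chevron.

    k_obs = kf0 exp(-mf u / RT) + ku0 exp(mu u / RT).
    Scalar in, scalar out; array in, array out.
    """
    u = _as_urea(urea)
    k = params.kf0 * np.exp(-params.mf * u / params.RT) + params.ku0 * np.exp(
        params.mu * u / params.RT
    )
    return float(k) if np.isscalar(urea) or np.ndim(urea) == 0 else k


def three_state_rate(params: KineticParameters, urea):
    """Observed rate with a high-energy on-pathway intermediate.

    The two-state numerator is divided by ``1 + Kpart exp(mpart u / RT)``;
    at high urea the unfolding-limb log-slope relaxes from mu/RT to
    (mu - mpart)/RT, producing the kink in the unfolding arm.  With
    ``Kpart = 0`` this is exactly :func:`two_state_rate`.
    """
    u = _as_urea(urea)
    num = params.kf0 * np.exp(-params.mf * u / params.RT) + params.ku0 * np.exp(
        params.mu * u / params.RT
    )
    den = 1.0 + params.Kpart * np.exp(params.mpart * u / params.RT)
    k = num / den
    return float(k) if np.isscalar(urea) or np.ndim(urea) == 0 else k


def stability(params: KineticParameters) -> tuple[float, float]:
    """Folding free energy and equilibrium m-value implied by the kinetics.

    Returns ``(dG_DN, m_DN)`` with ``dG_DN = RT ln(kf0/ku0)`` (positive for
    a stable native state) and ``m_DN = mf + mu``.  ``dG_DN`` depends only
    on the ratio kf0/ku0.
    """
    return params.RT * math.log(params.kf0 / params.ku0), params.mf + params.mu


def beta_tanford(params: KineticParameters) -> TanfordBetas:
    """Tanford beta values of the early and late transition states.

    beta_TS1 = mf / m_DN and beta_TS2 = 1 - (mu - mpart) / m_DN with
    m_DN = mf + mu.  Values outside [0, 1] are flagged (and a
    :class:`BetaRangeWarning` emitted) but never clamped.
    """
    m_dn = params.mf + params.mu
    if m_dn <= 0:
        raise DegenerateGeometryError("m_D-N = mf + mu must be positive for beta values")
    b1 = params.mf / m_dn
    b2 = 1.0 - (params.mu - params.mpart) / m_dn
    out = not (0.0 <= b1 <= 1.0 and 0.0 <= b2 <= 1.0)
    if out:
        warnings.warn(
            f"Tanford beta outside [0, 1]: beta_ts1={b1:.3f}, beta_ts2={b2:.3f}",
            BetaRangeWarning,
            stacklevel=2,
        )
    return TanfordBetas(beta_ts1=b1, beta_ts2=b2, out_of_range=out)
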
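"""Single-exponential fitting of stopped-flow fluorescence time courses.

Each mixing experiment relaxes as F(t) = offset + amplitude * exp(-kobs t);
the sign of the amplitude distinguishes unfolding (decay) from refolding
(rise).  A Wald-Wolfowitz runs test on the residuals is reported as a
lack-of-fit diagnostic but never escalates the model: the single
exponential is the model, by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    AlignmentError,
    DataError,
    FitFailureError,
    NoAmplitudeError,
    StateError,
)
from .kinetics import ChevronDataset

__all__ = [
    "ExponentialFit",
    "TraceRecord",
    "SingleExponentialModel",
    "fit_single_exponential",
    "average_traces",
    "build_chevron",
]


@dataclass(frozen=True)
class ExponentialFit:
    """Fitted parameters of one trace."""

    kobs: float
    amplitude: float
    offset: float
    rmse: float
    kobs_se: float = float("nan")
    runs_z: float = float("nan")


@dataclass(frozen=True)
class TraceRecord:
    """A stopped-flow time course, optionally with its exponential fit."""

    variant_id: str
    urea: float
    times: np.ndarray
    fluorescence: np.ndarray
    fit: Optional[ExponentialFit] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or f.shape != t.shape:
            raise DataError("times and fluorescence must be 1-D arrays of equal length")
        if t.size < 20:
            raise DataError(f"need >= 20 samples per trace, got {t.size}")
        if (t < 0).any() or (np.diff(t) <= 0).any():
            raise DataError("times must be non-negative and strictly increasing")
        if self.urea < 0:
            raise DataError("negative urea concentration")


class SingleExponentialModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of ``F(t) = offset + amplitude exp(-kobs t)``.

    Parameters
    ----------
    t_dead : float
        Samples with ``t < t_dead`` are dropped before fitting (instrument
        dead time); default 0 (keep everything).
    n_starts : int
        Number of perturbed restarts tried before declaring failure.
    seed : int
        Seed for the restart perturbations.

    Attributes (after :meth:`fit`)
    ------------------------------
    kobs_, amplitude_, offset_ : float
        Fitted parameters; ``kobs_`` is constrained positive.
    rmse_ : float
        Root-mean-square residual.
    kobs_se_ : float
        Covariance-derived standard error of ``kobs_``.
    runs_z_ : float
        Runs-test z statistic of the residual signs (lack-of-fit check).
    """

    def __init__(self, t_dead: float = 0.0, n_starts: int = 5, seed: int = 0):
        self.t_dead = t_dead
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        f = np.asarray(y, dtype=float).ravel()
        if t.shape != f.shape:
            raise DataError("time and fluorescence arrays differ in length")
        keep = t >= self.t_dead
        t, f = t[keep], f[keep]
        if t.size < 20:
            raise DataError("fewer than 20 usable samples after dead-time cut")

        # noise floor from first differences; a flat trace has no amplitude
        noise = float(np.std(np.diff(f))) / math.sqrt(2.0)
        signal = float(f.max() - f.min())
        sd_f = float(np.std(f))
        if sd_f == 0.0 or (noise > 0 and sd_f < 3.0 * noise):
            raise NoAmplitudeError(
                f"trace sd ({sd_f:.3g}) indistinguishable from noise floor ({noise:.3g})"
            )

        offset0 = float(np.mean(f[-max(2, t.size // 20):]))
        amp0 = float(f[0] - offset0)
        if amp0 == 0.0:
            amp0 = signal if f[0] > offset0 else -signal
        # time at which half the signal change has occurred
        half = offset0 + amp0 / 2.0
        crossed = np.nonzero((f - half) * np.sign(amp0) <= 0)[0]
        t_half = t[crossed[0]] if crossed.size and t[crossed[0]] > 0 else t[-1] / 10.0
        k0 = math.log(2.0) / t_half

        def resid(theta):
            off, amp, logk = theta
            return off + amp * np.exp(-np.exp(logk) * t) - f

        rng = np.random.default_rng(self.seed)
        best = None
        theta0 = np.array([offset0, amp0, math.log(k0)])
        for i in range(max(1, self.n_starts)):
            start = theta0 if i == 0 else theta0 + rng.normal(0, [abs(offset0) * 0.05 + noise, abs(amp0) * 0.3, 0.7])
            sol = least_squares(resid, start, method="lm", max_nfev=5000)
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitFailureError("single-exponential fit did not converge after multistart")

        off, amp, logk = best.x
        res = best.fun
        n, p = t.size, 3
        self.offset_ = float(off)
        self.amplitude_ = float(amp)
        self.kobs_ = float(np.exp(logk))
        self.rmse_ = float(np.sqrt(np.mean(res**2)))
        # delta-method SE of kobs from the log-kobs covariance
        try:
            jtj_inv = np.linalg.pinv(best.jac.T @ best.jac)
            s2 = float(res @ res) / max(n - p, 1)
            self.kobs_se_ = self.kobs_ * math.sqrt(max(s2 * jtj_inv[2, 2], 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            self.kobs_se_ = float("nan")
        self.runs_z_ = _runs_test_z(res)
        self.n_samples_ = n
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        return self.offset_ + self.amplitude_ * np.exp(-self.kobs_ * t)


def _runs_test_z(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs-test z statistic on residual signs."""
    s = np.sign(residuals)
    s = s[s != 0]
    if s.size < 2:
        return float("nan")
    n_pos = int((s > 0).sum())
    n_neg = int((s < 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    runs = 1 + int((s[1:] != s[:-1]).sum())
    n = n_pos + n_neg
    mean = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    return (runs - mean) / math.sqrt(var) if var > 0 else float("nan")


def fit_single_exponential(trace: TraceRecord, **kwargs) -> TraceRecord:
    """Fit one trace; returns a copy with ``fit`` populated.

    A warning-level check is applied post hoc: if the fitted relaxation
    time 1/kobs exceeds half the observed time window, the trace did not
    span enough signal evolution for a reliable rate.
    """
    import warnings

    model = SingleExponentialModel(**kwargs).fit(trace.times, trace.fluorescence)
    if 1.0 / model.kobs_ > (trace.times[-1] - trace.times[0]) / 2.0:
        warnings.warn(
            f"trace {trace.variant_id!r} at {trace.urea} M spans < 2 relaxation times",
            UserWarning,
            stacklevel=2,
        )
    return replace(
        trace,
        fit=ExponentialFit(
            kobs=model.kobs_,
            amplitude=model.amplitude_,
            offset=model.offset_,
            rmse=model.rmse_,
            kobs_se=model.kobs_se_,
            runs_z=model.runs_z_,
        ),
    )


def average_traces(traces: Sequence[TraceRecord]) -> TraceRecord:
    """Pointwise mean of replicate traces sharing time base and metadata."""
    if len(traces) < 2:
        raise DataError("need at least two traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if tr.times.shape != first.times.shape or not np.allclose(
            tr.times, first.times, rtol=0, atol=1e-12
        ):
            raise AlignmentError("traces do not share a common time base")
        if tr.variant_id != first.variant_id or tr.urea != first.urea:
            raise AlignmentError(
                f"metadata mismatch: ({tr.variant_id!r}, {tr.urea}) vs "
                f"({first.variant_id!r}, {first.urea})"
            )
    mean_f = np.mean([tr.fluorescence for tr in traces], axis=0)
    return TraceRecord(
        variant_id=first.variant_id,
        urea=first.urea,
        times=first.times.copy(),
        fluorescence=mean_f,
    )


def build_chevron(traces: Sequence[TraceRecord]) -> ChevronDataset:
    """Assemble fitted traces of one variant into a chevron dataset.

    Replicate urea values are preserved as separate points; sigma is taken
    from each fit's kobs standard error when finite.
    """
    if not traces:
        raise DataError("no traces given")
    vid = traces[0].variant_id
    urea, kobs, sigma = [], [], []
    for tr in traces:
        if tr.fit is None:
            raise StateError(f"unfitted trace present (variant {tr.variant_id!r}, {tr.urea} M)")
        if tr.variant_id != vid:
            raise StateError(f"mixed variants in one chevron: {vid!r} vs {tr.variant_id!r}")
        urea.append(tr.urea)
        kobs.append(tr.fit.kobs)
        sigma.append(tr.fit.kobs_se)
    sig = np.asarray(sigma, dtype=float)
    use_sigma = np.isfinite(sig).all() and (sig > 0).all()
    return ChevronDataset(
        variant_id=vid,
        urea=np.asarray(urea, dtype=float),
        kobs=np.asarray(kobs, dtype=float),
        sigma=sig if use_sigma else None,
    )
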
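"""Single and global (shared-parameter) chevron fitting.

Chevrons are fitted in log10(k_obs) space by nonlinear least squares.
Positivity of kf0, ku0 and Kpart is enforced by fitting their natural
logarithms; m-values are fitted on the natural scale with a lower bound of
zero.  The global fit stacks all variants into one parameter vector in
which the m-values selected by the constraint scheme appear exactly once:

* ``SHARED_ALL_M``          - mf, mu, mpart common to all variants (main analysis);
* ``FREE_MF_MU_SHARED_MPART`` - per-variant mf and mu, shared mpart (Hammond analysis);
* ``FREE_MF_ONLY``          - per-variant mf, shared mu and mpart (robustness check);
* ``FREE_ALL_M``            - nothing shared; typically degenerate and only
  exposed so the degeneracy diagnostics can demonstrate why.

Per-variant kf0, ku0 and Kpart are always free.  Standard errors come from
the Gauss-Newton covariance ``s^2 (J^T J)^+`` at the solution, mapped back
to the natural scale by the delta method.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .exceptions import DataError, DegeneracyWarning, FitFailureError
from .kinetics import (
    ChevronDataset,
    KineticParameters,
    TanfordBetas,
    beta_tanford,
    three_state_rate,
    two_state_rate,
)

__all__ = [
    "ConstraintScheme",
    "GlobalFitResult",
    "ChevronModel",
    "GlobalChevronModel",
    "fit_single_chevron",
    "global_fit",
    "betas_per_variant",
]

LN10 = math.log(10.0)
_M_NAMES = ("mf", "mu", "mpart")

#: Relative-SSR convergence tolerance and evaluation budget.
FTOL = 1e-10
MAX_NFEV = 5000


class ConstraintScheme(str, enum.Enum):
    """Which kinetic m-values are shared across variants in a global fit."""

    SHARED_ALL_M = "shared_all_m"
    FREE_MF_MU_SHARED_MPART = "free_mf_mu"
    FREE_MF_ONLY = "free_mf"
    FREE_ALL_M = "free_all_m"

    @property
    def shared_m(self) -> tuple[str, ...]:
        return {
            ConstraintScheme.SHARED_ALL_M: ("mf", "mu", "mpart"),
            ConstraintScheme.FREE_MF_MU_SHARED_MPART: ("mpart",),
            ConstraintScheme.FREE_MF_ONLY: ("mu", "mpart"),
            ConstraintScheme.FREE_ALL_M: (),
        }[self]

    @property
    def free_m(self) -> tuple[str, ...]:
        return tuple(m for m in _M_NAMES if m not in self.shared_m)


# ---------------------------------------------------------------------------
# single chevron


def _rate(model: str, params: KineticParameters, u: np.ndarray) -> np.ndarray:
    return (three_state_rate if model == "three_state" else two_state_rate)(params, u)


def _log10_rate(model: str, params: KineticParameters, u: np.ndarray) -> np.ndarray:
    """log10 k_obs, finite even where an exploratory step overflows exp."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        lk = np.log10(_rate(model, params, u))
    return np.nan_to_num(lk, nan=300.0, posinf=300.0, neginf=-300.0)


def _theta_names(model: str) -> list[str]:
    if model == "three_state":
        return ["ln_kf0", "ln_ku0", "ln_Kpart", "mf", "mu", "mpart"]
    return ["ln_kf0", "ln_ku0", "mf", "mu"]


def _exp(x: float) -> float:
    # clamp so exploratory optimizer steps cannot overflow exp()
    return math.exp(min(max(float(x), -700.0), 700.0))


def _theta_to_params(model: str, theta: np.ndarray, rt: float) -> KineticParameters:
    if model == "three_state":
        return KineticParameters(
            kf0=_exp(theta[0]),
            ku0=_exp(theta[1]),
            Kpart=_exp(theta[2]),
            mf=theta[3],
            mu=theta[4],
            mpart=theta[5],
            RT=rt,
        )
    return KineticParameters(
        kf0=_exp(theta[0]), ku0=_exp(theta[1]), mf=theta[2], mu=theta[3], RT=rt
    )


def _log_sigma(data: ChevronDataset) -> Optional[np.ndarray]:
    if data.sigma is None:
        return None
    return data.sigma / (data.kobs * LN10)


def _arm_init(data: ChevronDataset, rt: float) -> dict[str, float]:
    """Heuristic start from the two chevron limbs.

    Log-linear regressions on the folding (left of the minimum) and
    unfolding (right of the minimum) arms give kf0/mf and an apparent
    unfolding slope; the partitioning terms start generic (Kpart = 0.02,
    mpart = half the apparent unfolding m-value).
    """
    order = np.argsort(data.urea, kind="stable")
    u, k = data.urea[order], np.log10(data.kobs[order])
    imin = int(np.argmin(k))
    out = {
        "ln_kf0": math.log(max(data.kobs.max(), 1e-6)),
        "mf": 1.0,
        "ln_ku0": math.log(max(data.kobs.min() / 2.0, 1e-9)),
        "mu": 0.5,
    }
    left, right = slice(0, imin + 1), slice(imin, None)
    if np.unique(u[left]).size >= 2:
        fit = stats.linregress(u[left], k[left])
        mf = -fit.slope * rt * LN10
        if mf > 0:
            out["mf"] = mf
            out["ln_kf0"] = fit.intercept * LN10
    if np.unique(u[right]).size >= 2:
        fit = stats.linregress(u[right], k[right])
        mu = fit.slope * rt * LN10
        if mu > 0:
            out["mu"] = mu
            out["ln_ku0"] = fit.intercept * LN10
    out["ln_Kpart"] = math.log(0.02)
    out["mpart"] = out["mu"] / 2.0
    return out


class ChevronModel(BaseEstimator):
    """Nonlinear least-squares fit of one chevron.

    Parameters
    ----------
    model : {"three_state", "two_state"}
    n_starts : int
        Multistart budget: start 0 is the arm-regression heuristic, the
        rest are seeded perturbations of it.
    weighted : bool
        Weight residuals by per-point sigma (converted to log10 units).
    rt : float
        RT in kcal/mol.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : KineticParameters
    stderr_ : dict mapping parameter name to standard error (natural scale)
    objective_ : float, sum of squared log10 residuals
    """

    def __init__(
        self,
        model: str = "three_state",
        n_starts: int = 10,
        seed: int = 0,
        weighted: bool = False,
        rt: float = KineticParameters.__dataclass_fields__["RT"].default,
        init: Optional[KineticParameters] = None,
    ):
        self.model = model
        self.n_starts = n_starts
        self.seed = seed
        self.weighted = weighted
        self.rt = rt
        self.init = init

    def fit(self, X, y=None, sigma=None):
        if isinstance(X, ChevronDataset):
            data = X
        else:
            data = ChevronDataset("data", np.asarray(X, float).ravel(), np.asarray(y, float), sigma)
        min_pts = 7 if self.model == "three_state" else 5
        if data.n_points < min_pts:
            raise DataError(
                f"{self.model} chevron fit for {data.variant_id!r} needs >= {min_pts} "
                f"points, got {data.n_points}"
            )
        names = _theta_names(self.model)
        init = _arm_init(data, self.rt)
        if self.init is not None:
            init = {
                "ln_kf0": math.log(self.init.kf0),
                "ln_ku0": math.log(self.init.ku0),
                "ln_Kpart": math.log(self.init.Kpart) if self.init.Kpart > 0 else math.log(0.02),
                "mf": self.init.mf,
                "mu": self.init.mu,
                "mpart": self.init.mpart,
            }
        theta0 = np.array([init[n] for n in names])
        logk = np.log10(data.kobs)
        w = _log_sigma(data) if self.weighted else None

        def resid(theta):
            p = _theta_to_params(self.model, theta, self.rt)
            r = _log10_rate(self.model, p, data.urea) - logk
            return r / w if w is not None else r

        lower = np.array([-np.inf if n.startswith("ln_") else 0.0 for n in names])
        rng = np.random.default_rng(self.seed)
        best = None
        for i in range(max(1, self.n_starts)):
            start = theta0.copy()
            if i > 0:
                start += rng.normal(0.0, 0.5, size=start.shape)
                start = np.maximum(start, lower + 1e-9 * (lower == 0.0))
            sol = least_squares(
                resid, start, bounds=(lower, np.inf), method="trf",
                ftol=FTOL, xtol=1e-12, max_nfev=MAX_NFEV, x_scale="jac",
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitFailureError(
                f"chevron fit for {data.variant_id!r} did not converge after multistart"
            )
        self.params_ = _theta_to_params(self.model, best.x, self.rt)
        self.objective_ = float(2.0 * best.cost)
        self.stderr_ = _stderr_from_jac(best, names, {})
        self.converged_ = True
        self.n_points_ = data.n_points
        return self

    def predict(self, X):
        return _rate(self.model, self.params_, np.asarray(X, float))


def _stderr_from_jac(sol, names: Sequence[str], _unused) -> dict[str, float]:
    """Natural-scale standard errors from the least-squares Jacobian."""
    n, p = sol.fun.size, sol.x.size
    dof = max(n - p, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    out: dict[str, float] = {}
    for name, s, x in zip(names, se, sol.x):
        if name.startswith("ln_"):
            out[name[3:]] = math.exp(x) * s  # delta method for exp(theta)
        else:
            out[name] = s
    return out


def fit_single_chevron(
    data: ChevronDataset,
    model: str = "three_state",
    init: Optional[KineticParameters] = None,
    **kwargs,
) -> tuple[KineticParameters, dict[str, float], float]:
    """Fit one chevron; returns ``(params, standard_errors, objective)``."""
    m = ChevronModel(model=model, init=init, **kwargs).fit(data)
    return m.params_, m.stderr_, m.objective_


# ---------------------------------------------------------------------------
# global fit


@dataclass(frozen=True)
class GlobalFitResult:
    """Joint fit of many chevrons under one constraint scheme."""

    scheme: ConstraintScheme
    per_variant: Mapping[str, KineticParameters]
    standard_errors: Mapping[str, Mapping[str, float]]
    shared: Mapping[str, float]
    objective: float
    converged: bool
    n_points: int
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for vid, p in self.per_variant.items():
            row = {"variant": vid, "kf0": p.kf0, "ku0": p.ku0, "Kpart": p.Kpart,
                   "mf": p.mf, "mu": p.mu, "mpart": p.mpart}
            for name, se in self.standard_errors.get(vid, {}).items():
                row[f"{name}_se"] = se
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "shared": dict(self.shared),
            "objective": self.objective,
            "converged": self.converged,
            "n_points": self.n_points,
            "per_variant": {
                vid: {
                    "kf0": p.kf0, "ku0": p.ku0, "Kpart": p.Kpart,
                    "mf": p.mf, "mu": p.mu, "mpart": p.mpart, "RT": p.RT,
                    "se": dict(self.standard_errors.get(vid, {})),
                }
                for vid, p in self.per_variant.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GlobalFitResult":
        per_variant = {}
        errors = {}
        for vid, entry in doc["per_variant"].items():
            errors[vid] = dict(entry.get("se", {}))
            per_variant[vid] = KineticParameters(
                kf0=entry["kf0"], ku0=entry["ku0"], Kpart=entry["Kpart"],
                mf=entry["mf"], mu=entry["mu"], mpart=entry["mpart"], RT=entry["RT"],
            )
        return cls(
            scheme=ConstraintScheme(doc["scheme"]),
            per_variant=per_variant,
            standard_errors=errors,
            shared=dict(doc["shared"]),
            objective=float(doc["objective"]),
            converged=bool(doc["converged"]),
            n_points=int(doc["n_points"]),
        )

    @classmethod
    def from_json(cls, path) -> "GlobalFitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class _GlobalParameterMap:
    """Index bookkeeping between the joint vector and per-variant parameters."""

    def __init__(self, variant_ids: Sequence[str], scheme: ConstraintScheme):
        self.ids = list(variant_ids)
        self.scheme = scheme
        self.names: list[str] = [f"shared:{m}" for m in scheme.shared_m]
        for vid in self.ids:
            self.names += [f"{vid}:ln_kf0", f"{vid}:ln_ku0", f"{vid}:ln_Kpart"]
            self.names += [f"{vid}:{m}" for m in scheme.free_m]
        self.index = {n: i for i, n in enumerate(self.names)}
        self.size = len(self.names)

    def lower_bounds(self) -> np.ndarray:
        return np.array(
            [-np.inf if n.endswith(("ln_kf0", "ln_ku0", "ln_Kpart")) else 0.0 for n in self.names]
        )

    def pack(self, per_variant: Mapping[str, KineticParameters], shared: Mapping[str, float]) -> np.ndarray:
        theta = np.empty(self.size)
        for m in self.scheme.shared_m:
            theta[self.index[f"shared:{m}"]] = shared[m]
        for vid in self.ids:
            p = per_variant[vid]
            theta[self.index[f"{vid}:ln_kf0"]] = math.log(p.kf0)
            theta[self.index[f"{vid}:ln_ku0"]] = math.log(p.ku0)
            theta[self.index[f"{vid}:ln_Kpart"]] = math.log(max(p.Kpart, 1e-8))
            for m in self.scheme.free_m:
                theta[self.index[f"{vid}:{m}"]] = getattr(p, m)
        return theta

    def unpack(self, theta: np.ndarray, rt: float) -> tuple[dict[str, KineticParameters], dict[str, float]]:
        shared = {m: float(theta[self.index[f"shared:{m}"]]) for m in self.scheme.shared_m}
        per_variant: dict[str, KineticParameters] = {}
        for vid in self.ids:
            kw = dict(shared)
            for m in self.scheme.free_m:
                kw[m] = float(theta[self.index[f"{vid}:{m}"]])
            per_variant[vid] = KineticParameters(
                kf0=_exp(theta[self.index[f"{vid}:ln_kf0"]]),
                ku0=_exp(theta[self.index[f"{vid}:ln_ku0"]]),
                Kpart=_exp(theta[self.index[f"{vid}:ln_Kpart"]]),
                RT=rt,
                **kw,
            )
        return per_variant, shared


class GlobalChevronModel(BaseEstimator):
    """Joint three-state fit of many chevrons under a constraint scheme.

    ``fit`` accepts a list of :class:`ChevronDataset` (or a long-format
    DataFrame with columns variant, urea_M, kobs_s1 and optional sigma).
    The start point is assembled from per-variant single-chevron fits with
    shared m-values initialized at their across-variant medians; seeded
    randomized restarts are attempted only if that start fails to converge.
    """

    def __init__(
        self,
        scheme: ConstraintScheme | str = ConstraintScheme.SHARED_ALL_M,
        weighted: bool = False,
        rt: float = KineticParameters.__dataclass_fields__["RT"].default,
        wt_id: str = "wt",
        n_starts: int = 10,
        seed: int = 0,
        require_wt: bool = True,
    ):
        self.scheme = scheme
        self.weighted = weighted
        self.rt = rt
        self.wt_id = wt_id
        self.n_starts = n_starts
        self.seed = seed
        self.require_wt = require_wt

    def fit(self, X, y=None, init: Optional[Mapping[str, KineticParameters]] = None):
        datasets = _as_datasets(X)
        scheme = ConstraintScheme(self.scheme)
        if len(datasets) < 2:
            raise DataError("global fit needs at least two chevron datasets")
        ids = [d.variant_id for d in datasets]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate variant ids in global fit input")
        if self.require_wt and not any(v.lower() == self.wt_id.lower() for v in ids):
            raise DataError(f"wild-type dataset {self.wt_id!r} missing from global fit input")
        too_small = [d.variant_id for d in datasets if d.n_points < 7]
        if too_small:
            raise DataError(
                "too few points (< 7) for a three-state fit: " + ", ".join(too_small)
            )

        pmap = _GlobalParameterMap(ids, scheme)
        per_variant0, shared0, failures = self._initial_guesses(datasets, init)
        if failures and len(failures) == len(datasets):
            raise FitFailureError(f"no variant could be initialized: {failures}")
        theta0 = pmap.pack(per_variant0, shared0)

        u_all = np.concatenate([d.urea for d in datasets])
        logk_all = np.concatenate([np.log10(d.kobs) for d in datasets])
        slices = []
        start = 0
        for d in datasets:
            slices.append(slice(start, start + d.n_points))
            start += d.n_points
        weights = None
        if self.weighted:
            if any(d.sigma is None for d in datasets):
                raise DataError("weighted fit requested but sigma missing for some datasets")
            weights = np.concatenate([_log_sigma(d) for d in datasets])

        def resid(theta):
            per_variant, _ = pmap.unpack(theta, self.rt)
            model = np.empty_like(logk_all)
            for d, sl in zip(datasets, slices):
                model[sl] = _log10_rate("three_state", per_variant[d.variant_id], u_all[sl])
            r = model - logk_all
            return r / weights if weights is not None else r

        lower = pmap.lower_bounds()
        rng = np.random.default_rng(self.seed)
        best = None
        for i in range(max(1, self.n_starts)):
            start_vec = theta0 if i == 0 else theta0 + rng.normal(0.0, 0.3, size=theta0.shape)
            start_vec = np.maximum(start_vec, lower)
            sol = least_squares(
                resid, start_vec, bounds=(lower, np.inf), method="trf",
                ftol=FTOL, xtol=1e-12, max_nfev=MAX_NFEV, x_scale="jac",
            )
            if sol.success:
                best = sol
                break
        if best is None:
            raise FitFailureError(
                f"global fit ({scheme.value}) did not converge; "
                f"variants with failing single fits: {sorted(failures) or 'none'}"
            )

        per_variant, shared = pmap.unpack(best.x, self.rt)
        se = self._standard_errors(best, pmap)
        self.result_ = GlobalFitResult(
            scheme=scheme,
            per_variant=per_variant,
            standard_errors=se,
            shared=shared,
            objective=float(2.0 * best.cost),
            converged=True,
            n_points=int(logk_all.size),
            message=best.message,
        )
        return self

    def _initial_guesses(self, datasets, init=None):
        per_variant: dict[str, KineticParameters] = {}
        failures: list[str] = []
        for d in datasets:
            if init is not None and d.variant_id in init:
                per_variant[d.variant_id] = init[d.variant_id]
                continue
            try:
                p, _, _ = fit_single_chevron(
                    d, model="three_state", n_starts=5, seed=self.seed, rt=self.rt
                )
                per_variant[d.variant_id] = p
            except (FitFailureError, DataError):
                failures.append(d.variant_id)
        if per_variant:
            med = {
                m: float(np.median([getattr(p, m) for p in per_variant.values()]))
                for m in _M_NAMES
            }
            med_rates = {
                name: float(np.median([getattr(p, name) for p in per_variant.values()]))
                for name in ("kf0", "ku0", "Kpart")
            }
        else:
            med = {"mf": 1.0, "mu": 0.5, "mpart": 0.25}
            med_rates = {"kf0": 100.0, "ku0": 0.1, "Kpart": 0.02}
        for d in datasets:
            if d.variant_id not in per_variant:
                per_variant[d.variant_id] = KineticParameters(RT=self.rt, **med_rates, **med)
        shared = {m: max(med[m], 1e-3) for m in _M_NAMES}
        return per_variant, shared, failures

    def _standard_errors(self, sol, pmap: _GlobalParameterMap):
        n, p = sol.fun.size, sol.x.size
        s2 = float(sol.fun @ sol.fun) / max(n - p, 1)
        jtj = sol.jac.T @ sol.jac
        cov = s2 * np.linalg.pinv(jtj)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        _warn_if_degenerate(sol.jac, pmap.names)
        out: dict[str, dict[str, float]] = {vid: {} for vid in pmap.ids}
        shared_se = {}
        for name, s, x in zip(pmap.names, se_vec, sol.x):
            owner, pname = name.split(":")
            if pname.startswith("ln_"):
                s_nat, pname = math.exp(x) * s, pname[3:]
            else:
                s_nat = s
            if owner == "shared":
                shared_se[pname] = s_nat
            else:
                out[owner][pname] = s_nat
        for vid in pmap.ids:
            out[vid].update(shared_se)
        return out

    def predict(self, variant_id: str, urea):
        return three_state_rate(self.result_.per_variant[variant_id], np.asarray(urea, float))


def _warn_if_degenerate(jac: np.ndarray, names: Sequence[str], rcond: float = 1e-8) -> None:
    u_, sv, vt = np.linalg.svd(jac, full_matrices=False)
    if sv[0] == 0 or sv[-1] / sv[0] < rcond:
        bad = np.where(sv / sv[0] < rcond)[0]
        implicated: set[str] = set()
        for i in bad:
            comp = np.abs(vt[i])
            implicated.update(np.asarray(names)[comp > 0.3 * comp.max()])
        warnings.warn(
            "near-singular Jacobian; unreliable parameters: " + ", ".join(sorted(implicated)),
            DegeneracyWarning,
            stacklevel=3,
        )


def _as_datasets(X) -> list[ChevronDataset]:
    if isinstance(X, pd.DataFrame):
        out = []
        for vid, grp in X.groupby("variant", sort=False):
            sigma = grp["sigma"].to_numpy() if "sigma" in grp and grp["sigma"].notna().all() else None
            out.append(
                ChevronDataset(
                    variant_id=str(vid),
                    urea=grp["urea_M"].to_numpy(),
                    kobs=grp["kobs_s1"].to_numpy(),
                    sigma=sigma,
                )
            )
        return out
    return list(X)


def global_fit(
    datasets: Sequence[ChevronDataset],
    scheme: ConstraintScheme | str = ConstraintScheme.SHARED_ALL_M,
    init: Optional[Mapping[str, KineticParameters]] = None,
    **kwargs,
) -> GlobalFitResult:
    """Joint least-squares fit of all chevrons; see :class:`GlobalChevronModel`."""
    model = GlobalChevronModel(scheme=scheme, **kwargs).fit(datasets, init=init)
    return model.result_


def betas_per_variant(result: GlobalFitResult) -> dict[str, TanfordBetas]:
    """Tanford betas of every variant in a global fit result.

    Under ``SHARED_ALL_M`` all betas are identical by construction; this is
    permitted but warned about, since a Hammond analysis needs per-variant
    m-values.
    """
    if result.scheme is ConstraintScheme.SHARED_ALL_M:
        warnings.warn(
            "scheme shares all m-values: betas are identical across variants",
            UserWarning,
            stacklevel=2,
        )
    return {vid: beta_tanford(p) for vid, p in result.per_variant.items()}
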
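"""Single-chevron and shared-parameter global fitting."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import foldkin as fk
from foldkin.exceptions import DataError, DegeneracyWarning
from foldkin.fitting import _warn_if_degenerate

GRID25 = np.linspace(0.0, 9.0, 25)


class TestSingleChevron:
    def test_noiseless_recovery(self, wt):
        ds = fk.simulate_chevron(wt, GRID25, 0.0, variant_id="wt")
        p, se, obj = fk.fit_single_chevron(ds)
        for name in ("kf0", "ku0", "Kpart", "mf", "mu", "mpart"):
            assert getattr(p, name) == pytest.approx(getattr(wt, name), rel=1e-4)
        assert obj < 1e-12

    def test_noisy_recovery_median_error(self, wt):
        """5% multiplicative noise: kf0 recovered within 10% in the median."""
        rel_errors = []
        for rep in range(20):
            ds = fk.simulate_chevron(wt, GRID25, 0.05 / np.log(10), seed=1000 + rep)
            p, _, _ = fk.fit_single_chevron(ds, n_starts=3)
            rel_errors.append(abs(p.kf0 - wt.kf0) / wt.kf0)
        assert np.median(rel_errors) < 0.10

    def test_two_state_model_fit(self):
        p_true = fk.KineticParameters(kf0=100.0, mf=1.2, ku0=0.05, mu=0.6)
        u = np.linspace(0, 8, 15)
        ds = fk.ChevronDataset("v", u, fk.two_state_rate(p_true, u))
        p, _, _ = fk.fit_single_chevron(ds, model="two_state")
        assert p.kf0 == pytest.approx(100.0, rel=1e-6)
        assert p.mu == pytest.approx(0.6, rel=1e-6)

    def test_too_few_points_rejected(self, wt):
        ds = fk.simulate_chevron(wt, np.linspace(0, 9, 4), 0.0)
        with pytest.raises(DataError):
            fk.fit_single_chevron(ds)
        ds6 = fk.simulate_chevron(wt, np.linspace(0, 9, 6), 0.0)
        with pytest.raises(DataError):
            fk.fit_single_chevron(ds6, model="three_state")

    def test_standard_errors_positive_under_noise(self, wt):
        ds = fk.simulate_chevron(wt, GRID25, 0.02, seed=5)
        _, se, _ = fk.fit_single_chevron(ds)
        assert all(v >= 0 for v in se.values())
        assert se["kf0"] > 0


class TestGlobalFit:
    def test_noiseless_exact_recovery(self, wt):
        spec = fk.EnsembleSpec(n_variants=4, urea_grid=GRID25, noise_sd_log=0.0, seed=1)
        datasets, truth = fk.simulate_ensemble(spec)
        res = fk.global_fit(datasets, "shared_all_m", seed=0)
        truth = truth.set_index("variant")
        for vid, p in res.per_variant.items():
            for name in ("kf0", "ku0", "Kpart"):
                assert getattr(p, name) == pytest.approx(truth.loc[vid, name], rel=1e-5)
        for m in ("mf", "mu", "mpart"):
            assert res.shared[m] == pytest.approx(getattr(wt, m), rel=1e-5)

    def test_shared_fields_identical_across_variants(self, small_global_fit):
        res = small_global_fit
        for p in res.per_variant.values():
            assert p.mf == res.shared["mf"]
            assert p.mu == res.shared["mu"]
            assert p.mpart == res.shared["mpart"]

    def test_nested_scheme_objective_ordering(self, small_ensemble, small_global_fit):
        datasets, _ = small_ensemble
        obj_shared = small_global_fit.objective
        obj_free_mf = fk.global_fit(datasets, "free_mf", seed=0).objective
        obj_free_mf_mu = fk.global_fit(datasets, "free_mf_mu", seed=0).objective
        assert obj_free_mf_mu <= obj_free_mf + 1e-9
        assert obj_free_mf <= obj_shared + 1e-9

    def test_permutation_invariance(self, small_ensemble, small_global_fit):
        datasets, _ = small_ensemble
        res_rev = fk.global_fit(datasets[::-1], "shared_all_m", seed=0)
        for m in ("mf", "mu", "mpart"):
            assert res_rev.shared[m] == pytest.approx(small_global_fit.shared[m], rel=1e-6)
        for vid, p in small_global_fit.per_variant.items():
            assert res_rev.per_variant[vid].kf0 == pytest.approx(p.kf0, rel=1e-5)

    def test_missing_wildtype_rejected(self, small_ensemble):
        datasets, _ = small_ensemble
        with pytest.raises(DataError, match="wild-type"):
            fk.global_fit(datasets[1:], "shared_all_m", seed=0)

    def test_small_dataset_names_offender(self, wt, small_ensemble):
        datasets, _ = small_ensemble
        bad = fk.simulate_chevron(wt, np.linspace(0, 9, 4), 0.0, variant_id="short")
        with pytest.raises(DataError, match="short"):
            fk.global_fit(list(datasets) + [bad], "shared_all_m", seed=0)

    def test_matches_lmfit_shared_parameter_oracle(self, wt):
        """Independent shared-m fit via lmfit must land on the same optimum."""
        lmfit = pytest.importorskip("lmfit")
        spec = fk.EnsembleSpec(
            n_variants=2, urea_grid=np.linspace(0, 9, 15), noise_sd_log=0.01, seed=77
        )
        datasets, _ = fk.simulate_ensemble(spec)
        res = fk.global_fit(datasets, "shared_all_m", seed=0)

        pars = lmfit.Parameters()
        for m, val in (("mf", 1.0), ("mu", 0.5), ("mpart", 0.3)):
            pars.add(m, value=val, min=0.0)
        for d in datasets:
            v = d.variant_id
            pars.add(f"lnkf_{v}", value=np.log(d.kobs.max()))
            pars.add(f"lnku_{v}", value=np.log(d.kobs.min() / 2))
            pars.add(f"lnKp_{v}", value=np.log(0.02))

        def residual(pars):
            out = []
            for d in datasets:
                v = d.variant_id
                p = fk.KineticParameters(
                    kf0=np.exp(pars[f"lnkf_{v}"].value),
                    ku0=np.exp(pars[f"lnku_{v}"].value),
                    Kpart=np.exp(pars[f"lnKp_{v}"].value),
                    mf=pars["mf"].value, mu=pars["mu"].value, mpart=pars["mpart"].value,
                )
                out.append(np.log10(fk.three_state_rate(p, d.urea)) - np.log10(d.kobs))
            return np.concatenate(out)

        oracle = lmfit.minimize(residual, pars, method="least_squares")
        assert float(oracle.params["mf"].value) == pytest.approx(res.shared["mf"], rel=1e-3)
        assert float(oracle.params["mu"].value) == pytest.approx(res.shared["mu"], rel=1e-3)
        assert float(oracle.params["mpart"].value) == pytest.approx(res.shared["mpart"], rel=1e-3)
        assert 2 * float(oracle.chisqr) / 2 == pytest.approx(res.objective, rel=1e-4)

    def test_confidence_interval_coverage(self):
        """90% intervals from the fit covariance cover truth at roughly
        the nominal rate (pooled over rate parameters and replicates)."""
        z90 = 1.645
        hits = total = 0
        for rep in range(8):
            spec = fk.EnsembleSpec(
                n_variants=4, urea_grid=np.linspace(0, 9, 21),
                noise_sd_log=0.02, seed=9000 + rep,
            )
            datasets, truth = fk.simulate_ensemble(spec)
            res = fk.global_fit(datasets, "shared_all_m", seed=0)
            truth = truth.set_index("variant")
            for vid, p in res.per_variant.items():
                se = res.standard_errors[vid]
                for name in ("kf0", "ku0", "Kpart"):
                    est, s, true = getattr(p, name), se[name], truth.loc[vid, name]
                    if s > 0:
                        hits += abs(est - true) <= z90 * s
                        total += 1
        assert total >= 100
        assert 0.75 <= hits / total <= 1.0


class TestBetasPerVariant:
    def test_shared_scheme_betas_identical_with_warning(self, small_global_fit):
        with pytest.warns(UserWarning, match="identical"):
            betas = fk.betas_per_variant(small_global_fit)
        vals = {(b.beta_ts1, b.beta_ts2) for b in betas.values()}
        assert len(vals) == 1

    def test_hammond_ensemble_betas_vary(self):
        spec = fk.EnsembleSpec(
            n_variants=8, urea_grid=np.linspace(0, 9, 21),
            noise_sd_log=0.01, seed=31, hammond_slope=-0.03,
        )
        datasets, _ = fk.simulate_ensemble(spec)
        res = fk.global_fit(datasets, "free_mf_mu", seed=0)
        betas = fk.betas_per_variant(res)
        b1 = [b.beta_ts1 for b in betas.values()]
        assert np.std(b1) > 0.005

    def test_mu_below_mpart_flags_beta_above_one(self, small_global_fit):
        from foldkin.exceptions import BetaRangeWarning

        p = replace(small_global_fit.per_variant["wt"], mu=0.3, mpart=0.45)
        with pytest.warns(BetaRangeWarning):
            b = fk.beta_tanford(p)
        assert b.beta_ts2 > 1.0
        assert b.out_of_range


def test_degeneracy_warning_names_parameters():
    # rank-deficient Jacobian: two perfectly collinear columns
    jac = np.array([[1.0, 1.0, 0.3], [2.0, 2.0, 0.1], [3.0, 3.0, 0.9]])
    with pytest.warns(DegeneracyWarning, match="a|b"):
        _warn_if_degenerate(jac, ["a", "b", "c"])
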
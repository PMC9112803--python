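"""LFER, Hammond and Phi-vs-Phi regressions."""

import numpy as np
import pytest

import foldkin as fk
from foldkin.exceptions import DataError
from foldkin.kinetics import TanfordBetas
from foldkin.phi import VariantThermo


def thermo_row(vid, ddg_eq, y_ts1, ddg_ts2n, excluded=False):
    return VariantThermo(
        variant_id=vid,
        ddG_D_TS1=y_ts1,
        ddG_TS1_N=ddg_eq - y_ts1,
        ddG_TS2_N=ddg_ts2n,
        ddG_eq=ddg_eq,
        phi_ts1=None if excluded else y_ts1 / ddg_eq,
        phi_ts2=None if excluded else 1 - ddg_ts2n / ddg_eq,
        category_ts1="excluded" if excluded else "low",
        category_ts2="excluded" if excluded else "low",
    )


class TestLfer:
    def test_exact_half_slope(self):
        rows = [thermo_row(f"v{i}", x, 0.5 * x, 0.0) for i, x in enumerate([0.5, 1, 2, 3])]
        res = fk.lfer_fit(rows, "TS1")
        assert res.alpha == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.n_variants == 4

    def test_identity_line_gives_unit_slope(self):
        rows = [thermo_row(f"v{i}", x, x, 0.0) for i, x in enumerate([0.5, 1.5, 2.5])]
        assert fk.lfer_fit(rows, "TS1").alpha == pytest.approx(1.0, abs=1e-12)

    def test_ts2_uses_late_barrier(self):
        # ddG_TS2_N = (1 - 0.8) * ddG_eq => alpha_TS2 = 0.8
        rows = [thermo_row(f"v{i}", x, 0.3 * x, 0.2 * x) for i, x in enumerate([0.5, 1, 2, 3])]
        assert fk.lfer_fit(rows, "TS2").alpha == pytest.approx(0.8, abs=1e-12)

    def test_excluded_and_extra_excluded_dropped(self):
        rows = [thermo_row(f"v{i}", x, 0.5 * x, 0.0) for i, x in enumerate([1, 2, 3, 4])]
        rows.append(thermo_row("near_neutral", 0.1, 0.05, 0.0, excluded=True))
        res = fk.lfer_fit(rows, "TS1", extra_exclude=["v3"])
        assert res.n_variants == 3
        assert "near_neutral" not in res.included_ids
        assert "v3" not in res.included_ids

    def test_too_few_variants_rejected(self):
        rows = [thermo_row("a", 1, 0.5, 0), thermo_row("b", 2, 1.0, 0)]
        with pytest.raises(DataError):
            fk.lfer_fit(rows, "TS1")

    def test_slope_recovery_within_two_se(self):
        """y = 0.6 x + noise: the fitted slope covers truth in ~95% of replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            x = rng.uniform(-1, 3, 20)
            y = 0.6 * x + rng.normal(0, 0.15, 20)
            rows = [thermo_row(f"v{i}", xi, yi, 0.0) for i, (xi, yi) in enumerate(zip(x, y))]
            res = fk.lfer_fit(rows, "TS1")
            hits += abs(res.alpha - 0.6) <= 2 * res.se_alpha
        assert hits / n_rep >= 0.90

    def test_fixture_late_ts_more_native_like(self, fixture_table):
        rows = fk.fixture_thermo(fixture_table)
        a1 = fk.lfer_fit(rows, "TS1").alpha
        a2 = fk.lfer_fit(rows, "TS2").alpha
        assert a2 > a1


class TestHammond:
    def test_constant_beta_zero_slope(self):
        betas = {f"v{i}": TanfordBetas(0.6, 0.9) for i in range(5)}
        stab = {f"v{i}": 3.0 + i for i in range(5)}
        assert fk.hammond_fit(betas, stab, "TS1").slope == 0.0

    def test_constructed_slope_recovered(self):
        slope = -0.04
        stab = {f"v{i}": 2.0 + 0.5 * i for i in range(8)}
        betas = {
            v: TanfordBetas(0.6 + slope * (s - 4.0), 0.9 + slope * (s - 4.0))
            for v, s in stab.items()
        }
        for ts in ("TS1", "TS2"):
            res = fk.hammond_fit(betas, stab, ts)
            assert res.slope == pytest.approx(slope, abs=1e-12)

    def test_two_variants_rejected(self):
        betas = {"a": TanfordBetas(0.6, 0.9), "b": TanfordBetas(0.5, 0.8)}
        with pytest.raises(DataError):
            fk.hammond_fit(betas, {"a": 3.0, "b": 4.0}, "TS1")

    def test_unknown_ts_rejected(self):
        with pytest.raises(DataError):
            fk.hammond_fit({}, {}, "TS3")


class TestPhiVsPhi:
    def test_identical_phis(self):
        mapping = [(i, 100 + i) for i in range(1, 6)]
        phis = {i: 0.1 * i for i in range(1, 6)}
        phis_b = {100 + i: 0.1 * i for i in range(1, 6)}
        pairs, s = fk.phi_vs_phi(mapping, phis, phis_b)
        assert len(pairs) == 5
        assert s.rms_identity == pytest.approx(0.0, abs=1e-12)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.n_dropped == 0

    def test_constant_offset(self):
        mapping = [(i, i) for i in range(1, 6)]
        phis_a = {i: 0.1 * i for i in range(1, 6)}
        phis_b = {i: 0.1 * i + 0.2 for i in range(1, 6)}
        _, s = fk.phi_vs_phi(mapping, phis_a, phis_b)
        assert s.rms_identity == pytest.approx(0.2, abs=1e-12)
        assert s.mean_offset == pytest.approx(0.2, abs=1e-12)
        assert s.pearson_r == pytest.approx(1.0)

    def test_uncorrelated_phis_match_independent_correlation(self):
        rng = np.random.default_rng(42)
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(0, 1, 20)
        mapping = [(i, i) for i in range(20)]
        _, s = fk.phi_vs_phi(mapping, dict(enumerate(a)), dict(enumerate(b)))
        expected_r = float(np.corrcoef(a, b)[0, 1])  # independent route
        assert s.pearson_r == pytest.approx(expected_r, abs=1e-12)
        assert abs(s.pearson_r) < 0.5

    def test_excluded_positions_dropped_and_counted(self):
        mapping = [(1, 1), (2, 2), (3, 3)]
        _, s = fk.phi_vs_phi(mapping, {1: 0.5, 2: None, 3: 0.7}, {1: 0.4, 2: 0.5, 3: None})
        assert s.n_pairs == 1
        assert s.n_dropped == 2

    def test_empty_retained_set_rejected(self):
        with pytest.raises(DataError):
            fk.phi_vs_phi([(1, 1)], {1: None}, {1: 0.5})

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = dict(enumerate(rng.uniform(0, 1, 10)))
        b = dict(enumerate(rng.uniform(0, 1, 10)))
        mapping = [(i, i) for i in range(10)]
        _, s_ab = fk.phi_vs_phi(mapping, a, b)
        _, s_ba = fk.phi_vs_phi(mapping, b, a)
        assert s_ab.rms_identity == pytest.approx(s_ba.rms_identity, abs=1e-12)
        assert s_ab.pearson_r == pytest.approx(s_ba.pearson_r, abs=1e-12)
        assert s_ab.mean_offset == pytest.approx(-s_ba.mean_offset, abs=1e-12)
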
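"""Oxygen modification factor and LQ survival under oxygen heterogeneity."""

import numpy as np
import pytest

from oxymap import GridGeometry, SynthParams, generate_domain, solve_to_stationary_hypoxia
from oxymap.radiation import (
    RadiosensitivityParams,
    omf,
    po2_from_field,
    po2_histogram,
    scenario_curves,
    survival,
    survival_normoxic,
    weighted_survival,
)

P = RadiosensitivityParams()


class TestOmf:
    def test_anoxic_floor_is_reciprocal_oer(self):
        assert omf(0.0) == pytest.approx(1.0 / 3.0)

    def test_half_saturation_at_km(self):
        # (3*3 + 3) / (3 * (3 + 3)) = 12/18 = 2/3
        assert omf(3.0) == pytest.approx(2.0 / 3.0)

    def test_asymptote(self):
        assert omf(1e6) == pytest.approx(1.0, abs=1e-5)

    def test_strictly_increasing_and_bounded(self):
        po2 = np.linspace(0.0, 200.0, 2000)
        vals = omf(po2)
        assert (np.diff(vals) > 0).all()
        assert vals[0] == pytest.approx(1 / 3)
        assert (vals < 1.0).all() and (vals >= 1 / 3).all()

    def test_negative_po2_rejected(self):
        with pytest.raises(ValueError):
            omf(-1.0)


class TestSurvival:
    def test_normoxic_2gy_rounds_to_48_percent(self):
        """alpha=0.3, beta=0.03, OMF=1, D=2 Gy -> exp(-0.72) = 0.4868."""
        sf = survival_normoxic(2.0)
        assert sf == pytest.approx(np.exp(-0.72), abs=1e-12)
        assert int(100 * sf) == 48

    def test_zero_dose_survives_fully(self):
        for po2 in (0.0, 3.0, 60.0):
            assert survival(0.0, po2) == 1.0

    def test_anoxic_2gy_by_independent_substitution(self):
        """Second computation path: scalar arithmetic on the formulas."""
        o = (1 / 3) * (3 * 0 + 3) / (0 + 3)
        eff = o * 2.0
        expected = np.exp(-0.3 * eff - 0.03 * eff**2)
        assert survival(2.0, 0.0) == pytest.approx(expected, abs=1e-15)

    def test_sixty_mmhg_2gy_by_independent_substitution(self):
        o = (3 * 60 + 3) / (3 * (60 + 3))
        eff = o * 2.0
        expected = np.exp(-0.3 * eff - 0.03 * eff**2)
        assert survival(2.0, 60.0) == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(0.49984, abs=5e-5)

    def test_strictly_decreasing_in_dose(self):
        doses = np.linspace(0.0, 12.0, 100)
        for po2 in (0.0, 5.0, 60.0):
            sf = survival(doses, po2)
            assert (np.diff(sf) < 0).all()

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            survival(-1.0, 5.0)


class TestWeightedSurvival:
    def test_uniform_profile_collapses_to_scalar(self):
        assert weighted_survival(np.full(50, 7.0), 3.0) == pytest.approx(
            survival(3.0, 7.0), abs=1e-15
        )

    def test_two_cell_average(self):
        lo, hi = survival(4.0, 0.0), survival(4.0, 1e9)
        assert weighted_survival([0.0, 1e9], 4.0) == pytest.approx((lo + hi) / 2)

    def test_matches_brute_force_cell_loop(self):
        rng = np.random.default_rng(0)
        po2 = rng.exponential(10.0, 80 * 80)
        w = rng.integers(1, 4, po2.size).astype(float)
        got = weighted_survival(po2, 5.0, weights=w)
        expected = sum(wi * survival(5.0, p) for wi, p in zip(w, po2)) / w.sum()
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_weight_sum_rejected(self):
        with pytest.raises(ValueError):
            weighted_survival([1.0, 2.0], 2.0, weights=[0.0, 0.0])


class TestHistogram:
    def test_uniform_field_fills_last_bin(self):
        K = np.ones((10, 10))
        counts, edges = po2_histogram(K, np.ones((10, 10), bool))
        assert counts[-1] == 100 and counts[:-1].sum() == 0
        assert edges[0] == 0.0 and edges[-1] == 100.0 and len(counts) == 20

    def test_counts_partition_tumor(self):
        rng = np.random.default_rng(1)
        K = rng.random((30, 30))
        tumor = rng.random((30, 30)) < 0.6
        tumor[0, 0] = True
        counts, _ = po2_histogram(K, tumor)
        assert counts.sum() == tumor.sum()

    def test_relative_cut_maps_into_low_bins(self):
        """Cells below 5% of max land in the [0, 5] mm Hg region."""
        K = np.concatenate([np.full(50, 0.03), np.full(50, 1.0)]).reshape(10, 10)
        counts, _ = po2_histogram(K, np.ones((10, 10), bool))
        assert counts[0] >= 50


@pytest.fixture(scope="module")
def sparse_field():
    """A sparsely vascularized tumor: most cells severely hypoxic."""
    geom = GridGeometry()
    dom = generate_domain(
        SynthParams(n_vessels=6, perfused_fraction=0.5, seed=3), geom
    )
    res = solve_to_stationary_hypoxia(dom, threshold_pct=10.0)
    return dom, res.K


class TestScenarios:
    def test_all_curves_strictly_decreasing(self, sparse_field):
        dom, K = sparse_field
        doses = np.arange(0.5, 10.5, 0.5)
        sc = scenario_curves(K, dom.tumor_mask, doses)
        for col in sc.columns:
            assert (np.diff(sc[col]) < 0).all(), col

    def test_normoxic_limit_bounds_every_scenario(self, sparse_field):
        """OMF <= 1, so the fully oxygenated LQ survival is the minimum."""
        dom, K = sparse_field
        doses = np.arange(1.0, 10.5, 1.0)
        sc = scenario_curves(K, dom.tumor_mask, doses)
        floor = survival_normoxic(doses)
        for col in sc.columns:
            assert (sc[col].to_numpy() >= floor - 1e-12).all(), col

    def test_heterogeneous_closest_to_anoxia(self, sparse_field):
        """On a severely hypoxic field the per-cell curve needs the highest
        dose of all non-anoxic scenarios and hugs the anoxia curve from
        below."""
        dom, K = sparse_field
        po2 = po2_from_field(K)[dom.tumor_mask]
        assert (po2 < 5.0).mean() > 0.6  # severely hypoxic field
        doses = np.arange(1.0, 10.5, 1.0)
        sc = scenario_curves(K, dom.tumor_mask, doses)
        het, anox = sc["heterogeneous"], sc["anoxic"]
        others = [c for c in sc.columns if c not in ("heterogeneous", "anoxic")]
        for col in others:
            assert (het.to_numpy() >= sc[col].to_numpy()).all(), col
        assert (het.to_numpy() <= anox.to_numpy()).all()
        # closest neighbor in log-survival space is the anoxia curve
        gap_anox = np.abs(np.log(het) - np.log(anox))
        for col in others:
            assert (gap_anox <= np.abs(np.log(het) - np.log(sc[col]))).all(), col

    def test_histogram_close_to_heterogeneous(self, sparse_field):
        """5 mm Hg binning compresses the map with bounded discretization
        error: the brute-force per-cell bound computed on the same map."""
        dom, K = sparse_field
        po2 = po2_from_field(K)[dom.tumor_mask]
        d = 4.0
        sc = scenario_curves(K, dom.tumor_mask, [d])
        # brute-force bound: assign every cell the survival extremes of its bin
        bins = np.clip((po2 // 5).astype(int), 0, 19)
        lo_edges, hi_edges = bins * 5.0, bins * 5.0 + 5.0
        sf_hi = np.mean([survival(d, p) for p in lo_edges])  # lower pO2 -> higher SF
        sf_lo = np.mean([survival(d, p) for p in hi_edges])
        assert sf_lo - 1e-12 <= sc["histogram"].iloc[0] <= sf_hi + 1e-12
        assert sf_lo - 1e-12 <= sc["heterogeneous"].iloc[0] <= sf_hi + 1e-12

    def test_scenario_a_value_at_2gy(self, sparse_field):
        dom, K = sparse_field
        sc = scenario_curves(K, dom.tumor_mask, [2.0])
        assert sc["normoxic"].iloc[0] == pytest.approx(0.49984, abs=5e-5)

    def test_empty_dose_grid_rejected(self, sparse_field):
        dom, K = sparse_field
        with pytest.raises(ValueError):
            scenario_curves(K, dom.tumor_mask, [])


class TestParams:
    @pytest.mark.parametrize("kwargs", [dict(alpha=-1), dict(oer_m=0.5), dict(k_m=0.0)])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RadiosensitivityParams(**kwargs)
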
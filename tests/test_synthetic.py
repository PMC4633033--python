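"""Synthetic cohort generator: distributions, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest

from bmiconn import functional
from bmiconn.errors import InvalidSpecError
from bmiconn.structural import build_structural_matrix
from bmiconn.synthetic import (
    SyntheticSpec,
    default_spec,
    generate_cohort,
    make_atlas,
    noise_sd_for_signal_fraction,
    simulate_bmi,
    simulate_feature_cohort,
    simulate_fibers,
    simulate_timeseries,
)

from conftest import powered_spec


class TestMakeAtlas:
    def test_full_size_unique_ids(self):
        atlas = make_atlas(116, seed=0)
        assert atlas.n_regions == 116
        assert len({r.id for r in atlas.regions}) == 116
        assert np.all(atlas.surface_areas > 0)

    def test_deterministic_under_seed(self):
        a = make_atlas(4, seed=7)
        b = make_atlas(4, seed=7)
        assert a == b

    def test_configured_reward_count(self):
        atlas = make_atlas(10, seed=0, n_reward=4)
        assert int(atlas.reward_flags.sum()) == 4

    def test_too_small_rejected(self):
        with pytest.raises(InvalidSpecError):
            make_atlas(3, seed=0)


class TestSimulateFibers:
    def test_full_sparsity_empty(self):
        atlas = make_atlas(6, seed=0)
        spec = SyntheticSpec(n_regions=6, edge_sparsity=1.0, seed=0)
        assert len(simulate_fibers(atlas, spec, 0.0, seed=1)) == 0

    def test_lengths_within_cutoff(self):
        atlas = make_atlas(8, seed=0)
        spec = SyntheticSpec(n_regions=8, edge_sparsity=0.0, seed=0)
        fs = simulate_fibers(atlas, spec, 0.0, seed=1)
        assert fs.length_mm.min() >= 20.0
        assert fs.length_mm.max() <= 500.0

    def test_mean_length_near_target(self):
        atlas = make_atlas(20, seed=0)
        spec = SyntheticSpec(n_regions=20, edge_sparsity=0.0, mean_fibers_per_edge=60, seed=0)
        fs = simulate_fibers(atlas, spec, 0.0, seed=2)
        assert len(fs) >= 10_000
        assert fs.length_mm.mean() == pytest.approx(26.2, abs=1.0)

    def test_deterministic_under_seed(self):
        atlas = make_atlas(6, seed=0)
        spec = SyntheticSpec(n_regions=6, seed=0)
        a = simulate_fibers(atlas, spec, 1.0, seed=3)
        b = simulate_fibers(atlas, spec, 1.0, seed=3)
        assert np.array_equal(a.length_mm, b.length_mm)
        assert np.array_equal(a.region_u, b.region_u)

    def test_planted_effect_recovered(self):
        """Empirical Cohen's d of fiber density near the planted value."""
        atlas = make_atlas(6, seed=0)
        spec = SyntheticSpec(
            n_regions=6, edge_sparsity=0.0, planted_edges=[(0, 1, 1.2)], seed=0
        )
        ds = []
        for rep in range(10):
            hw, nhw = [], []
            for i in range(60):
                f0 = simulate_fibers(atlas, spec, 0.0, seed=10_000 + rep * 200 + i)
                f1 = simulate_fibers(atlas, spec, 1.0, seed=50_000 + rep * 200 + i)
                hw.append(build_structural_matrix(f0, atlas).density[0, 1])
                nhw.append(build_structural_matrix(f1, atlas).density[0, 1])
            a, b = np.array(hw), np.array(nhw)
            sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            ds.append((b.mean() - a.mean()) / sp)
        assert abs(np.mean(ds) - 1.2) < 0.35


class TestSimulateTimeseries:
    def _edge_values(self, n_subj, rng, edge=(0, 1)):
        return pd.DataFrame(
            {edge: rng.standard_normal(n_subj)}, index=[f"s{i}" for i in range(n_subj)]
        )

    def test_deterministic_under_seed(self, rng):
        atlas = make_atlas(5, seed=0)
        spec = SyntheticSpec(n_regions=5, n_timepoints=128, seed=0)
        df = self._edge_values(3, rng)
        a = simulate_timeseries(atlas, spec, df, seed=4)
        b = simulate_timeseries(atlas, spec, df, seed=4)
        for sid in a:
            assert np.array_equal(a[sid].values, b[sid].values)

    def test_power_concentrated_in_band(self, rng):
        atlas = make_atlas(5, seed=0)
        spec = SyntheticSpec(n_regions=5, n_timepoints=600, seed=0)
        ts = simulate_timeseries(atlas, spec, self._edge_values(1, rng), seed=5)["s0"]
        spec_power = np.abs(np.fft.rfft(ts.values - ts.values.mean(0), axis=0)) ** 2
        freqs = np.fft.rfftfreq(600, d=spec.sampling_interval)
        band = (freqs >= 0.009) & (freqs <= 0.08)
        assert spec_power[band].sum() / spec_power[freqs > 0].sum() >= 0.90

    def test_no_coupling_no_correlation(self, rng):
        atlas = make_atlas(6, seed=0)
        spec = SyntheticSpec(n_regions=6, n_timepoints=200, seed=0)
        n = 150
        df = self._edge_values(n, rng)
        series = simulate_timeseries(atlas, spec, df, seed=6)
        mfc = np.array(
            [functional.correlation_matrix(series[f"s{i}"]).mean_fc[0] for i in range(n)]
        )
        assert abs(np.corrcoef(mfc, df[(0, 1)])[0, 1]) < 3.0 / np.sqrt(n)

    def test_planted_coupling_near_target(self):
        """Across-subject density/mean-FC correlation lands near target_r."""
        rng = np.random.default_rng(11)
        atlas = make_atlas(16, seed=0)
        spec = SyntheticSpec(
            n_regions=16,
            n_timepoints=512,
            coupling_edges=[((0, 1), 0, 0.45)],
            seed=0,
        )
        n = 120
        rs = []
        for rep in range(30):
            df = self._edge_values(n, rng)
            series = simulate_timeseries(atlas, spec, df, seed=700 + rep)
            mfc = np.array(
                [functional.correlation_matrix(series[f"s{i}"]).mean_fc[0] for i in range(n)]
            )
            rs.append(np.corrcoef(mfc, df[(0, 1)])[0, 1])
        assert abs(np.mean(rs) - 0.45) < 0.15


class TestSimulateBmi:
    def test_noiseless_single_driver_monotone(self, rng):
        feats = pd.DataFrame({"x": rng.standard_normal(400)})
        spec = SyntheticSpec(bmi_driver_features=[("x", 1.0)], noise_sd=0.0, seed=0)
        bmi, groups = simulate_bmi(feats, spec, seed=0)
        order = np.argsort(feats["x"].to_numpy())
        assert np.all(np.diff(bmi.to_numpy()[order]) >= 0)
        for g in ("HW", "nonHW"):
            sub = groups == g
            r = np.corrcoef(bmi[sub], feats["x"][sub])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_group_means_match_study(self, rng):
        feats = pd.DataFrame({"x": rng.standard_normal(120)})
        spec = SyntheticSpec(bmi_driver_features=[("x", 1.0)], seed=0)
        bmi, groups = simulate_bmi(feats, spec, seed=1)
        assert bmi[groups == "HW"].mean() == pytest.approx(22.53, abs=0.5)
        assert bmi[groups == "nonHW"].mean() == pytest.approx(32.55, abs=0.5)

    def test_boundary_rule_exact(self, rng):
        feats = pd.DataFrame({"x": rng.standard_normal(200)})
        spec = SyntheticSpec(bmi_driver_features=[("x", 1.0)], noise_sd=1.5, seed=0)
        bmi, groups = simulate_bmi(feats, spec, seed=2)
        assert np.array_equal(groups == "HW", bmi < 25.0)

    def test_signal_fraction_yields_matching_r2(self, rng):
        feats = pd.DataFrame({"x": rng.standard_normal(10_000)})
        spec = SyntheticSpec(
            bmi_driver_features=[("x", 1.0)],
            noise_sd=noise_sd_for_signal_fraction(0.57),
            seed=0,
        )
        bmi, _ = simulate_bmi(feats, spec, seed=3)
        r2 = np.corrcoef(bmi, feats["x"])[0, 1] ** 2
        assert r2 == pytest.approx(0.57, abs=0.05)

    def test_unknown_driver_rejected(self, rng):
        feats = pd.DataFrame({"x": rng.standard_normal(10)})
        spec = SyntheticSpec(bmi_driver_features=[("zz", 1.0)], seed=0)
        with pytest.raises(InvalidSpecError):
            simulate_bmi(feats, spec, seed=0)


class TestGenerateCohort:
    def test_smoke_minimal_instance(self):
        spec = SyntheticSpec(n_per_group=2, n_regions=6, n_timepoints=64, seed=0)
        cohort = generate_cohort(spec)
        assert len(cohort.subjects) == 4

    def test_subject_count_at_study_scale(self):
        spec = powered_spec(seed=1, n_per_group=4)
        cohort = generate_cohort(spec)
        assert len(cohort.subjects) == 8
        assert sum(s.group == "HW" for s in cohort.subjects) == 4

    def test_deterministic_under_seed(self):
        spec = powered_spec(seed=5, n_per_group=3)
        a, b = generate_cohort(spec), generate_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.bmi == sb.bmi
            assert np.array_equal(sa.fiber_set.length_mm, sb.fiber_set.length_mm)
            assert np.array_equal(sa.roi_timeseries.values, sb.roi_timeseries.values)

    def test_group_labels_respect_bmi_rule(self):
        spec = powered_spec(seed=2, n_per_group=5)
        cohort = generate_cohort(spec)
        for s in cohort.subjects:
            assert (s.group == "HW") == (s.bmi < 25.0)

    def test_default_spec_validates(self):
        spec = default_spec(seed=0)
        spec.validate()
        assert spec.n_per_group == 60
        assert spec.n_regions == 116


def test_feature_cohort_shapes_and_groups():
    X, y, groups = simulate_feature_cohort(60, 0.5, seed=0)
    assert X.shape == (60, 16)
    assert set(groups) == {"HW", "nonHW"}
    assert np.array_equal(groups == "HW", y < 25.0)
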
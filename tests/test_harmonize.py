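"""Cross-study harmonization: filtering, averaging, affine rescaling, merging."""

import numpy as np
import pandas as pd
import pytest

import crisprboost as cb
from crisprboost.harmonize import DegenerateFitError, find_overlap


def _ds(seqs, effs, reads=None, tag="t"):
    frame = pd.DataFrame({"sequence30": seqs, "efficiency": effs})
    if reads is not None:
        frame["reads"] = reads
    return cb.EfficiencyDataset(frame, tag)


S = [f"g{i}" for i in range(10)]  # guide keys; harmonization never parses them


class TestFilterMinReads:
    def test_boundary_is_inclusive(self):
        ds = _ds(S[:3], [1, 2, 3], reads=[199, 200, 201])
        kept = cb.filter_min_reads(ds, 200)
        assert len(kept) == 2
        assert set(kept.frame.reads) == {200, 201}

    def test_threshold_zero_is_identity(self):
        ds = _ds(S[:3], [1, 2, 3], reads=[0, 5, 10])
        assert len(cb.filter_min_reads(ds, 0)) == 3

    def test_empty_dataset_passes_through(self):
        ds = _ds([], [], reads=[])
        assert len(cb.filter_min_reads(ds, 200)) == 0

    def test_missing_reads_is_schema_error(self):
        with pytest.raises(ValueError, match="read counts"):
            cb.filter_min_reads(_ds(S[:2], [1, 2]), 200)


class TestAverageReplicates:
    def test_intersection_mean(self):
        a = _ds(["g1", "g2"], [10, 5])
        b = _ds(["g1", "g3"], [20, 7])
        out = cb.average_replicates(a, b)
        assert len(out) == 1
        assert out.frame.efficiency.iloc[0] == 15

    def test_disjoint_gives_empty(self):
        assert len(cb.average_replicates(_ds(["g1"], [1]), _ds(["g2"], [2]))) == 0

    def test_self_average_is_identity(self):
        a = _ds(S[:4], [1.0, 2.0, 3.0, 4.0])
        out = cb.average_replicates(a, a)
        merged = out.frame.sort_values("sequence30")
        assert np.allclose(merged.efficiency, [1, 2, 3, 4])


class TestFitNormalization:
    def test_collinear_points_fit_exactly(self):
        m = cb.fit_normalization([10, 20, 30], [20, 40, 60])
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.slope == pytest.approx(2.0)
        assert m.n_overlap == 3

    def test_identity_data(self):
        m = cb.fit_normalization([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert (m.intercept, m.slope) == (pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))

    def test_parameter_recovery_on_noisy_pairs(self, rng):
        src = rng.uniform(0, 100, 500)
        ref = 5 + 0.8 * src + rng.normal(0, 2, 500)
        m = cb.fit_normalization(src, ref)
        assert m.slope == pytest.approx(0.8, abs=0.05)
        assert m.residual_sd == pytest.approx(2.0, rel=0.2)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            cb.fit_normalization([1.0], [2.0])
        with pytest.raises(DegenerateFitError):
            cb.fit_normalization([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestApplyNormalization:
    def test_identity_and_doubling(self):
        ds = _ds(S[:3], [1.0, 2.0, 3.0])
        ident = cb.NormalizationModel(0.0, 1.0, 5, 0.0)
        assert np.allclose(cb.apply_normalization(ds, ident).frame.efficiency, [1, 2, 3])
        double = cb.NormalizationModel(0.0, 2.0, 5, 0.0)
        assert np.allclose(cb.apply_normalization(ds, double).frame.efficiency, [2, 4, 6])

    def test_affine_round_trip(self):
        ds = _ds(S[:3], [10.0, 20.0, 30.0])
        fwd = cb.NormalizationModel(3.0, 1.7, 5, 0.0)
        inv = cb.NormalizationModel(-3.0 / 1.7, 1.0 / 1.7, 5, 0.0)
        back = cb.apply_normalization(cb.apply_normalization(ds, fwd), inv)
        assert np.allclose(back.frame.efficiency, ds.frame.efficiency, atol=1e-9)

    def test_positive_affine_preserves_spearman(self, rng):
        eff = rng.uniform(0, 100, 50)
        cov = rng.normal(size=50)
        ds = _ds([f"g{i}" for i in range(50)], eff)
        out = cb.apply_normalization(ds, cb.NormalizationModel(7.0, 2.5, 5, 0.0))
        assert cb.spearman(ds.frame.efficiency, cov) == pytest.approx(
            cb.spearman(out.frame.efficiency, cov)
        )


class TestMergeAverageDuplicates:
    def test_shared_guides_are_averaged(self):
        a = _ds(["g1", "g2"], [30.0, 1.0])
        b = _ds(["g1", "g3"], [50.0, 2.0])
        out = cb.merge_average_duplicates([a, b])
        eff = dict(zip(out.frame.sequence30, out.frame.efficiency))
        assert eff == {"g1": 40.0, "g2": 1.0, "g3": 2.0}

    def test_two_copies_identity(self):
        a = _ds(S[:3], [1.0, 2.0, 3.0])
        out = cb.merge_average_duplicates([a, a])
        assert np.allclose(np.sort(out.frame.efficiency), [1, 2, 3])

    def test_order_invariance(self, rng):
        parts = [
            _ds([f"g{i}" for i in rng.integers(0, 20, 8)], rng.uniform(0, 100, 8))
            for _ in range(3)
        ]
        # duplicate keys inside one part are pre-averaged by groupby
        out1 = cb.merge_average_duplicates(parts)
        out2 = cb.merge_average_duplicates(parts[::-1])
        pd.testing.assert_frame_equal(out1.frame, out2.frame)


class TestBuildTrainingSet:
    def test_synthetic_paired_screens_recover_planted_structure(self):
        # all reads above the filter, so the planted overlap survives intact
        cfg = cb.GeneratorConfig(
            n_guides=600, overlap=49, noise_sd=5.0, low_read_fraction=0.0, seed=9
        )
        screen_a, day8, day10, truth = cb.simulate_paired_screens(cfg)
        combined, model, report = cb.build_training_set(
            screen_a, cb.EfficiencyDataset(screen_a.frame.iloc[:0].copy(), "empty"),
            day8, day10,
        )
        assert report["n_overlap"] == 49
        # rescaling the second screen's scores back to screen A's scale
        # inverts the planted affine map: slope ~ 1/b, intercept ~ -a/b
        # (noise on the source side attenuates the slope slightly)
        assert model.slope == pytest.approx(1 / cfg.affine_b, rel=0.2)
        assert model.intercept == pytest.approx(-cfg.affine_a / cfg.affine_b, abs=8.0)
        assert report["n_combined_unique"] <= len(screen_a) + report["n_screenB_unique"]

    def test_disjoint_screens_raise_degenerate_fit(self):
        a = _ds(["g1", "g2", "g3"], [1.0, 2.0, 3.0])
        empty = cb.EfficiencyDataset(a.frame.iloc[:0].copy(), "empty")
        b8 = _ds(["h1", "h2"], [1.0, 2.0], reads=[500, 500])
        b10 = _ds(["h1", "h2"], [2.0, 3.0], reads=[500, 500])
        with pytest.raises(DegenerateFitError):
            cb.build_training_set(a, empty, b8, b10)

    def test_overlap_matches_planted_keys(self):
        cfg = cb.GeneratorConfig(n_guides=200, overlap=17, noise_sd=1.0, seed=4)
        screen_a, day8, _, truth = cb.simulate_paired_screens(cfg)
        shared = find_overlap(screen_a, day8)
        assert set(shared.sequence30) == truth["overlap_sequences"]
        assert len(shared) == 17

    def test_affine_recovery_within_ols_confidence_interval(self):
        import statsmodels.api as sm

        hits = 0
        for seed in range(40):
            # low noise keeps errors-in-variables attenuation negligible,
            # so the OLS CI is an honest interval for the planted 1/b
            cfg = cb.GeneratorConfig(n_guides=300, overlap=60, noise_sd=0.5, seed=seed)
            screen_a, day8, day10, truth = cb.simulate_paired_screens(cfg)
            empty = cb.EfficiencyDataset(screen_a.frame.iloc[:0].copy(), "empty")
            _, model, _ = cb.build_training_set(screen_a, empty, day8, day10)
            # true inverse-link slope
            overlap = find_overlap(
                cb.average_replicates(day8, day10), screen_a
            )
            ols = sm.OLS(
                overlap["efficiency_b"], sm.add_constant(overlap["efficiency_a"])
            ).fit()
            lo, hi = ols.conf_int().iloc[1]
            hits += lo <= 1 / cfg.affine_b <= hi
        assert hits >= 36  # >= 90% coverage over seeded replicates
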
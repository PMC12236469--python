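"""Illumination/bleed-through correction, EMD, aggregation, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from opscreen import profiles as pf
from opscreen.simulate import FeatureTableTruth, make_feature_table


class TestIllumination:
    def test_identical_fields_zeroed(self):
        f = np.tile(np.random.default_rng(0).random((1, 16, 16)), (20, 1, 1))
        np.testing.assert_allclose(pf.illumination_correct(f), 0.0, atol=1e-12)

    def test_bright_field_retains_signal(self):
        rng = np.random.default_rng(1)
        dark = rng.random((19, 8, 8)) * 0.01
        bright = dark[0] + 5.0
        fields = np.concatenate([dark, bright[None]])
        out = pf.illumination_correct(fields)
        assert np.abs(out[:19]).max() < 0.02
        assert out[19].mean() > 4.5

    def test_percentile_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        fields = rng.standard_normal((40, 6, 6))
        out = pf.illumination_correct(fields)
        # brute-force per-pixel oracle via explicit sorting + interpolation
        for y in range(6):
            for x in range(6):
                v = np.sort(fields[:, y, x])
                q = np.percentile(v, 5)
                np.testing.assert_allclose(out[:, y, x], fields[:, y, x] - q)

    def test_single_field_warns_identity(self):
        f = np.ones((1, 4, 4))
        with pytest.warns(UserWarning):
            out = pf.illumination_correct(f)
        np.testing.assert_array_equal(out, f)


class TestBleedthrough:
    def test_zero_coefficient_identity(self):
        t = np.random.default_rng(3).random((8, 8))
        np.testing.assert_array_equal(pf.bleedthrough_correct(t, t * 2, 0.0), t)

    def test_exact_cancellation(self):
        s = np.random.default_rng(4).random((8, 8))
        np.testing.assert_allclose(pf.bleedthrough_correct(0.3 * s, s, 0.3), 0.0,
                                   atol=1e-12)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            pf.bleedthrough_correct(np.ones((2, 2)), np.ones((2, 2)), -0.1)

    def test_estimated_coefficient_recovers_planted(self):
        rng = np.random.default_rng(5)
        source = rng.exponential(1.0, (128, 128))
        source[rng.random((128, 128)) < 0.02] += 30.0  # bright bleed donors
        target = 0.3 * source + 0.05 * rng.standard_normal((128, 128))
        est = pf.estimate_bleedthrough(target, source)
        assert abs(est - 0.3) < 0.02


class TestEmd:
    def test_identical_zero(self):
        a = np.arange(10.0)
        assert pf.emd_1d(a, a) == 0.0

    def test_point_masses(self):
        assert pf.emd_1d([0.0], [1.0]) == pytest.approx(1.0)

    def test_equal_size_sorted_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = rng.integers(2, 200)
            a, b = rng.standard_normal((2, n))
            oracle = np.mean(np.abs(np.sort(a) - np.sort(b)))
            assert pf.emd_1d(a, b) == pytest.approx(oracle, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pf.emd_1d([], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.integers(0, 2 ** 31 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (rng.standard_normal(rng.integers(2, 30)) for _ in range(3))
        dab, dba = pf.emd_1d(a, b), pf.emd_1d(b, a)
        assert dab == pytest.approx(dba, abs=1e-12)          # symmetry
        assert pf.emd_1d(a, c) <= dab + pf.emd_1d(b, c) + 1e-9  # triangle


class TestAggregation:
    def test_planted_shift_in_median_and_emd(self):
        eff = np.zeros((2, 2))
        eff[1, 0] = 5.0
        truth = FeatureTableTruth(n_variants=2, n_features=2, n_synonymous=1,
                                  cells_per_variant=4000, n_wt_cells=4000,
                                  effect_matrix=eff, seed=7)
        table = make_feature_table(truth)
        prof = pf.aggregate_variants(table, ["f000", "f001"])
        wt_med = prof.loc["WT", "median_f000"]
        wt = table[table["variant"] == "WT"]["f000"]
        sd = wt.std()
        # W1 of equal-variance Gaussians with means shifted by d equals d
        assert prof.loc["var_0", "median_f000"] - wt_med == pytest.approx(5 * sd, rel=0.05)
        assert prof.loc["var_0", "emd_f000"] == pytest.approx(5 * sd, rel=0.05)
        assert prof.loc["syn_0", "emd_f000"] < 0.1 * sd

    def test_pure_dispersion_gaussian_closed_form(self):
        disp = np.ones((1, 1)) * 3.0
        truth = FeatureTableTruth(n_variants=1, n_features=1, n_synonymous=0,
                                  cells_per_variant=20000, n_wt_cells=20000,
                                  dispersion_matrix=disp, seed=8)
        table = make_feature_table(truth)
        wt = table[table["variant"] == "WT"]["f000"]
        sd = wt.std()
        prof = pf.aggregate_variants(table, ["f000"])
        # W1 of two centred Gaussians: |s1 - s2| * sqrt(2/pi)
        expect = (3 - 1) * sd * np.sqrt(2 / np.pi)
        assert prof.loc["var_0", "emd_f000"] == pytest.approx(expect, rel=0.05)
        assert abs(prof.loc["var_0", "median_f000"] - prof.loc["WT", "median_f000"]) < 0.1 * sd

    def test_missing_wt_rejected(self):
        df = pd.DataFrame({"variant": ["a"], "f0": [1.0]})
        with pytest.raises(ValueError):
            pf.aggregate_variants(df, ["f0"])


class TestEmdReproducibilityFilter:
    def test_unstable_feature_scores_highest(self):
        rng = np.random.default_rng(9)
        n = 400
        data = {f"f{i}": rng.standard_normal(n) for i in range(10)}
        rare = rng.standard_normal(n)
        rare[:6] += 40.0           # rare mode makes half-split EMD unstable
        data["f_unstable"] = rng.permutation(rare)
        wt = pd.DataFrame(data)
        kept, scores = pf.emd_reproducibility_filter(wt, list(data), seed=1)
        assert scores.idxmax() == "f_unstable"
        assert "f_unstable" not in kept

    def test_iid_gaussian_removal_small_and_stable(self):
        rng = np.random.default_rng(10)
        wt = pd.DataFrame(rng.standard_normal((500, 30)),
                          columns=[f"f{i}" for i in range(30)])
        fractions = []
        for seed in range(3):
            kept, _ = pf.emd_reproducibility_filter(wt, list(wt.columns), seed=seed)
            fractions.append(1 - len(kept) / 30)
        assert max(fractions) < 0.35

    def test_zero_mad_feature_removed(self):
        wt = pd.DataFrame({"good": np.random.default_rng(11).standard_normal(200),
                           "flat": np.ones(200)})
        with pytest.warns(UserWarning, match="zero-MAD"):
            kept, _ = pf.emd_reproducibility_filter(wt, ["good", "flat"], seed=0)
        assert kept == ["good"]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        wt = pd.DataFrame(rng.standard_normal((300, 12)),
                          columns=[f"f{i}" for i in range(12)])
        k1, s1 = pf.emd_reproducibility_filter(wt, list(wt.columns), seed=5)
        k2, s2 = pf.emd_reproducibility_filter(wt, list(wt.columns), seed=5)
        assert k1 == k2
        pd.testing.assert_series_equal(s1, s2)


class TestSelection:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal(50)
        prof = pd.DataFrame({"a": base, "b": base.copy(),
                             "c": rng.standard_normal(50)})
        kept = pf.select_features(prof)
        assert sorted(kept) in (["a", "c"], ["b", "c"])

    def test_constant_column_dropped(self):
        prof = pd.DataFrame({"a": np.ones(20),
                             "b": np.random.default_rng(14).standard_normal(20)})
        assert pf.select_features(prof) == ["b"]

    def test_blocklist_patterns(self):
        rng = np.random.default_rng(15)
        prof = pd.DataFrame(rng.standard_normal((30, 3)),
                            columns=["median_Orientation_1", "median_Area",
                                     "emd_Location_Y"])
        kept = pf.select_features(prof)
        assert kept == ["median_Area"]

    def test_surviving_set_obeys_correlation_cap(self):
        rng = np.random.default_rng(16)
        block = rng.standard_normal((60, 1)) + 0.05 * rng.standard_normal((60, 8))
        rest = rng.standard_normal((60, 8))
        prof = pd.DataFrame(np.hstack([block, rest]),
                            columns=[f"f{i}" for i in range(16)])
        cfg = pf.SelectionConfig(correlation_threshold=0.8, blocklist=())
        kept = pf.select_features(prof, cfg)
        corr = prof[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.8 + 1e-12


class TestNormalization:
    def test_mode_all_standardizes(self):
        rng = np.random.default_rng(17)
        prof = pd.DataFrame(rng.standard_normal((40, 4)) * 5 + 3,
                            columns=list("abcd"),
                            index=[f"v{i}" for i in range(40)])
        out = pf.normalize_profiles(prof, mode="all")
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-12)

    def test_synonymous_reference(self):
        rng = np.random.default_rng(18)
        idx = [f"syn_{i}" for i in range(10)] + [f"var_{i}" for i in range(10)]
        data = np.vstack([rng.standard_normal((10, 2)),
                          rng.standard_normal((10, 2)) + 5.0])
        prof = pd.DataFrame(data, columns=["a", "b"], index=idx)
        out = pf.normalize_profiles(prof, mode="synonymous",
                                    synonymous_labels=idx[:10])
        assert abs(out.loc[idx[:10]].mean().mean()) < 1e-9
        assert out.loc[idx[10:]].mean().mean() > 3.0

    def test_constant_column_dropped(self):
        prof = pd.DataFrame({"a": np.ones(5), "b": np.arange(5.0)})
        with pytest.warns(UserWarning, match="zero-SD"):
            out = pf.normalize_profiles(prof, mode="all")
        assert list(out.columns) == ["b"]

    def test_synonymous_needs_two(self):
        prof = pd.DataFrame({"a": np.arange(4.0)}, index=["syn_0", "v1", "v2", "v3"])
        with pytest.raises(ValueError):
            pf.normalize_profiles(prof, mode="synonymous", synonymous_labels=["syn_0"])
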
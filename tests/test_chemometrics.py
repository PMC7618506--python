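import numpy as np
import pandas as pd
import pytest

from pharmatrace import chemometrics as ch
from pharmatrace.chemometrics import FeatureMatrix
from pharmatrace.tables_io import SpectrumSet


def make_spectra(rows, blank_rows=()):
    records = []
    for mid, mz, inten in rows:
        records.append(
            {"measurement_id": mid, "tablet_id": mid.split("-")[0], "group": "G",
             "mz": mz, "intensity": inten, "blank": False}
        )
    for mid, mz, inten in blank_rows:
        records.append(
            {"measurement_id": mid, "tablet_id": "BLK", "group": "BLANK",
             "mz": mz, "intensity": inten, "blank": True}
        )
    return SpectrumSet(pd.DataFrame(records))


def make_features(matrix, groups, features=None):
    arr = np.asarray(matrix, dtype=float)
    mids = [f"m{i + 1}" for i in range(arr.shape[0])]
    cols = features or [100.0 + j for j in range(arr.shape[1])]
    meta = pd.DataFrame(
        {"tablet_id": mids, "group": list(groups)}, index=mids
    )
    return FeatureMatrix(pd.DataFrame(arr, index=mids, columns=cols), meta)


class TestSubtractBackground:
    def test_peak_equal_to_blank_mean_removed(self):
        spectra = make_spectra([("m1", 200.0, 10.0), ("m1", 300.0, 8.0)])
        blanks = make_spectra([], [("b1", 200.001, 10.0)])
        _, blanks = blanks.split_blanks()
        out = ch.subtract_background(spectra, blanks, mz_tol=0.015)
        assert list(out.peaks["mz"]) == [300.0]

    def test_unmatched_peak_unchanged(self):
        spectra = make_spectra([("m1", 200.0, 10.0)])
        blanks = make_spectra([], [("b1", 250.0, 5.0)])
        _, blanks = blanks.split_blanks()
        out = ch.subtract_background(spectra, blanks, mz_tol=0.015)
        assert out.peaks.iloc[0]["intensity"] == 10.0

    def test_no_blanks_rejected(self):
        spectra = make_spectra([("m1", 200.0, 10.0)])
        empty = SpectrumSet(spectra.peaks.iloc[0:0])
        with pytest.raises(ValueError, match="blank"):
            ch.subtract_background(spectra, empty)

    def test_matches_nearest_blank_oracle(self):
        rng = np.random.default_rng(3)
        mz = np.sort(rng.uniform(60, 790, size=40))
        inten = rng.uniform(5, 100, size=40)
        spectra = make_spectra([("m1", m, i) for m, i in zip(mz, inten)])
        bl_mz = np.sort(rng.uniform(60, 790, size=10))
        bl_int = rng.uniform(1, 20, size=10)
        blanks = make_spectra([], [("b1", m, i) for m, i in zip(bl_mz, bl_int)])
        _, blanks = blanks.split_blanks()
        out = ch.subtract_background(spectra, blanks, mz_tol=0.5)
        expected = {}
        for m, i in zip(mz, inten):
            d = np.abs(bl_mz - m)
            j = int(np.argmin(d))
            val = i - bl_int[j] if d[j] <= 0.5 else i
            if val > 0:
                expected[round(m, 6)] = val
        got = {round(m, 6): v for m, v in zip(out.peaks["mz"], out.peaks["intensity"])}
        assert got.keys() == expected.keys()
        for k in expected:
            assert got[k] == pytest.approx(expected[k])


class TestNormalizeRelative:
    def test_base_peak_scaled_to_100(self):
        out = ch.normalize_relative(make_spectra([("m1", 100.0, 10.0), ("m1", 200.0, 5.0)]))
        assert sorted(out.peaks["intensity"]) == [50.0, 100.0]

    def test_single_peak(self):
        out = ch.normalize_relative(make_spectra([("m1", 100.0, 3.0)]))
        assert out.peaks.iloc[0]["intensity"] == 100.0

    def test_scale_invariance(self):
        spectra = make_spectra([("m1", 100.0, 10.0), ("m1", 200.0, 4.0)])
        scaled = SpectrumSet(spectra.peaks.assign(intensity=spectra.peaks["intensity"] * 7))
        a = ch.normalize_relative(spectra).peaks["intensity"]
        b = ch.normalize_relative(scaled).peaks["intensity"]
        assert np.allclose(a, b)


class TestAggregateMasses:
    def test_close_peaks_merge(self):
        out = ch.aggregate_masses(make_spectra([("m1", 100.2, 10.0), ("m1", 100.9, 30.0)]))
        assert len(out) == 1
        merged = out.peaks.iloc[0]
        assert merged["intensity"] == 40.0
        assert merged["mz"] == pytest.approx((100.2 * 10 + 100.9 * 30) / 40)

    def test_distant_peaks_stay_separate(self):
        out = ch.aggregate_masses(make_spectra([("m1", 100.0, 10.0), ("m1", 101.5, 5.0)]))
        assert len(out) == 2

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(7)
        rows = []
        for mid in ("m1", "m2"):
            mz = np.sort(rng.uniform(60, 790, size=50))
            for m, i in zip(mz, rng.uniform(1, 100, size=50)):
                rows.append((mid, m, i))
        spectra = make_spectra(rows)
        out = ch.aggregate_masses(spectra, window=1.0)
        assert out.peaks["intensity"].sum() == pytest.approx(
            spectra.peaks["intensity"].sum()
        )


class TestAlignFeatures:
    def test_within_tolerance_is_one_feature(self):
        spectra = make_spectra([("m1", 200.000, 10.0), ("m2", 200.010, 20.0)])
        fm = ch.align_features(spectra, mz_tol=0.015)
        assert fm.intensities.shape[1] == 1

    def test_distant_masses_are_distinct_features(self):
        spectra = make_spectra([("m1", 200.0, 10.0), ("m2", 200.5, 20.0)])
        fm = ch.align_features(spectra, mz_tol=0.015)
        assert fm.intensities.shape[1] == 2

    def test_peak_count_conserved(self):
        rng = np.random.default_rng(11)
        rows = []
        for mid in ("m1", "m2", "m3"):
            mz = np.sort(rng.uniform(60, 790, size=30))
            for m, i in zip(mz, rng.uniform(1, 100, size=30)):
                rows.append((mid, m + rng.normal(0, 0.003), i))
        spectra = make_spectra(rows)
        fm = ch.align_features(spectra, mz_tol=0.015)
        assert (fm.intensities.to_numpy() > 0).sum() <= 90
        assert fm.intensities.to_numpy().sum() == pytest.approx(
            spectra.peaks["intensity"].sum()
        )

    def test_matches_brute_force_cluster_count(self):
        """Greedy centroid clustering agrees with a transitive-closure oracle
        when clusters are separated by more than the tolerance."""
        rng = np.random.default_rng(13)
        centers = np.sort(rng.uniform(60, 790, size=25))
        rows = []
        for mid in ("m1", "m2"):
            for c in centers:
                rows.append((mid, c + rng.uniform(-0.005, 0.005), rng.uniform(5, 50)))
        spectra = make_spectra(rows)
        fm = ch.align_features(spectra, mz_tol=0.015)
        # oracle: union-find over pairs within tolerance
        allmz = np.sort(spectra.peaks["mz"].to_numpy())
        n_clusters = 1 + int((np.diff(allmz) > 0.015).sum())
        assert fm.intensities.shape[1] == n_clusters


class TestAnovaSelect:
    def test_flat_feature_excluded(self):
        rng = np.random.default_rng(0)
        mat = np.column_stack([
            50 + rng.normal(0, 1, 12),          # flat across groups
            np.r_[80 + rng.normal(0, 2, 6), 20 + rng.normal(0, 2, 6)],  # shifted
        ])
        fm = make_features(mat, ["g1"] * 6 + ["g2"] * 6)
        sel = ch.anova_select(fm, alpha=0.05, min_intensity=10)
        assert fm.intensities.columns[1] in sel
        assert fm.intensities.columns[0] not in sel

    def test_low_intensity_excluded_before_testing(self):
        mat = np.array([[5.0, 90], [5.2, 91], [4.8, 10], [5.1, 11]])
        fm = make_features(mat, ["g1", "g1", "g2", "g2"])
        sel = ch.anova_select(fm, alpha=0.05, min_intensity=10)
        assert fm.intensities.columns[0] not in sel

    def test_planted_shift_power(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(50):
            a = 70 + rng.normal(0, 5, 6)
            b = 20 + rng.normal(0, 5, 6)
            fm = make_features(np.r_[a, b][:, None], ["g1"] * 6 + ["g2"] * 6)
            if fm.intensities.columns[0] in ch.anova_select(fm, alpha=0.05,
                                                            min_intensity=10):
                hits += 1
        assert hits >= 49

    def test_singleton_group_warned(self):
        mat = np.array([[50.0], [60.0], [55.0]])
        fm = make_features(mat, ["g1", "g1", "g2"])
        with pytest.warns(UserWarning, match="one measurement"):
            with pytest.raises(ValueError, match="fewer than 2"):
                ch.anova_select(fm, alpha=0.05, min_intensity=10)


class TestFisherRatio:
    def test_equal_means_rank_last(self):
        rng = np.random.default_rng(1)
        null = rng.normal(50, 5, size=(12, 1))
        shifted = np.r_[80 + rng.normal(0, 2, 6), 20 + rng.normal(0, 2, 6)][:, None]
        fm = make_features(np.hstack([null, shifted]), ["a"] * 6 + ["b"] * 6)
        sel = ch.fisher_ratio_select(fm, ["a"] * 6 + ["b"] * 6, k=1)
        assert sel == [fm.intensities.columns[1]]

    def test_symmetric_under_class_swap(self):
        rng = np.random.default_rng(2)
        fm = make_features(rng.uniform(0, 100, size=(10, 8)), ["a"] * 5 + ["b"] * 5)
        s1 = ch.fisher_ratio_select(fm, ["a"] * 5 + ["b"] * 5, k=8)
        s2 = ch.fisher_ratio_select(fm, ["b"] * 5 + ["a"] * 5, k=8)
        assert s1 == s2

    def test_k_larger_than_feature_count(self):
        rng = np.random.default_rng(3)
        fm = make_features(rng.uniform(10, 90, size=(8, 5)), ["a"] * 4 + ["b"] * 4)
        sel = ch.fisher_ratio_select(fm, ["a"] * 4 + ["b"] * 4, k=95)
        assert len(sel) <= 5

    def test_three_classes_rejected(self):
        fm = make_features(np.ones((6, 2)), ["a", "a", "b", "b", "c", "c"])
        with pytest.raises(ValueError, match="exactly 2"):
            ch.fisher_ratio_select(fm, ["a", "a", "b", "b", "c", "c"])
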
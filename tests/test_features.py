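import numpy as np
import pandas as pd
import pytest

from ecgpain.features import (
    FEATURE_COLUMNS,
    DatasetError,
    NormalizationError,
    assemble_dataset,
    build_feature_table,
    extract_features,
    make_windows,
    normalize_by_baseline,
)
from ecgpain.preprocess import apply_zero_phase, center, design_bandpass
from ecgpain.synth import (
    BeatModel,
    EffectSpec,
    NoiseSpec,
    ProtocolLayout,
    generate_cohort,
    synth_beat_train,
)

FS = 1000.0


class TestMakeWindows:
    @pytest.mark.parametrize("epoch_s,expected", [(300, 57), (120, 21), (20, 1)])
    def test_window_counts(self, epoch_s, expected):
        # floor((L - 20)/5) + 1
        windows = make_windows(0, int(epoch_s * FS), FS)
        assert len(windows) == expected

    def test_step_is_5s(self):
        windows = make_windows(0, 300_000, FS)
        starts = np.array([w[0] for w in windows])
        assert np.all(np.diff(starts) == 5000)

    def test_windows_inside_epoch(self):
        for start, end in make_windows(100, 100 + 123_456, FS):
            assert 100 <= start and end <= 100 + 123_456

    def test_short_epoch_warns_empty(self):
        with pytest.warns(UserWarning):
            assert make_windows(0, 19_999, FS) == []

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            make_windows(0, 100_000, FS, overlap=1.0)


@pytest.fixture(scope="module")
def clean_gt_features(clean_train):
    signal, truth, layout = clean_train
    return signal, truth


class TestExtractFeatures:
    def test_clean_60bpm_window(self, clean_gt_features):
        signal, truth = clean_gt_features
        row = extract_features(truth, (40_000, 60_000), signal)
        assert row["R_peaks"] == 20
        assert row["R_distance"] == pytest.approx(1000.0)

    def test_constant_amplitude_mean(self, clean_gt_features):
        signal, truth = clean_gt_features
        row = extract_features(truth, (40_000, 60_000), signal)
        r = truth.fiducials["R_peak"]
        in_win = r[(r >= 40_000) & (r < 60_000)]
        assert row["R_amplitude"] == pytest.approx(signal[in_win].mean())

    def test_peak_counts_agree_across_waves(self, clean_gt_features):
        signal, truth = clean_gt_features
        row = extract_features(truth, (40_000, 60_000), signal)
        assert (row["P_peaks"] == row["R_peaks"] == row["S_peaks"]
                == row["T_peaks"])

    def test_all_21_features_present(self, clean_gt_features):
        signal, truth = clean_gt_features
        row = extract_features(truth, (40_000, 60_000), signal)
        assert set(FEATURE_COLUMNS) <= set(row)
        assert len(FEATURE_COLUMNS) == 21

    def test_sparse_window_flags_distance_nan(self, clean_gt_features):
        signal, truth = clean_gt_features
        # a window holding at most one beat cannot define distances
        r0 = int(truth.fiducials["R_peak"][0])
        row = extract_features(truth, (r0 - 100, r0 + 100), signal)
        assert np.isnan(row["R_distance"])

    def test_brute_force_oracle(self, clean_gt_features):
        """Direct per-event recount, independent of the vectorized path."""
        signal, truth = clean_gt_features
        window = (100_000, 120_000)
        row = extract_features(truth, window, signal)

        def events(key):
            return [int(v) for v in truth.fiducials[key]
                    if window[0] <= v < window[1]]

        for w in ("P", "R", "S", "T"):
            peaks = events(f"{w}_peak")
            assert row[f"{w}_peaks"] == len(peaks)
            assert row[f"{w}_amplitude"] == pytest.approx(
                sum(signal[i] for i in peaks) / len(peaks))
            gaps = [b - a for a, b in zip(peaks, peaks[1:])]
            assert row[f"{w}_distance"] == pytest.approx(sum(gaps) / len(gaps))
        for w in ("P", "R", "T"):
            onsets = events(f"{w}_onset")
            offsets = events(f"{w}_offset")
            assert row[f"{w}_onsetamp"] == pytest.approx(
                sum(signal[i] for i in onsets) / len(onsets))
            assert row[f"{w}_offsetamp"] == pytest.approx(
                sum(signal[i] for i in offsets) / len(offsets))
            pairs = [
                (on, off)
                for on, off in zip(truth.fiducials[f"{w}_onset"],
                                   truth.fiducials[f"{w}_offset"])
                if window[0] <= on < window[1] and window[0] <= off < window[1]
            ]
            widths = [off - on for on, off in pairs]
            assert row[f"{w}_onoffdist"] == pytest.approx(
                sum(widths) / len(widths))


def _one_recording_table(effect=None, seed=0, cpt_s=120.0, filtered=True):
    layout = ProtocolLayout().with_cpt_duration(cpt_s)
    effect = effect if effect is not None else EffectSpec.identity()
    signal, truth = synth_beat_train(BeatModel(rr_jitter=0.0), layout,
                                     effect, seed=seed)
    if filtered:
        signal = apply_zero_phase(design_bandpass(), center(signal))
    return build_feature_table(truth, signal, truth.epochs, "P01", 1, FS)


class TestNormalize:
    def test_baseline_means_exactly_one(self):
        table = _one_recording_table()
        normalized, ref = normalize_by_baseline(table)
        base = normalized[normalized["epoch"] == "baseline"]
        means = base[list(FEATURE_COLUMNS)].mean()
        np.testing.assert_allclose(means.to_numpy(), 1.0, rtol=1e-12)

    def test_cpt_s_amplitude_effect_recovered(self):
        # measured on the unfiltered clean signal: the band-pass shifts the
        # isoelectric level, which this exactness check is not about
        table = _one_recording_table(effect=EffectSpec(
            hr_factor=1.0, s_amp_factor=0.7, t_amp_factor=1.0,
            r_amp_factor=1.0, t_offset_shift=0.0), filtered=False)
        normalized, _ = normalize_by_baseline(table)
        cpt = normalized[normalized["epoch"] == "cpt"]
        assert cpt["S_amplitude"].mean() == pytest.approx(0.7, abs=0.03)

    def test_scale_equivariance(self):
        layout = ProtocolLayout()
        signal, truth = synth_beat_train(BeatModel(rr_jitter=0.0), layout, seed=0)
        filtered = apply_zero_phase(design_bandpass(), center(signal))
        t1 = build_feature_table(truth, filtered, truth.epochs, "P01", 1, FS)
        t2 = build_feature_table(truth, filtered * 3.0, truth.epochs, "P01", 1, FS)
        n1, _ = normalize_by_baseline(t1)
        n2, _ = normalize_by_baseline(t2)
        amp_cols = [c for c in FEATURE_COLUMNS if "amp" in c]
        np.testing.assert_allclose(n1[amp_cols].to_numpy(),
                                   n2[amp_cols].to_numpy(), rtol=1e-9)

    def test_missing_baseline_rejected(self):
        table = _one_recording_table()
        no_base = table[table["epoch"] != "baseline"]
        with pytest.raises(NormalizationError):
            normalize_by_baseline(no_base)

    def test_zero_baseline_mean_named(self):
        table = _one_recording_table()
        table.loc[table["epoch"] == "baseline", "P_peaks"] = 0.0
        with pytest.raises(NormalizationError, match="P_peaks"):
            normalize_by_baseline(table)


class TestAssembleDataset:
    def test_full_cpt_row_counts(self):
        table = _one_recording_table(cpt_s=120.0)
        normalized, _ = normalize_by_baseline(table)
        dataset = assemble_dataset(normalized)
        counts = dataset["label"].value_counts().to_dict()
        assert counts[0] == 57 and counts[1] == 21

    def test_other_epochs_unlabeled(self):
        table = _one_recording_table()
        normalized, _ = normalize_by_baseline(table)
        dataset = assemble_dataset(
            normalized, epochs=("baseline", "warm1", "cpt", "warm2", "rest"))
        assert dataset.loc[dataset["epoch"] == "warm1", "label"].isna().all()
        assert (dataset.loc[dataset["epoch"] == "cpt", "label"] == 1).all()

    def test_missing_class_rejected(self):
        table = _one_recording_table()
        normalized, _ = normalize_by_baseline(table)
        with pytest.raises(DatasetError):
            assemble_dataset(normalized[normalized["epoch"] == "baseline"])

    def test_incomplete_rows_dropped(self):
        table = _one_recording_table()
        table.loc[table.index[:3], "T_onoffdist"] = np.nan
        normalized, _ = normalize_by_baseline(table)
        dataset = assemble_dataset(normalized)
        assert dataset.attrs["n_dropped"] == 3
        assert not dataset[list(FEATURE_COLUMNS)].isna().any().any()


class TestCohortBookkeeping:
    def test_labeled_rows_72x78_shape(self):
        # window arithmetic: 57 baseline + 21 CPT windows per recording when
        # CPT runs the full 120 s -> 78 rows each
        n_per = 57 + 21
        assert 72 * n_per == 5616

    def test_null_cohort_features_match_between_classes(self):
        # identity effect + zero noise + zero jitter: CPT windows carry the
        # same per-beat morphology as baseline windows
        cohort = generate_cohort(
            1, 1, seed=3, effect=EffectSpec.identity(),
            noise=NoiseSpec.silent(),
            template=BeatModel(rr_jitter=0.0), cpt_range_s=(120.0, 120.0))
        rec, truth = cohort[0]
        filtered = apply_zero_phase(design_bandpass(), center(rec.signal))
        table = build_feature_table(truth, filtered, truth.epochs,
                                    rec.participant, rec.session, FS)
        normalized, _ = normalize_by_baseline(table)
        dataset = assemble_dataset(normalized)
        base = dataset[dataset["label"] == 0]["S_amplitude"].mean()
        cpt = dataset[dataset["label"] == 1]["S_amplitude"].mean()
        # sub-sample phase of the drawn RR leaves a ~1e-5 sampling residue
        assert cpt == pytest.approx(base, rel=1e-3)
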
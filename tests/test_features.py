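import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegsel.features import (
    CANONICAL_BANDS,
    DegenerateSignalError,
    FeatureError,
    FeatureName,
    FeatureTable,
    FeatureConfig,
    band_powers,
    build_feature_table,
    epoch_signal,
    hjorth_activity,
    hjorth_mobility,
    lempel_ziv,
    lz76_phrase_count,
    normalize_features,
    psd_bins,
    sample_entropy,
    summarize,
)
from eegsel.synth import control_profile, generate_recording


# ---------------------------------------------------------------------------
# oracles


def sampen_bruteforce(x, m, r):
    """O(n^2) literal template counting; independent of the fast path."""
    n = len(x)

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) < r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    return -math.log(a / b)


def quantile_oracle(values, q):
    """Linear-interpolation quantile computed from first principles."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])


# ---------------------------------------------------------------------------
# epoching


def test_epoching_counts(montage32):
    rec = generate_recording(control_profile(), 4, 256, montage32, seed=0)
    ep = epoch_signal(rec, 1.0)
    assert ep.shape == (32, 4, 256)
    # trailing partial window dropped
    rec2 = rec.copy_with(samples=rec.samples[:, : int(4.5 * 256)])
    assert epoch_signal(rec2, 1.0).shape == (32, 4, 256)
    with pytest.raises(FeatureError):
        epoch_signal(rec, 0.0)


# ---------------------------------------------------------------------------
# spectra


class TestPsdBins:
    def test_tone_lands_in_its_bin(self):
        fs = 128
        t = np.arange(fs) / fs
        b = psd_bins(np.sin(2 * np.pi * 45 * t), fs)
        assert max(b, key=b.get) == "44-46"

    def test_zero_signal_all_zero(self):
        assert all(v == 0 for v in psd_bins(np.zeros(128), 128).values())

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(128)
        total = sum(psd_bins(x, 128).values())
        assert total == pytest.approx(np.var(x), rel=0.01)

    def test_bin_wider_than_nyquist_rejected(self):
        with pytest.raises(FeatureError):
            psd_bins(np.zeros(128), 128, bin_width=100)


class TestBandPowers:
    @pytest.mark.parametrize("freq,band", [(10, "alpha"), (2, "delta"), (20, "beta"), (45, "gamma")])
    def test_tone_dominates_its_band(self, freq, band):
        fs = 128
        t = np.arange(fs) / fs
        bp = band_powers(np.sin(2 * np.pi * freq * t), fs)
        others = [v for k, v in bp.items() if k != band]
        assert bp[band] > 10 * max(max(others), 1e-12)

    def test_white_noise_powers_proportional_to_bandwidth(self):
        fs, n_ep = 128, 100
        rng = np.random.default_rng(0)
        freqs = np.fft.rfftfreq(fs, 1 / fs)
        width = {}
        for name, (lo, hi) in CANONICAL_BANDS.items():
            hi = min(hi, fs / 2)
            sel = freqs > 30 if name == "gamma" else (freqs >= lo) & (freqs < hi)
            width[name] = sel.sum()
        acc = {k: 0.0 for k in CANONICAL_BANDS}
        for _ in range(n_ep):
            bp = band_powers(rng.standard_normal(fs), fs)
            for k, v in bp.items():
                acc[k] += v
        dens = {k: acc[k] / width[k] for k in acc}
        ref = np.mean(list(dens.values()))
        for k, v in dens.items():
            assert v == pytest.approx(ref, rel=0.25)


# ---------------------------------------------------------------------------
# complexity metrics


class TestLempelZiv:
    @pytest.mark.parametrize(
        "bits,count",
        [([0, 1, 0, 1], 3), ([0, 0, 0, 0], 2), ([0], 1), ([0, 0], 2),
         ([0, 1, 0], 3), ([0, 0, 1, 0, 1, 1, 1, 0], 4)],  # 0|01|011|10
    )
    def test_hand_parsed_phrase_counts(self, bits, count):
        assert lz76_phrase_count(np.array(bits)) == count

    def test_constant_signal(self):
        # all values equal -> all-zero binarisation -> 2 phrases
        x = np.full(64, 3.7)
        assert lempel_ziv(x) == pytest.approx(2 * math.log2(64) / 64)

    def test_random_beats_periodic(self):
        # a strict median split needs continuous amplitudes: on a two-valued
        # signal the median coincides with the majority value and the
        # binarised string collapses
        n = 512
        periodic = np.tile([1.0, -1.0, 1.0, 0.5], n // 4)
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rand = rng.standard_normal(n)
            if lempel_ziv(rand) > lempel_ziv(periodic):
                wins += 1
        assert wins == 50


class TestHjorth:
    def test_sinusoid_activity_closed_form(self):
        fs, A, f = 128, 3.0, 8
        t = np.arange(fs) / fs
        x = A * np.sin(2 * np.pi * f * t)
        assert hjorth_activity(x) == pytest.approx(A**2 / 2, rel=0.02)

    @pytest.mark.parametrize("f", [4, 8, 12, 16])
    def test_sinusoid_mobility_approximates_angular_frequency(self, f):
        fs = 128
        t = np.arange(fs) / fs
        x = np.sin(2 * np.pi * f * t)
        assert hjorth_mobility(x, fs) == pytest.approx(2 * np.pi * f, rel=0.03)

    def test_constant_epoch(self):
        x = np.full(32, 5.0)
        assert hjorth_activity(x) == 0.0
        assert hjorth_mobility(x, 128) == 0.0


class TestSampleEntropy:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for x in (np.arange(64.0), rng.standard_normal(64), np.sin(np.arange(64) / 3)):
            r = 0.2 * x.std()
            assert sample_entropy(x, 2, r) == pytest.approx(
                sampen_bruteforce(list(x), 2, r), abs=1e-12
            )

    def test_constant_epoch_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sample_entropy(np.full(32, 1.0))

    def test_noise_exceeds_sinusoid(self):
        n, fs = 128, 128
        t = np.arange(n) / fs
        sine = np.sin(2 * np.pi * 10 * t)
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(n) * sine.std()
            if sample_entropy(noise) > sample_entropy(sine):
                wins += 1
        assert wins >= 48


# ---------------------------------------------------------------------------
# summaries


class TestSummarize:
    def test_example_values(self):
        s = summarize(np.array([1.0, 2, 3, 4]))
        assert s["mean"] == 2.5
        assert s["upper_qrt"] == pytest.approx(quantile_oracle([1, 2, 3, 4], 0.75))
        assert s["lower_qrt"] == pytest.approx(quantile_oracle([1, 2, 3, 4], 0.25))
        assert s["upper_qrt"] == 3.25 and s["lower_qrt"] == 1.75

    def test_constant_and_singleton(self):
        c = summarize(np.full(5, 2.0))
        assert c == {"mean": 2.0, "std": 0.0, "upper_qrt": 2.0, "lower_qrt": 2.0}
        s1 = summarize(np.array([7.0]))
        assert s1["mean"] == 7.0 and s1["std"] == 0.0
        assert s1["upper_qrt"] == 7.0 and s1["lower_qrt"] == 7.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40), st.randoms())
    def test_permutation_invariance(self, values, rnd):
        a = summarize(np.array(values))
        shuffled = list(values)
        rnd.shuffle(shuffled)
        b = summarize(np.array(shuffled))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# naming grammar


class TestFeatureName:
    @pytest.mark.parametrize(
        "name",
        ["hjorthActivity_FC5_mean", "LZC_T7_upper_qrt", "sampEn_FC2_mean",
         "PSD_CP5_44-46_std", "bandPower_Fp1_0-4_lower_qrt"],
    )
    def test_printed_names_round_trip(self, name):
        assert FeatureName.parse(name).serialize() == name

    def test_parse_rejects_garbage(self):
        for bad in ("PSD_CP5", "foo", "PSD_CP5_44-46_median", "a_b_c_d_e_mean"):
            with pytest.raises(FeatureError):
                FeatureName.parse(bad)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.sampled_from(["PSD", "LZC", "sampEn", "hjorthActivity"]),
        st.sampled_from(["CP5", "Fp1", "Oz"]),
        st.sampled_from(["mean", "std", "upper_qrt", "lower_qrt"]),
        st.one_of(st.none(), st.tuples(st.integers(0, 62), st.integers(1, 2))),
    )
    def test_round_trip_property(self, metric, channel, stat, band):
        b = None if band is None else (float(band[0]), float(band[0] + band[1]))
        fn = FeatureName(metric, channel, stat, b)
        assert FeatureName.parse(fn.serialize()) == fn


# ---------------------------------------------------------------------------
# table construction and normalisation


@pytest.fixture(scope="module")
def small_table(montage32):
    recs = [
        generate_recording(control_profile(), 4, 256, montage32, seed=s,
                           subject_id=f"sub-{s}")
        for s in (1, 2)
    ]
    from eegsel.preprocess import run_preprocess, PreprocessConfig

    recs = [run_preprocess(r, PreprocessConfig()) for r in recs]
    return build_feature_table(recs)


def test_table_grid_shape(small_table):
    # 32 channels x 32 PSD bins x 4 stats
    psd_cols = [c for c in small_table.feature_names if c.startswith("PSD_")]
    assert len(psd_cols) == 32 * 32 * 4
    # all names parse and regenerate
    for c in small_table.feature_names:
        assert FeatureName.parse(c).serialize() == c
    # PSD and band powers are nonnegative pre-normalisation
    for c in psd_cols[:50] + [c for c in small_table.feature_names if c.startswith("bandPower_")][:50]:
        assert (small_table.data[c] >= 0).all()


def test_identical_recordings_identical_rows(montage32):
    rec = generate_recording(control_profile(), 4, 256, montage32, seed=5)
    t = build_feature_table(
        [rec, rec.copy_with(subject_id="sub-copy")],
        FeatureConfig(metrics=("PSD", "LZC")),
    )
    assert np.allclose(t.data.iloc[0].to_numpy(), t.data.iloc[1].to_numpy())


def test_heterogeneous_montages_rejected(montage32):
    from eegsel.montage import montage_from_positions
    from eegsel.synth import Recording

    rec = generate_recording(control_profile(), 4, 256, montage32, seed=0)
    m2 = montage_from_positions(["A", "B", "C"], [[0, 0], [1, 0], [0, 1]])
    other = Recording("x", "CONTROL", 256.0, np.zeros((3, 1024)), m2)
    with pytest.raises(FeatureError):
        build_feature_table([rec, other])


class TestNormalize:
    def _table(self, X, cols=None):
        import pandas as pd

        cols = cols or [f"f{j}" for j in range(X.shape[1])]
        idx = [f"s{i}" for i in range(X.shape[0])]
        return FeatureTable(
            data=pd.DataFrame(X, columns=cols, index=idx),
            labels=__import__("pandas").Series(["A"] * len(idx), index=idx),
        )

    def test_zscore_columns(self):
        rng = np.random.default_rng(0)
        t = normalize_features(self._table(rng.normal(5, 3, size=(20, 3))))
        X = t.data.to_numpy()
        assert np.allclose(X.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(X.std(axis=0), 1, atol=1e-10)  # population std

    def test_tiny_scale_column_takes_log_path(self):
        rng = np.random.default_rng(1)
        X = np.c_[rng.normal(size=12), 1e-6 + 1e-6 * rng.uniform(size=12)]
        t = normalize_features(self._table(X))
        assert t.normalization["f1"]["log"] is True
        assert t.normalization["f0"]["log"] is False
        col = t.data["f1"].to_numpy()
        assert np.allclose(col.mean(), 0, atol=1e-10)
        assert np.allclose(col.std(), 1, atol=1e-10)

    def test_constant_column_zeroed_and_flagged(self):
        X = np.c_[np.random.default_rng(2).normal(size=10), np.full(10, 4.2)]
        t = normalize_features(self._table(X))
        assert (t.data["f1"] == 0).all()
        assert t.normalization["f1"]["constant"] is True


def test_table_csv_round_trip(small_table, tmp_path):
    t = normalize_features(small_table.subset(small_table.feature_names[:10]))
    p = tmp_path / "table.csv"
    t.to_csv(p)
    back = FeatureTable.from_csv(p)
    assert np.allclose(back.data.to_numpy(), t.data.to_numpy())
    assert list(back.labels) == list(t.labels)
    assert back.normalization.keys() == t.normalization.keys()
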
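"""Unit and property tests for the RR/HRV feature set, with independent
brute-force oracles for the entropy features."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from afcf import (
    FeatureLengthError, RRSeries, cosen, extract_all, fuzzy_entropy,
    mad_feature, rmssd_family, sample_entropy, spectral_features,
    time_domain_features,
)

# --------------------------------------------------------------------------
# independent O(n^2) oracles (plain loops, no shared code with the package)


def sampen_oracle(x, m, r):
    n = len(x)

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    return -math.log(a / b)


def fuzzyen_oracle(x, m, r, n_exp):
    y = [v / (sum(x) / len(x)) for v in x]
    n = len(y)

    def phi(mm):
        tmpls = []
        for i in range(n - m):
            t = y[i:i + mm]
            mu = sum(t) / mm
            tmpls.append([v - mu for v in t])
        tot, cnt = 0.0, 0
        for i in range(len(tmpls)):
            for j in range(i + 1, len(tmpls)):
                d = max(abs(a - b) for a, b in zip(tmpls[i], tmpls[j]))
                tot += math.exp(-((d / r) ** n_exp))
                cnt += 1
        return tot / cnt

    return -math.log(phi(m + 1) / phi(m))


# --------------------------------------------------------------------------
# time domain


@pytest.mark.parametrize(
    "intervals, expect",
    [
        ([1000, 1000, 1000], {"mRR": 1000, "SDNN": 0, "mHR": 60, "PNN50": 0}),
        ([800, 860, 870, 1000], {"PNN50": 100 * 2 / 3}),
    ],
)
def test_time_domain_examples(intervals, expect):
    got = time_domain_features(RRSeries("x", intervals))
    for k, v in expect.items():
        assert got[k] == pytest.approx(v)


def test_min_max_mean_two_beats():
    rr = RRSeries("x", [722, 855])
    vals = {"minRR": 722.0, "maxRR": 855.0, "mRR": 788.5}
    # PNN50 needs 3 intervals, so check the 2-beat statistics directly
    x = rr.intervals
    assert float(x.min()) == vals["minRR"]
    assert float(x.max()) == vals["maxRR"]
    assert float(x.mean()) == vals["mRR"]
    with pytest.raises(FeatureLengthError, match="PNN50"):
        time_domain_features(rr)


def test_too_short_series_rejected():
    with pytest.raises(ValueError):
        RRSeries("x", [800])
    with pytest.raises(ValueError):
        RRSeries("x", [800, -5])


# --------------------------------------------------------------------------
# RMSSD family


@pytest.mark.parametrize(
    "intervals, lag, center, expect",
    [
        ([800, 850, 800, 850], 1, "mean", 50.0),
        ([800, 850, 800, 850], 2, "mean", 0.0),
        ([1000] * 10, 1, "mean", 0.0),
        ([1000] * 10, 3, "median", 0.0),
    ],
)
def test_rmssd_examples(intervals, lag, center, expect):
    assert rmssd_family(RRSeries("x", intervals), lag, center) == pytest.approx(expect)


def test_rmssd_bad_lag():
    with pytest.raises(ValueError, match="lag"):
        rmssd_family(RRSeries("x", [800, 850, 900]), 4)


# --------------------------------------------------------------------------
# spectral


def _modulated(freq, n=120):
    t = np.cumsum(np.full(n, 1.0))
    return RRSeries("x", 1000 + 50 * np.sin(2 * np.pi * freq * t))


def test_lf_modulation_dominates():
    assert spectral_features(_modulated(0.10))["LF_HF"] > 1


def test_hf_modulation_dominates():
    assert spectral_features(_modulated(0.30))["LF_HF"] < 1


def test_normalized_powers_sum_to_one():
    rng = np.random.default_rng(7)
    s = spectral_features(RRSeries("w", 1000 + rng.normal(0, 50, 300)))
    assert s["LFn"] + s["HFn"] == pytest.approx(1.0, abs=1e-9)
    assert s["LF"] >= 0 and s["HF"] >= 0


def test_short_series_flagged_unreliable():
    with pytest.warns(UserWarning, match="unreliable"):
        spectral_features(RRSeries("s", [800.0] * 10))


# --------------------------------------------------------------------------
# COSEn / sample entropy


def test_cosen_constant_closed_form():
    # all templates match: SampEn = 0, so COSEn = ln(2*30) - ln(1000)
    got = cosen(RRSeries("c", [1000.0] * 60), m=1, r=30.0)
    assert got == pytest.approx(math.log(60) - math.log(1000), abs=1e-12)


def test_sampen_scale_invariance():
    rng = np.random.default_rng(2)
    x = rng.uniform(500, 1100, 80)
    c = 2.5
    assert sample_entropy(x, 1, 30.0) == pytest.approx(
        sample_entropy(c * x, 1, c * 30.0), abs=1e-12
    )


@pytest.mark.parametrize("n", [20, 60, 200])
def test_sampen_matches_bruteforce_oracle(n):
    rng = np.random.default_rng(n)
    x = rng.uniform(400, 1200, n)
    assert sample_entropy(x, 1, 100.0) == pytest.approx(
        sampen_oracle(list(x), 1, 100.0), abs=1e-12
    )


def test_cosen_alternans_against_oracle():
    x = np.tile([800.0, 400.0], 20)  # 40-beat alternans
    se = sampen_oracle(list(x), 1, 30.0)
    expect = se + math.log(60) - math.log(float(np.mean(x)))
    assert cosen(RRSeries("a", x), 1, 30.0) == pytest.approx(expect, abs=1e-12)


def test_sampen_degenerate_counts_warn_nan():
    # strictly increasing with huge steps: no template matches at r=1
    x = np.array([100.0, 300.0, 900.0, 2700.0, 8100.0])
    with pytest.warns(UserWarning, match="SampEn undefined"):
        assert math.isnan(sample_entropy(x, 1, 1.0))


# --------------------------------------------------------------------------
# fuzzy entropy


def test_nfen_degenerate_constant_is_nan():
    with pytest.warns(UserWarning, match="zero-variance"):
        assert math.isnan(fuzzy_entropy(RRSeries("c", [1000.0] * 30)))


@given(st.floats(min_value=0.1, max_value=10.0))
def test_nfen_scale_invariance(c):
    rng = np.random.default_rng(11)
    x = rng.uniform(600, 1000, 30)
    a = fuzzy_entropy(RRSeries("a", x))
    b = fuzzy_entropy(RRSeries("b", c * x))
    assert a == pytest.approx(b, abs=1e-9)


@pytest.mark.parametrize("n", [30, 100, 200])
def test_nfen_matches_bruteforce_oracle(n):
    rng = np.random.default_rng(5 + n)
    x = rng.uniform(400, 1200, n)
    y = x / x.mean()
    r = 0.2 * float(np.std(y, ddof=1))
    assert fuzzy_entropy(RRSeries("f", x)) == pytest.approx(
        fuzzyen_oracle(list(x), 1, r, 2.0), abs=1e-10
    )


# --------------------------------------------------------------------------
# MAD


def test_mad_constant_is_zero():
    assert mad_feature(RRSeries("c", [900.0] * 12)) == 0.0


def test_mad_hand_computed_windows():
    # HR = [100,100,100,200,200,200]; window SDs {0, 57.735, 57.735, 0}
    got = mad_feature(RRSeries("m", [600, 600, 600, 300, 300, 300]))
    assert got == pytest.approx(np.std([100, 100, 200], ddof=1) / 2, abs=1e-3)
    assert got == pytest.approx(28.8675, abs=1e-3)


def test_mad_disjoint_window_knob():
    rr = RRSeries("m", [600, 600, 600, 300, 300, 300])
    sds = [0.0, np.std([200, 200, 200], ddof=1)]
    assert mad_feature(rr, sliding=False) == pytest.approx(np.median(sds))


# --------------------------------------------------------------------------
# full vector


def test_extract_all_constant_series():
    vec = extract_all(RRSeries("c", [1000.0] * 60))
    assert vec["SDNN"] == 0 and vec["PNN50"] == 0 and vec["MAD"] == 0
    for k in ("RMSSD", "RMSSD1", "RMSSD2", "RMSSD3",
              "RMeSSD1", "RMeSSD2", "RMeSSD3"):
        assert vec[k] == 0
    assert math.isnan(vec["NFEn"])  # degenerate tolerance
    assert "CNNout" not in vec


def test_extract_all_single_stream_identity():
    rng = np.random.default_rng(3)
    vec = extract_all(RRSeries("x", rng.uniform(500, 1100, 60)))
    assert vec["RMSSD"] == vec["RMSSD1"]
    assert vec["COSEn1"] == vec["COSEn2"]


def test_extract_all_stand_ins_flag():
    rr = RRSeries("x", [800.0, 850, 820, 790, 805, 830])
    vec = extract_all(rr, include_stand_ins=True, cnn_out=0.7)
    assert vec["CNNout"] == 0.7 and math.isnan(vec["RNNout"])


def test_extract_all_short_series_yields_sentinels_not_errors():
    vec = extract_all(RRSeries("s", [800.0, 900.0]))
    assert math.isnan(vec["PNN50"]) and math.isnan(vec["AFEv"])
    assert vec["mRR"] == 850.0


@given(st.floats(min_value=0.25, max_value=4.0))
def test_scale_equivariance(c):
    rng = np.random.default_rng(17)
    x = rng.uniform(500, 1100, 40)
    a = extract_all(RRSeries("a", x))
    b = extract_all(RRSeries("b", c * x))
    for k in ("mRR", "minRR", "maxRR", "SDNN", "RMSSD1", "RMSSD2",
              "RMeSSD1", "RMeSSD3"):
        assert b[k] == pytest.approx(c * a[k], rel=1e-9)
    for k in ("mHR", "medHR"):
        assert b[k] == pytest.approx(a[k] / c, rel=1e-9)
    assert b["NFEn"] == pytest.approx(a["NFEn"], abs=1e-9)
    assert b["PNN50"] <= 100 and b["PNN50"] >= 0
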
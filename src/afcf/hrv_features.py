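"""Meta-level ECG features computed from an RR-interval series.

Two published feature sets are covered: the 14 RR features used by an
SVM-based AFib detector (mRR, minRR, maxRR, medHR, SDNN, PNN50, RMSSD,
LF/HF band powers, COSEn, NFEn, MAD, AFEv) and the 10 RR-variability
features of a handheld-device classifier (lagged RMSSD/RMeSSD variants,
mHR, COSEn, plus two neural-network outputs that are external inputs
here).  When both sets name the same statistic it is computed once on the
same RR stream, so the duplicated names (e.g. RMSSD vs RMSSD1, COSEn1 vs
COSEn2) coincide; in the original detectors they differed only because of
different upstream QRS detectors, which are out of scope.

Conventions used throughout:

* heart rate per beat is 60000 / RR_ms (bpm);
* standard deviations use the n-1 denominator;
* undefined values (zero denominators, degenerate series) are reported as
  ``nan`` sentinels, never as infinities.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import lombscargle

from .afev import af_evidence
from .rr import FeatureLengthError, RRSeries

__all__ = [
    "time_domain_features",
    "rmssd_family",
    "spectral_features",
    "cosen",
    "sample_entropy",
    "fuzzy_entropy",
    "mad_feature",
    "extract_all",
    "FEATURE_NAMES",
]

#: The feature-vector column order: the SVM set, then the device set.
FEATURE_NAMES = [
    "mRR", "minRR", "maxRR", "medHR", "SDNN", "PNN50", "RMSSD",
    "LF", "HF", "LFn", "HFn", "LF_HF", "COSEn1", "NFEn", "MAD", "AFEv",
    "RMSSD1", "RMSSD2", "RMSSD3", "RMeSSD1", "RMeSSD2", "RMeSSD3",
    "mHR", "COSEn2", "CNNout", "RNNout",
]

# Frequency bands (Hz) for spectral HRV power.
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def _time_domain_core(rr: RRSeries) -> dict[str, float]:
    x = rr.require("time_domain", 2)
    hr = 60000.0 / x
    return {
        "mRR": float(np.mean(x)),
        "minRR": float(np.min(x)),
        "maxRR": float(np.max(x)),
        "SDNN": float(np.std(x, ddof=1)),
        "mHR": float(np.mean(hr)),
        "medHR": float(np.median(hr)),
    }


def time_domain_features(rr: RRSeries) -> dict[str, float]:
    """mRR/minRR/maxRR (ms), SDNN (ms), mHR/medHR (bpm), PNN50 (%).

    PNN50 is the percentage of successive-difference magnitudes exceeding
    50 ms and needs at least 3 intervals; the rest need 2.
    """
    out = _time_domain_core(rr)
    x = rr.intervals
    if len(rr) >= 3:
        d = np.abs(np.diff(x))
        out["PNN50"] = float(100.0 * np.count_nonzero(d > 50.0) / d.size)
    else:
        raise FeatureLengthError("PNN50", 3, len(rr))
    return out


def rmssd_family(rr: RRSeries, lag: int = 1, center: str = "mean") -> float:
    """Root {mean|median} squared lag-k RR difference, in ms.

    lag 1 differences successive intervals, lag 2 every other interval,
    lag 3 every third.  ``center="median"`` gives the RMeSSD variants.
    """
    if lag not in (1, 2, 3):
        raise ValueError(f"lag must be 1, 2 or 3, got {lag}")
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    x = rr.require(f"RMSSD(lag={lag})", lag + 1)
    d = x[lag:] - x[:-lag]
    agg = np.mean if center == "mean" else np.median
    return float(np.sqrt(agg(d * d)))


def spectral_features(rr: RRSeries, f_step: float = 0.001) -> dict[str, float]:
    """LF/HF band powers from a Lomb-Scargle periodogram of the tachogram.

    The tachogram (onset time, RR) is unevenly sampled, so the spectrum is
    estimated with Lomb-Scargle directly — no resampling.  LF is power in
    0.04-0.15 Hz, HF in 0.15-0.40 Hz; LFn/HFn normalize by LF+HF and
    LF_HF is the raw ratio (nan when HF is 0).  Series shorter than 30
    intervals or 60 s are flagged unreliable with a warning.
    """
    x = rr.require("spectral", 8)
    if len(rr) < 30 or rr.duration_s < 60.0:
        warnings.warn(
            f"record {rr.record_id!r}: spectral features from "
            f"{len(rr)} beats / {rr.duration_s:.0f} s are unreliable "
            "(< 30 beats or < 60 s)",
            stacklevel=2,
        )
    t = rr.onset_times
    y = x - np.mean(x)
    freqs = np.arange(f_step, HF_BAND[1] + 0.05, f_step)
    pgram = lombscargle(t, y, 2.0 * np.pi * freqs)
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])
    lf = float(np.trapezoid(pgram[lf_mask], freqs[lf_mask]))
    hf = float(np.trapezoid(pgram[hf_mask], freqs[hf_mask]))
    tot = lf + hf
    return {
        "LF": lf,
        "HF": hf,
        "LFn": lf / tot if tot > 0 else float("nan"),
        "HFn": hf / tot if tot > 0 else float("nan"),
        "LF_HF": lf / hf if hf > 0 else float("nan"),
    }


def _template_matrix(x: np.ndarray, window: int, n_templates: int) -> np.ndarray:
    """First ``n_templates`` sliding templates of the given window length.

    SampEn/FuzzyEn compare counts at lengths m and m+1 over the *same*
    number of templates (n - m), so the shorter-window list is truncated.
    """
    return np.lib.stride_tricks.sliding_window_view(x, window)[:n_templates]


def _chebyshev_pair_distances(x: np.ndarray, window: int,
                              n_templates: int) -> np.ndarray:
    tmpl = _template_matrix(x, window, n_templates)
    d = np.abs(tmpl[:, None, :] - tmpl[None, :, :]).max(axis=2)
    iu = np.triu_indices(tmpl.shape[0], k=1)
    return d[iu]


def sample_entropy(x: np.ndarray, m: int = 1, r: float = 30.0) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev template matching (d <= r),
    self-matches excluded, and n-m templates at both lengths m and m+1.

    Returns nan (with a warning) when either count is zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise FeatureLengthError("SampEn", m + 2, x.size)
    n_templates = x.size - m
    b = int(np.count_nonzero(_chebyshev_pair_distances(x, m, n_templates) <= r))
    a = int(np.count_nonzero(_chebyshev_pair_distances(x, m + 1, n_templates) <= r))
    if a == 0 or b == 0:
        warnings.warn(
            f"SampEn undefined: template match counts A={a}, B={b} "
            f"(m={m}, r={r:g}); returning nan",
            stacklevel=2,
        )
        return float("nan")
    return float(-np.log(a / b))


def cosen(rr: RRSeries, m: int = 1, r: float = 30.0) -> float:
    """Coefficient of sample entropy: SampEn(m, r) + ln(2r) - ln(mean RR).

    The correction terms make short-series entropies comparable across
    heart rates; r defaults to 30 ms, the usual choice for 30 s AF
    screening strips.  r and the mean RR share units (ms) before the logs.
    """
    x = rr.require("COSEn", m + 2)
    se = sample_entropy(x, m=m, r=r)
    return float(se + np.log(2.0 * r) - np.log(np.mean(x)))


def fuzzy_entropy(rr: RRSeries, m: int = 1, r: float | None = None,
                  n_exp: float = 2.0) -> float:
    """Normalized fuzzy entropy (NFEn) of the RR series.

    The series is first normalized by its mean (making the value scale
    invariant), each template is centred on its own mean, and matching is
    soft: membership exp(-(d/r)^n_exp) of the Chebyshev distance d.  The
    entropy is -ln(phi_{m+1}/phi_m) over mean memberships.  r defaults to
    0.2 x SD of the normalized series; a zero-variance series has no
    usable tolerance and yields nan.
    """
    x = rr.require("NFEn", m + 2)
    y = x / np.mean(x)
    if r is None:
        sd = float(np.std(y, ddof=1))
        if sd == 0.0:
            warnings.warn(
                f"record {rr.record_id!r}: NFEn undefined for zero-variance "
                "series (tolerance r = 0.2*SD = 0); returning nan",
                stacklevel=2,
            )
            return float("nan")
        r = 0.2 * sd
    phi = []
    n_templates = y.size - m
    for mm in (m, m + 1):
        tmpl = _template_matrix(y, mm, n_templates)
        tmpl = tmpl - tmpl.mean(axis=1, keepdims=True)
        d = np.abs(tmpl[:, None, :] - tmpl[None, :, :]).max(axis=2)
        iu = np.triu_indices(tmpl.shape[0], k=1)
        phi.append(float(np.mean(np.exp(-((d[iu] / r) ** n_exp)))))
    return float(-np.log(phi[1] / phi[0]))


def mad_feature(rr: RRSeries, sliding: bool = True) -> float:
    """Median over 3-beat windows of the in-window heart-rate SD (bpm).

    Per-beat heart rate is 60000/RR; each window of three adjacent beats
    contributes its sample SD, and the feature is the median of those
    window SDs — a robust local-variation summary.  ``sliding=False``
    switches to disjoint windows.
    """
    x = rr.require("MAD", 5)
    hr = 60000.0 / x
    if sliding:
        win = np.lib.stride_tricks.sliding_window_view(hr, 3)
    else:
        n_full = hr.size // 3
        win = hr[: 3 * n_full].reshape(n_full, 3)
    sds = np.std(win, axis=1, ddof=1)
    return float(np.median(sds))


def extract_all(rr: RRSeries, include_stand_ins: bool = False,
                cnn_out: float | None = None,
                rnn_out: float | None = None) -> dict[str, float]:
    """Compute the full feature vector for one record.

    All 22 RR-computable features are populated; per-feature failures
    (short series, degenerate inputs) become nan sentinels rather than
    aborting the vector.  CNNout/RNNout are outputs of trained neural
    networks external to this package: they are included only when
    ``include_stand_ins`` is set, filled from the given values (or nan),
    and otherwise omitted.
    """
    out: dict[str, float] = {}

    def _safe(fn, *keys):
        try:
            res = fn()
        except (FeatureLengthError, ValueError):
            res = {k: float("nan") for k in keys} if len(keys) > 1 else float("nan")
        if isinstance(res, dict):
            out.update(res)
        else:
            out[keys[0]] = res

    _safe(lambda: _time_domain_core(rr),
          "mRR", "minRR", "maxRR", "SDNN", "mHR", "medHR")
    _safe(lambda: time_domain_features(rr)["PNN50"], "PNN50")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _safe(lambda: spectral_features(rr), "LF", "HF", "LFn", "HFn", "LF_HF")
        _safe(lambda: cosen(rr), "COSEn1")
        _safe(lambda: fuzzy_entropy(rr), "NFEn")
    for lag in (1, 2, 3):
        _safe(lambda lag=lag: rmssd_family(rr, lag, "mean"), f"RMSSD{lag}")
        _safe(lambda lag=lag: rmssd_family(rr, lag, "median"), f"RMeSSD{lag}")
    _safe(lambda: mad_feature(rr), "MAD")
    _safe(lambda: float(af_evidence(rr)), "AFEv")
    # single-stream identities: both sets see the same RR sequence
    out["RMSSD"] = out["RMSSD1"]
    out["COSEn2"] = out["COSEn1"]
    if include_stand_ins:
        out["CNNout"] = float("nan") if cnn_out is None else float(cnn_out)
        out["RNNout"] = float("nan") if rnn_out is None else float(rnn_out)
    order = [f for f in FEATURE_NAMES if f in out]
    return {k: out[k] for k in order}
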
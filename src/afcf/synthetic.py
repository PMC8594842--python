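"""Seeded synthetic generators: RR series of named rhythms, and ensembles
of correlated base-classifier votes with a continuous scorer.

These generators emulate the *shapes and statistical signatures* of a
short-strip AFib screening study — 30 s single-lead records, a handful of
categorical base detectors plus one continuous scorer, class
distributions matching an outpatient screening population — so that
every other module is testable offline.  They do not model ECG
waveforms, atrioventricular conduction, or the confuser rhythms
(flutter, NSVT, SVT) that plague real detectors.

Rhythm models
-------------
* ``sinus``: base RR plus a ~0.1 Hz (Mayer-wave/baroreflex) and a 0.25 Hz
  respiratory sinusoid plus small white jitter — regular, serially
  correlated intervals.
* ``afib``: i.i.d. log-normal intervals with a high coefficient of
  variation — the irregularly irregular, serially uncorrelated AF
  signature.
* ``slow_afib``: AF dynamics with every interval floored above 1000 ms,
  so the ventricular rate is below 60 bpm by construction.
* ``noisy_afib``: AF intervals corrupted by spurious (split) and missed
  (merged) beats at a stated rate, mimicking QRS-detection errors.

Ensemble model
--------------
Each record carries a shared latent difficulty; every voter's
probability of a correct call decreases with difficulty and increases
with its per-class skill, which induces correlated errors across voters.
Class counts are honored exactly when given, so fixtures can match a
study's distribution verbatim.  All outputs are byte-reproducible from
one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta_table import CATEGORICAL, SCORE, MetaTable, RhythmLabel
from .rr import RRSeries

__all__ = [
    "RhythmSpec", "gen_rr",
    "VoterSkill", "EnsembleSpec", "gen_ensemble",
    "gen_complementary_experts",
    "training_set_spec", "test_set_spec", "DEFAULT_VOTERS",
]

RHYTHMS = ("sinus", "afib", "slow_afib", "noisy_afib")


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of one synthetic RR record.

    ``mean_rr_ms`` defaults per rhythm: 800 (sinus), 700 (afib and
    noisy_afib; AF is typically rapid), 1300 (slow_afib).  Variability
    knobs: sinus modulation amplitudes and jitter (ms), AF coefficient of
    variation, corruption rate for noisy_afib.
    """

    rhythm: str
    duration_s: float = 30.0
    mean_rr_ms: float | None = None
    seed: int = 0
    lf_amp_ms: float = 30.0       # ~0.1 Hz modulation (sinus)
    hf_amp_ms: float = 25.0       # respiratory 0.25 Hz modulation (sinus)
    jitter_ms: float = 5.0        # white jitter (sinus)
    cv: float = 0.24              # coefficient of variation (afib)
    corruption_rate: float = 0.08  # beat split/merge rate (noisy_afib)

    def __post_init__(self):
        if self.rhythm not in RHYTHMS:
            raise ValueError(f"unknown rhythm {self.rhythm!r}; choose from {RHYTHMS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("lf_amp_ms", "hf_amp_ms", "jitter_ms", "cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mean_rr_ms is not None and self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")


_LF_FREQ = 0.095   # Hz, Mayer-wave band
_RESP_FREQ = 0.25  # Hz, respiration

_SLOW_FLOOR_MS = 1010.0   # hard per-interval floor => HR < 59.5 bpm always


def _lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def gen_rr(spec: RhythmSpec, record_id: str | None = None) -> RRSeries:
    """Generate one RR series whose cumulative time ≈ ``duration_s``."""
    rng = np.random.default_rng(spec.seed)
    rid = record_id or f"{spec.rhythm}-{spec.seed}"
    target_ms = spec.duration_s * 1000.0

    if spec.rhythm == "sinus":
        mean = spec.mean_rr_ms or 800.0
        phases = rng.uniform(0, 2 * np.pi, size=2)
        intervals = []
        t = 0.0
        while t < target_ms:
            rr = (
                mean
                + spec.lf_amp_ms * np.sin(2 * np.pi * _LF_FREQ * t / 1000.0 + phases[0])
                + spec.hf_amp_ms * np.sin(2 * np.pi * _RESP_FREQ * t / 1000.0 + phases[1])
                + spec.jitter_ms * rng.standard_normal()
            )
            rr = max(rr, 200.0)
            intervals.append(rr)
            t += rr
        x = np.array(intervals)
    elif spec.rhythm in ("afib", "noisy_afib"):
        mean = spec.mean_rr_ms or 700.0
        n_est = int(np.ceil(target_ms / mean) * 2) + 8
        draws = _lognormal(rng, mean, spec.cv, n_est)
        x = draws[: np.searchsorted(np.cumsum(draws), target_ms) + 1]
        if spec.rhythm == "noisy_afib":
            x = _corrupt(rng, x, spec.corruption_rate)
    elif spec.rhythm == "slow_afib":
        mean = spec.mean_rr_ms or 1300.0
        excess = max(mean - _SLOW_FLOOR_MS, 50.0)
        n_est = int(np.ceil(target_ms / mean) * 2) + 8
        draws = _SLOW_FLOOR_MS + _lognormal(rng, excess, 0.5, n_est)
        x = draws[: np.searchsorted(np.cumsum(draws), target_ms) + 1]
    else:  # pragma: no cover - guarded by RhythmSpec
        raise ValueError(spec.rhythm)

    if x.size < 4:
        x = np.resize(x, 4)
    return RRSeries(rid, x)


def _corrupt(rng, x: np.ndarray, rate: float) -> np.ndarray:
    """Split (spurious beat) or merge (missed beat) intervals at ``rate``."""
    out: list[float] = []
    i = 0
    while i < x.size:
        u = rng.random()
        if u < rate / 2:                      # spurious detection: split
            frac = rng.uniform(0.3, 0.7)
            out += [x[i] * frac, x[i] * (1 - frac)]
            i += 1
        elif u < rate and i + 1 < x.size:     # missed beat: merge
            out.append(x[i] + x[i + 1])
            i += 2
        else:
            out.append(x[i])
            i += 1
    return np.array(out)


# --------------------------------------------------------------------------
# Vote ensembles


@dataclass(frozen=True)
class VoterSkill:
    """One base detector's per-class probability of a correct call."""

    name: str
    p_correct_afib: float = 0.90
    p_correct_nonafib: float = 0.95
    p_correct_noisy: float = 0.60

    def __post_init__(self):
        for f in ("p_correct_afib", "p_correct_nonafib", "p_correct_noisy"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1], got {v}")


#: Six categorical voters with skills in the range of strong published
#: detectors (sensitivities ~0.87-0.92, specificities ~0.94-0.97).
DEFAULT_VOTERS = (
    VoterSkill("alg_1", 0.92, 0.97),
    VoterSkill("alg_2", 0.91, 0.96),
    VoterSkill("alg_3", 0.90, 0.96),
    VoterSkill("alg_4", 0.89, 0.95),
    VoterSkill("alg_5", 0.88, 0.95),
    VoterSkill("alg_6", 0.87, 0.94),
)


@dataclass(frozen=True)
class EnsembleSpec:
    """Shape and skill profile of a synthetic vote ensemble.

    ``counts`` fixes exact per-class record counts (honored verbatim);
    alternatively give ``n_records`` and ``prevalence`` for Bernoulli
    labels with no noisy class.  ``difficulty_weight`` scales the shared
    latent difficulty: 0 makes voter errors independent, larger values
    concentrate every voter's errors on the same hard records.
    """

    counts: dict | None = None              # RhythmLabel -> int
    n_records: int | None = None
    prevalence: float = 0.17
    voters: tuple[VoterSkill, ...] = DEFAULT_VOTERS
    difficulty_weight: float = 1.0
    scorer_name: str = "scorer"
    scorer_skill: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.counts is None and self.n_records is None:
            raise ValueError("give either counts or n_records")
        if self.counts is not None:
            bad = {k: v for k, v in self.counts.items() if v < 0}
            if bad or sum(self.counts.values()) <= 0:
                raise ValueError(f"infeasible class counts: {self.counts}")


def training_set_spec(seed: int = 0) -> EnsembleSpec:
    """The 2,532-record training distribution of an outpatient screening
    study: 2,317 non-AFib, 137 AFib, 78 noisy."""
    return EnsembleSpec(
        counts={RhythmLabel.NON_AFIB: 2317, RhythmLabel.AFIB: 137,
                RhythmLabel.NOISY: 78},
        seed=seed,
    )


def test_set_spec(seed: int = 0) -> EnsembleSpec:
    """The matching 4,644-record test distribution: 777 AFib, 3,867 non-AFib."""
    return EnsembleSpec(
        counts={RhythmLabel.AFIB: 777, RhythmLabel.NON_AFIB: 3867},
        seed=seed,
    )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _draw_labels(spec: EnsembleSpec, rng) -> list[RhythmLabel]:
    if spec.counts is not None:
        labels = [lab for lab, c in spec.counts.items() for _ in range(c)]
        labels = [l if isinstance(l, RhythmLabel) else RhythmLabel(l)
                  for l in labels]
        perm = rng.permutation(len(labels))
        return [labels[i] for i in perm]
    draws = rng.random(spec.n_records) < spec.prevalence
    return [RhythmLabel.AFIB if d else RhythmLabel.NON_AFIB for d in draws]


def gen_ensemble(spec: EnsembleSpec) -> MetaTable:
    """Labeled MetaTable of categorical votes plus one continuous score.

    Correct-call probability of voter j on record i is
    sigmoid(logit(skill_jc) - w * z_i) with shared difficulty z_i ~ N(0,1)
    and w = ``difficulty_weight``; incorrect calls go mostly to the
    opposing rhythm class with a small noisy fraction.  The continuous
    scorer mixes class-conditional Beta distributions through the same
    difficulty channel.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _draw_labels(spec, rng)
    n = len(labels)
    ids = [f"rec{i:05d}" for i in range(n)]
    z = rng.standard_normal(n)
    w = spec.difficulty_weight

    data: dict[str, list] = {}
    kinds: dict[str, str] = {}
    for voter in spec.voters:
        votes: list[RhythmLabel] = []
        for i, lab in enumerate(labels):
            skill = {
                RhythmLabel.AFIB: voter.p_correct_afib,
                RhythmLabel.NON_AFIB: voter.p_correct_nonafib,
                RhythmLabel.NOISY: voter.p_correct_noisy,
            }[lab]
            p_ok = _sigmoid(_logit(skill) - w * z[i])
            if rng.random() < p_ok:
                votes.append(lab)
            elif lab == RhythmLabel.AFIB:
                votes.append(RhythmLabel.NON_AFIB if rng.random() < 0.9
                             else RhythmLabel.NOISY)
            elif lab == RhythmLabel.NON_AFIB:
                votes.append(RhythmLabel.AFIB if rng.random() < 0.9
                             else RhythmLabel.NOISY)
            else:
                votes.append(RhythmLabel.AFIB if rng.random() < 0.5
                             else RhythmLabel.NON_AFIB)
        data[voter.name] = votes
        kinds[voter.name] = CATEGORICAL

    scores = np.empty(n)
    for i, lab in enumerate(labels):
        p_ok = _sigmoid(_logit(spec.scorer_skill) - w * z[i])
        toward_afib = (lab == RhythmLabel.AFIB) == (rng.random() < p_ok)
        if lab == RhythmLabel.NOISY:
            scores[i] = rng.beta(2, 2)
        elif toward_afib:
            scores[i] = rng.beta(8, 2)
        else:
            scores[i] = rng.beta(2, 8)
    data[spec.scorer_name] = scores
    kinds[spec.scorer_name] = SCORE

    df = pd.DataFrame(data, index=pd.Index(ids, name="record_id"))
    return MetaTable(df, kinds, pd.Series(labels, index=df.index))


def gen_complementary_experts(n: int, seed: int = 0,
                              prevalence: float = 0.35,
                              p_local: float = 0.98,
                              p_away: float = 0.70) -> MetaTable:
    """Seven voters, each near-perfect on its own 1/7 subpopulation.

    Records are partitioned uniformly into 7 subpopulations; voter j is
    correct with probability ``p_local`` on subpopulation j and
    ``p_away`` elsewhere.  No single voter can excel globally, but the
    voters jointly cover the population — the scenario in which a fusion
    of complementary detectors should beat every individual one.
    """
    if n < 700:
        raise ValueError("need n >= 700 for stable 7-subpopulation structure")
    rng = np.random.default_rng(seed)
    subpop = rng.integers(0, 7, size=n)
    n_af = int(round(n * prevalence))
    lab_arr = np.array([RhythmLabel.AFIB] * n_af
                       + [RhythmLabel.NON_AFIB] * (n - n_af), dtype=object)
    lab_arr = lab_arr[rng.permutation(n)]

    data: dict[str, list] = {}
    kinds: dict[str, str] = {}
    for j in range(7):
        p_ok = np.where(subpop == j, p_local, p_away)
        ok = rng.random(n) < p_ok
        votes = [
            lab if good else
            (RhythmLabel.NON_AFIB if lab == RhythmLabel.AFIB else RhythmLabel.AFIB)
            for lab, good in zip(lab_arr, ok)
        ]
        data[f"expert_{j + 1}"] = votes
        kinds[f"expert_{j + 1}"] = CATEGORICAL

    ids = [f"rec{i:05d}" for i in range(n)]
    df = pd.DataFrame(data, index=pd.Index(ids, name="record_id"))
    return MetaTable(df, kinds, pd.Series(list(lab_arr), index=df.index))
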
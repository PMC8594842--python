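"""Synthetic RR and vote-ensemble generators: exact class counts, rhythm
signatures, correlation structure, and byte determinism."""

import numpy as np
import pytest
from collections import Counter

from afcf.meta_table import RhythmLabel
from afcf.synthetic import (
    EnsembleSpec, RhythmSpec, VoterSkill, gen_complementary_experts,
    gen_ensemble, gen_rr, training_set_spec,
)
from afcf.synthetic import test_set_spec as held_out_spec  # avoid collection
from afcf import af_evidence, cosen, rmssd_family


# --------------------------------------------------------------------------
# RR rhythms


def test_sinus_serially_correlated():
    s = gen_rr(RhythmSpec("sinus", mean_rr_ms=800, seed=3))
    x = s.intervals
    assert np.corrcoef(x[1:], x[:-1])[0, 1] > 0.5


def test_afib_serially_uncorrelated_median():
    acs = []
    for seed in range(100):
        x = gen_rr(RhythmSpec("afib", seed=seed)).intervals
        acs.append(abs(np.corrcoef(x[1:], x[:-1])[0, 1]))
    assert np.median(acs) < 0.15


def test_slow_afib_rate_below_60_always():
    for seed in range(20):
        x = gen_rr(RhythmSpec("slow_afib", seed=seed)).intervals
        hr = 60000.0 / x
        assert hr.max() < 60.0
        assert hr.mean() < 60.0


def test_duration_approximately_honored():
    for rhythm in ("sinus", "afib", "slow_afib", "noisy_afib"):
        s = gen_rr(RhythmSpec(rhythm, duration_s=30, seed=1))
        assert 28.0 <= s.duration_s <= 35.0


def test_noisy_afib_alters_beat_sequence():
    clean = gen_rr(RhythmSpec("afib", seed=5)).intervals
    noisy = gen_rr(RhythmSpec("noisy_afib", seed=5)).intervals
    assert len(noisy) != len(clean) or not np.array_equal(noisy, clean)


def test_rhythm_spec_validation():
    with pytest.raises(ValueError, match="unknown rhythm"):
        RhythmSpec("flutter")
    with pytest.raises(ValueError):
        RhythmSpec("sinus", duration_s=-1)


def test_rr_generation_deterministic():
    a = gen_rr(RhythmSpec("afib", seed=11)).intervals
    b = gen_rr(RhythmSpec("afib", seed=11)).intervals
    assert np.array_equal(a, b)


def test_afib_features_separate_from_sinus():
    """The AF signatures the detectors rely on: higher entropy, higher
    Lorenz-plot evidence, higher short-term variability (median over
    100 paired seeds)."""
    diffs = {"cosen": [], "afev": [], "rmssd": []}
    for seed in range(100):
        af = gen_rr(RhythmSpec("afib", seed=seed))
        si = gen_rr(RhythmSpec("sinus", seed=seed))
        diffs["cosen"].append(cosen(af) - cosen(si))
        diffs["afev"].append(af_evidence(af) - af_evidence(si))
        diffs["rmssd"].append(rmssd_family(af, 1) - rmssd_family(si, 1))
    for name, d in diffs.items():
        assert np.median(d) > 0, name


# --------------------------------------------------------------------------
# ensembles


def test_training_distribution_counts_exact():
    table = gen_ensemble(training_set_spec(0))
    counts = Counter(table.labels)
    assert counts[RhythmLabel.NON_AFIB] == 2317
    assert counts[RhythmLabel.AFIB] == 137
    assert counts[RhythmLabel.NOISY] == 78


def test_test_distribution_counts_exact():
    table = gen_ensemble(held_out_spec(0))
    counts = Counter(table.labels)
    assert counts[RhythmLabel.AFIB] == 777
    assert counts[RhythmLabel.NON_AFIB] == 3867


def test_perfect_independent_voter_equals_labels():
    spec = EnsembleSpec(
        counts={RhythmLabel.AFIB: 50, RhythmLabel.NON_AFIB: 150},
        voters=(VoterSkill("oracle", 1.0, 1.0),),
        difficulty_weight=0.0,
        seed=1,
    )
    table = gen_ensemble(spec)
    assert list(table.data["oracle"]) == list(table.labels)


def test_difficulty_weight_induces_error_correlation():
    def error_corr(w, seed=0):
        spec = EnsembleSpec(
            counts={RhythmLabel.AFIB: 600, RhythmLabel.NON_AFIB: 1400},
            voters=(VoterSkill("v1", 0.85, 0.85),
                    VoterSkill("v2", 0.85, 0.85)),
            difficulty_weight=w, seed=seed,
        )
        t = gen_ensemble(spec)
        e1 = np.array([v != l for v, l in zip(t.data["v1"], t.labels)], float)
        e2 = np.array([v != l for v, l in zip(t.data["v2"], t.labels)], float)
        return np.corrcoef(e1, e2)[0, 1]

    corr_independent = np.mean([error_corr(0.0, s) for s in range(5)])
    corr_shared = np.mean([error_corr(2.0, s) for s in range(5)])
    assert corr_shared > corr_independent + 0.1


def test_ensemble_deterministic_byte_identical():
    a = gen_ensemble(training_set_spec(7))
    b = gen_ensemble(training_set_spec(7))
    assert a.data.equals(b.data)
    assert list(a.labels) == list(b.labels)


def test_infeasible_counts_rejected():
    with pytest.raises(ValueError, match="infeasible|counts"):
        EnsembleSpec(counts={RhythmLabel.AFIB: -3})


# --------------------------------------------------------------------------
# complementary experts


def test_expert_accuracy_strictly_inside_mixture_bounds():
    table = gen_complementary_experts(2000, seed=0)
    for name in table.feature_names:
        acc = np.mean([v == l for v, l in zip(table.data[name], table.labels)])
        assert 0.70 < acc < 0.98


def test_no_single_expert_near_perfect_f1():
    worst_best = 0.0
    for seed in range(50):
        table = gen_complementary_experts(2000, seed=seed)
        y = np.array([l == RhythmLabel.AFIB for l in table.labels], int)
        best = 0.0
        for name in table.feature_names:
            p = np.array([v == RhythmLabel.AFIB for v in table.data[name]], int)
            tp = int(np.sum(y & p)); fp = int(np.sum(~y.astype(bool) & p.astype(bool)))
            fn = int(np.sum(y & ~p.astype(bool)))
            best = max(best, 2 * tp / (2 * tp + fp + fn))
        worst_best = max(worst_best, best)
    assert worst_best <= 0.95


def test_local_expert_oracle_combiner_accuracy():
    # re-derive each record's local expert from the generator's own RNG
    # stream: picking the voter whose subpopulation matches should beat
    # any fixed voter by a wide margin
    n, seed = 2000, 3
    rng = np.random.default_rng(seed)
    subpop = rng.integers(0, 7, size=n)
    table = gen_complementary_experts(n, seed=seed)
    votes = [table.data[f"expert_{j + 1}"] for j in range(7)]
    picked = [votes[subpop[i]].iloc[i] for i in range(n)]
    acc = np.mean([v == l for v, l in zip(picked, table.labels)])
    assert acc >= 0.97


def test_experts_require_minimum_population():
    with pytest.raises(ValueError, match="700"):
        gen_complementary_experts(100, seed=0)
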
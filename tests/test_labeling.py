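"""Gold-standard labeling strategies and the voting negative selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpiflux.labeling import (
    InteractionScores,
    LabelSet,
    load_direct_labels,
    positives_from_scores,
    potential_negative_labeling,
    random_labeling,
    random_stitch_labeling,
    read_fingerprints,
    tanimoto,
    tanimoto_labeling,
    write_fingerprints,
)


# ---------------------------------------------------------------------------
# Positives from scores
# ---------------------------------------------------------------------------


def test_score_threshold_is_strict():
    scores = InteractionScores(
        scores={("m1", "p1"): 501, ("m2", "p2"): 500, ("m3", "p3"): 499}
    )
    assert positives_from_scores(scores) == {("m1", "p1")}
    assert positives_from_scores(scores, threshold=0) == set(scores.scores)


def test_empty_scores_no_positives():
    assert positives_from_scores(InteractionScores(scores={})) == set()


def test_score_range_validated():
    with pytest.raises(ValueError, match="outside"):
        InteractionScores(scores={("m", "p"): 1001})


# ---------------------------------------------------------------------------
# Potential-negative voting
# ---------------------------------------------------------------------------


def _voting_instance(n_pos=4, n_neg=12, separable=True, seed=0):
    """Positives near (1,1), assumed negatives near (0,0) when separable."""
    rng = np.random.default_rng(seed)
    pos = [(f"pm{i}", f"pp{i}") for i in range(n_pos)]
    neg = [(f"nm{i}", f"np{i}") for i in range(n_neg)]
    rows, keys = [], []
    for m, p in pos:
        keys.append(f"{m}:{p}")
        rows.append(rng.normal(loc=1.0, scale=0.1, size=4))
    for m, p in neg:
        keys.append(f"{m}:{p}")
        loc = 0.0 if separable else 1.0
        rows.append(rng.normal(loc=loc, scale=0.1, size=4))
    features = pd.DataFrame(rows, index=keys)
    return features, set(pos), set(neg)


def test_voting_bookkeeping_on_4_12_instance():
    """t = 3 subsets of 4; every pair scored by exactly t-1 classifiers."""
    features, pos, neg = _voting_instance()
    labels, scoring = potential_negative_labeling(features, pos, neg, seed=0)
    assert scoring.t == 3
    sizes = [sum(1 for s in scoring.subset_of.values() if s == k) for k in range(3)]
    assert sizes == [4, 4, 4]
    assert set(scoring.votes) == neg
    assert all(0 <= v <= 2 for v in scoring.votes.values())
    assert labels.positives == pos
    assert labels.negatives <= neg


def test_voting_selects_separable_negatives():
    """Cleanly separable negatives are unanimously confirmed."""
    features, pos, neg = _voting_instance(separable=True)
    labels, scoring = potential_negative_labeling(features, pos, neg, seed=0)
    # oracle: a single SVM trained on everything also separates the classes
    from sklearn.svm import SVC

    X = features.to_numpy()
    y = np.array([1.0] * 4 + [0.0] * 12)
    assert SVC(kernel="rbf").fit(X, y).score(X, y) == 1.0
    assert labels.negatives == neg


def test_voting_rejects_positive_lookalikes():
    """Assumed negatives indistinguishable from positives are not selected."""
    features, pos, neg = _voting_instance(separable=False, n_neg=12)
    labels, _ = potential_negative_labeling(features, pos, neg, seed=0)
    assert len(labels.negatives) < len(neg) / 2


def test_voting_requires_ratio_at_least_two():
    features, pos, neg = _voting_instance(n_pos=4, n_neg=6)
    with pytest.raises(ValueError, match="t="):
        potential_negative_labeling(features, pos, neg, seed=0)


# ---------------------------------------------------------------------------
# Random STITCH labeling
# ---------------------------------------------------------------------------


def test_random_stitch_rule():
    scores = InteractionScores(scores={("m1", "p1"): 800, ("m2", "p2"): 700})
    universe = {("m1", "p1"), ("m1", "p2"), ("m3", "p1"), ("m3", "p3")}
    labels = random_stitch_labeling(scores, universe)
    assert labels.labels[("m1", "p1")] == 1
    assert labels.labels[("m1", "p2")] == 0  # both members occur in positives
    assert ("m3", "p1") not in labels.labels  # m3 never positive: unlabeled
    assert ("m3", "p3") not in labels.labels


def test_random_stitch_negative_members_all_in_positives(default_bundle):
    universe = {(m, p) for (m, p) in default_bundle.scores.scores}
    labels = random_stitch_labeling(default_bundle.scores, universe)
    pos_mets = {m for m, _ in labels.positives}
    pos_prots = {p for _, p in labels.positives}
    for m, p in labels.negatives:
        assert m in pos_mets and p in pos_prots
    assert labels.positives.isdisjoint(labels.negatives)


# ---------------------------------------------------------------------------
# Tanimoto
# ---------------------------------------------------------------------------


def _bits(*on: int) -> np.ndarray:
    out = np.zeros(64, dtype=bool)
    out[list(on)] = True
    return out


def test_tanimoto_basic_cases():
    a = _bits(0, 1)
    assert tanimoto(a, a) == 1.0
    assert tanimoto(_bits(0, 1), _bits(2, 3)) == 0.0
    assert tanimoto(_bits(0, 1), _bits(0, 2)) == pytest.approx(1 / 3)
    assert tanimoto(np.zeros(64, bool), np.zeros(64, bool)) == 0.0
    with pytest.raises(ValueError, match="64"):
        tanimoto(np.zeros(32, bool), np.zeros(64, bool))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_tanimoto_matches_popcount_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(30):
        a = rng.random(64) < rng.uniform(0, 0.5)
        b = rng.random(64) < rng.uniform(0, 0.5)
        inter = sum(1 for i in range(64) if a[i] and b[i])
        union = sum(1 for i in range(64) if a[i] or b[i])
        expected = inter / union if union else 0.0
        assert tanimoto(a, b) == pytest.approx(expected)
        assert tanimoto(b, a) == tanimoto(a, b)


def test_tanimoto_labeling_rules():
    fps = {"m1": _bits(0, 1), "m2": _bits(32, 33), "m3": _bits(1, 2)}
    positives = {("m1", "p1"), ("m2", "p1")}
    labels = tanimoto_labeling(positives, fps)
    # sim(m1, m2) = 0 but (m2, p1) is itself positive: stays positive
    assert labels.labels[("m2", "p1")] == 1
    # sim(m1, m3) > 0: no nomination; sim(m2, m3) = 0 -> (m3, p1) negative
    assert labels.labels[("m3", "p1")] == 0
    with pytest.raises(KeyError, match="m9"):
        tanimoto_labeling({("m9", "p1")}, fps)


def test_fingerprint_tsv_round_trip(tmp_path):
    fps = {"m1": _bits(0, 63), "m2": _bits(5, 6, 7)}
    path = tmp_path / "fp.tsv"
    write_fingerprints(fps, path)
    back = read_fingerprints(path)
    for met in fps:
        assert (back[met] == fps[met]).all()


# ---------------------------------------------------------------------------
# Random labeling and direct labels
# ---------------------------------------------------------------------------


def test_random_labeling_balance_and_determinism():
    pairs = {(f"m{i}", f"p{i}") for i in range(10)}
    labels = random_labeling(pairs, seed=3)
    assert sum(labels.labels.values()) == 5
    assert random_labeling(pairs, seed=3).labels == labels.labels
    assert random_labeling(pairs, seed=4).labels != labels.labels


def test_random_labeling_is_uniform_over_seeds():
    """Each pair is positive in about half of many seeded labelings."""
    pairs = sorted({(f"m{i}", f"p{i}") for i in range(8)})
    counts = {p: 0 for p in pairs}
    n = 400
    for seed in range(n):
        labels = random_labeling(pairs, seed=seed)
        for p in pairs:
            counts[p] += labels.labels[p]
    # binomial(400, 0.5): 5 sigma ~ 50
    for p, c in counts.items():
        assert abs(c - n / 2) < 50


def test_direct_labels_parsing(tmp_path):
    path = tmp_path / "labels.tsv"
    path.write_text(
        "metabolite\tprotein\tlabel\nm1\tp1\t1\nm2\tp2\t0\nm3\tp3\t0\nm2\tp2\t0\n"
    )
    labels = load_direct_labels(path)
    assert labels.labels == {("m1", "p1"): 1, ("m2", "p2"): 0, ("m3", "p3"): 0}

    bad = tmp_path / "conflict.tsv"
    bad.write_text("metabolite\tprotein\tlabel\nm1\tp1\t1\nm1\tp1\t0\n")
    with pytest.raises(ValueError, match="conflict"):
        load_direct_labels(bad)

    malformed = tmp_path / "malformed.tsv"
    malformed.write_text("metabolite\tprotein\tlabel\nm1\tp1\t2\n")
    with pytest.raises(ValueError, match="malformed"):
        load_direct_labels(malformed)


def test_all_strategies_keep_classes_disjoint(default_bundle):
    universe = {(m, p) for (m, p) in default_bundle.scores.scores}
    strategies = [
        random_stitch_labeling(default_bundle.scores, universe),
        random_labeling(universe, seed=0),
        default_bundle.labels,
    ]
    for labels in strategies:
        assert labels.positives.isdisjoint(labels.negatives)
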
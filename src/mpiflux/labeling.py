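"""Gold-standard construction: positive and negative metabolite-protein pairs.

Interaction evidence rarely comes with reliable non-interacting pairs, so
four strategies construct the negative class:

* **potential-negative** — PU-learning-style voting: partition the assumed
  negatives into ``t`` subsets, train one SVM per subset against all
  positives, and keep only pairs unanimously predicted negative by every
  classifier that did not train on them.
* **random-stitch** — a pair is negative iff unscored/low-scored but both
  its metabolite and its protein occur in at least one positive pair.
* **tanimoto** — metabolites with zero fingerprint similarity to a known
  binder of a protein nominate negatives for that protein.
* **direct** — explicit 0/1 labels from a curated database table.

A balanced **random-control** labeling is provided to establish the chance
baseline of any classifier trained downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "InteractionScores",
    "LabelSet",
    "NegativeScoring",
    "read_scores",
    "write_scores",
    "read_fingerprints",
    "write_fingerprints",
    "positives_from_scores",
    "potential_negative_labeling",
    "random_stitch_labeling",
    "tanimoto",
    "tanimoto_labeling",
    "random_labeling",
    "load_direct_labels",
    "write_labels",
]

Pair = tuple[str, str]  # (metabolite, protein)


@dataclass
class InteractionScores:
    """STITCH-style confidence scores, integers in [0, 1000] per pair."""

    scores: dict[Pair, int]

    def __post_init__(self) -> None:
        for pair, s in self.scores.items():
            if not 0 <= s <= 1000:
                raise ValueError(f"score {s} for pair {pair} outside [0, 1000]")


@dataclass
class LabelSet:
    labels: dict[Pair, int]  # 1 = interacting, 0 = non-interacting
    strategy: str
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, lab in self.labels.items():
            if lab not in (0, 1):
                raise ValueError(f"label {lab!r} for pair {pair} not in {{0, 1}}")

    @property
    def positives(self) -> set[Pair]:
        return {p for p, l in self.labels.items() if l == 1}

    @property
    def negatives(self) -> set[Pair]:
        return {p for p, l in self.labels.items() if l == 0}


@dataclass
class NegativeScoring:
    """Bookkeeping of the potential-negative voting scheme."""

    t: int
    votes: dict[Pair, int]  # held-out negative votes, in [0, t-1]
    subset_of: dict[Pair, int]  # which subset each assumed negative trained in


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------


def read_scores(path: str | Path) -> InteractionScores:
    df = pd.read_csv(path, sep="\t")
    return InteractionScores(
        scores={
            (str(r.metabolite), str(r.protein)): int(r.combined_score)
            for r in df.itertuples()
        }
    )


def write_scores(scores: InteractionScores, path: str | Path) -> None:
    df = pd.DataFrame(
        [(m, p, s) for (m, p), s in sorted(scores.scores.items())],
        columns=["metabolite", "protein", "combined_score"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    """Fingerprint TSV: metabolite, 16-hex-character string (64 bits, MSB first)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, np.ndarray] = {}
    for r in df.itertuples():
        word = r.fingerprint.strip()
        if len(word) != 16:
            raise ValueError(f"fingerprint for {r.metabolite!r} is not 16 hex chars")
        bits = np.array([int(c) for c in format(int(word, 16), "064b")], dtype=bool)
        out[str(r.metabolite)] = bits
    return out


def write_fingerprints(fps: Mapping[str, np.ndarray], path: str | Path) -> None:
    rows = []
    for met, bits in sorted(fps.items()):
        word = int("".join("1" if b else "0" for b in bits), 2)
        rows.append((met, format(word, "016x")))
    pd.DataFrame(rows, columns=["metabolite", "fingerprint"]).to_csv(
        path, sep="\t", index=False
    )


def write_labels(labels: LabelSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [(m, p, l, labels.strategy) for (m, p), l in sorted(labels.labels.items())],
        columns=["metabolite", "protein", "label", "strategy"],
    )
    df.to_csv(path, sep="\t", index=False)


def load_direct_labels(path: str | Path) -> LabelSet:
    """Explicit 0/1 pair labels from TSV (metabolite, protein, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    labels: dict[Pair, int] = {}
    for r in df.itertuples():
        if r.label not in ("0", "1"):
            raise ValueError(f"malformed label {r.label!r} for ({r.metabolite}, {r.protein})")
        pair = (str(r.metabolite), str(r.protein))
        lab = int(r.label)
        if pair in labels and labels[pair] != lab:
            raise ValueError(f"conflicting duplicate labels for pair {pair}")
        labels[pair] = lab
    return LabelSet(labels=labels, strategy="direct")


# ---------------------------------------------------------------------------
# Labeling strategies
# ---------------------------------------------------------------------------


def positives_from_scores(
    scores: InteractionScores, threshold: int = 500
) -> set[Pair]:
    """Pairs scored strictly above the confidence threshold."""
    return {pair for pair, s in scores.scores.items() if s > threshold}


def potential_negative_labeling(
    features: pd.DataFrame,
    positives: set[Pair],
    assumed_negatives: set[Pair],
    seed: int,
    svm_params: dict | None = None,
) -> tuple[LabelSet, NegativeScoring]:
    """PU-learning negative selection by held-out SVM voting.

    ``t = floor(|assumed_negatives| / |positives|)`` subsets are drawn at
    random (sizes differing by at most 1). Each subset trains one
    RBF-kernel SVM against all positives; every assumed negative is then
    scored by the ``t - 1`` classifiers whose training subset excluded it,
    and selected as a confirmed negative only on a unanimous vote
    (``votes == t - 1``).

    ``features`` rows are indexed by "metabolite:protein" keys and must
    cover all pairs.
    """
    if not positives:
        raise ValueError("empty positive set")
    t = len(assumed_negatives) // len(positives)
    if t < 2:
        raise ValueError(
            f"assumed-negative/positive ratio t={t} < 2: held-out voting impossible"
        )
    rng = np.random.default_rng(seed)

    def key(pair: Pair) -> str:
        return f"{pair[0]}:{pair[1]}"

    missing = [p for p in positives | assumed_negatives if key(p) not in features.index]
    if missing:
        raise KeyError(f"pairs lack feature rows: {sorted(missing)[:5]}")

    neg_list = sorted(assumed_negatives)
    order = rng.permutation(len(neg_list))
    subset_of = {neg_list[j]: int(i % t) for i, j in enumerate(order)}
    subsets: list[list[Pair]] = [[] for _ in range(t)]
    for pair, s in subset_of.items():
        subsets[s].append(pair)

    X_pos = features.loc[[key(p) for p in sorted(positives)]].to_numpy()
    votes: dict[Pair, int] = {p: 0 for p in assumed_negatives}
    params = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}
    params.update(svm_params or {})
    for s, subset in enumerate(subsets):
        X_neg = features.loc[[key(p) for p in subset]].to_numpy()
        X = np.vstack([X_pos, X_neg])
        y = np.concatenate([np.ones(len(X_pos)), np.zeros(len(X_neg))])
        try:
            clf = SVC(random_state=seed, **params).fit(X, y)
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(f"voting SVM failed on subset {s}: {exc}") from exc
        held_out = [p for p in neg_list if subset_of[p] != s]
        X_held = features.loc[[key(p) for p in held_out]].to_numpy()
        pred = clf.predict(X_held)
        for pair, yhat in zip(held_out, pred):
            if yhat == 0:
                votes[pair] += 1

    selected = {p for p, v in votes.items() if v == t - 1}
    labels = {p: 1 for p in positives}
    labels.update({p: 0 for p in selected})
    label_set = LabelSet(
        labels=labels,
        strategy="potential-negative",
        notes={"t": t, "n_selected": len(selected), "seed": seed},
    )
    return label_set, NegativeScoring(t=t, votes=votes, subset_of=subset_of)


def random_stitch_labeling(
    scores: InteractionScores, universe: Iterable[Pair], threshold: int = 500
) -> LabelSet:
    """Negatives = unscored/low-scored pairs whose metabolite AND protein
    both occur in at least one positive pair; other pairs stay unlabeled."""
    positives = positives_from_scores(scores, threshold)
    pos_mets = {m for m, _ in positives}
    pos_prots = {p for _, p in positives}
    labels: dict[Pair, int] = {}
    for pair in universe:
        if pair in positives:
            labels[pair] = 1
        elif pair[0] in pos_mets and pair[1] in pos_prots:
            labels[pair] = 0
    for pair in positives:
        labels[pair] = 1
    return LabelSet(labels=labels, strategy="random-stitch")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Bit-set Jaccard index of two 64-bit fingerprints.

    Two all-zero fingerprints have, by convention, similarity 0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != (64,) or b.shape != (64,):
        raise ValueError("fingerprints must be 64 bits")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def tanimoto_labeling(
    positives: set[Pair],
    fingerprints: Mapping[str, np.ndarray],
    candidates: Iterable[str] | None = None,
) -> LabelSet:
    """Zero-similarity metabolites of each positive's binder nominate negatives.

    For every positive (met_i, prot_j) and every other metabolite met_i'
    with Tanimoto(met_i, met_i') == 0, the pair (met_i', prot_j) is labeled
    non-interacting unless it is itself a positive.
    """
    mets = sorted(set(candidates) if candidates is not None else set(fingerprints))
    for m in {m for m, _ in positives} | set(mets):
        if m not in fingerprints:
            raise KeyError(f"missing fingerprint for metabolite {m!r}")
    labels: dict[Pair, int] = {p: 1 for p in positives}
    for met_i, prot_j in sorted(positives):
        for met_other in mets:
            if met_other == met_i:
                continue
            if tanimoto(fingerprints[met_i], fingerprints[met_other]) == 0.0:
                pair = (met_other, prot_j)
                if pair not in labels:
                    labels[pair] = 0
    return LabelSet(labels=labels, strategy="tanimoto")


def random_labeling(pairs: Iterable[Pair], seed: int) -> LabelSet:
    """Uniformly random balanced labels: exactly floor(n/2) positives."""
    pair_list = sorted(set(pairs))
    if len(pair_list) < 2:
        raise ValueError("need at least 2 pairs for balanced random labels")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pair_list))
    n_pos = len(pair_list) // 2
    labels = {
        pair_list[j]: (1 if rank < n_pos else 0) for rank, j in enumerate(order)
    }
    return LabelSet(labels=labels, strategy="random-control", notes={"seed": seed})
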
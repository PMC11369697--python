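"""End-to-end workflow orchestration with artifact provenance.

Each stage consumes and emits the package's standard text formats and
writes a JSON metadata sidecar (parameters, seed, SHA-256 hashes of its
inputs) sufficient to re-run the stage bit-identically. Stages:

    simulate -> fluxes -> features -> label -> train -> rank
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import model_io
from .classify import CVConfig, CVResult, balanced_cv
from .features import (
    EtaTable,
    FilterReport,
    FluxSumTable,
    PairFeatureMatrix,
    build_pair_features,
    compute_eta,
    cv_filter,
    flux_sum,
)
from .flux_estimation import FluxTable, pfba_all, read_fluxes, write_fluxes
from .labeling import (
    LabelSet,
    load_direct_labels,
    positives_from_scores,
    potential_negative_labeling,
    random_labeling,
    random_stitch_labeling,
    read_fingerprints,
    read_scores,
    tanimoto_labeling,
    write_labels,
)
from .model_io import MetabolicModel, map_pairs_to_proteins, reaction_enzyme_abundance
from .ranking import aggregate_predictions, rank_metabolites, write_ranking

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "labels_to_reaction_pairs",
    "compute_feature_stack",
    "label_pairs",
    "train",
    "rank",
    "run_pipeline",
]


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    compartment: str = "c"
    cv_threshold: float = 1.0
    feature_mode: str = "distance"  # distance | concat | constant:<c>
    strategy: str = "direct"  # potential | random-stitch | tanimoto | direct | random
    classifier: str = "rf"
    folds: int = 5
    repetitions: int = 100
    grid: dict | None = None
    score_threshold: int = 500
    min_positive_fraction: float = 0.5
    simulate: dict | None = None  # synthetic-data config; None = real inputs
    model_path: Path | None = None
    conditions_path: Path | None = None
    abundance_path: Path | None = None
    fluxes_path: Path | None = None  # skip pFBA when given
    scores_path: Path | None = None
    labels_path: Path | None = None
    fingerprints_path: Path | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_sidecar(artifact: Path, params: dict, inputs: list[Path]) -> None:
    meta = {
        "artifact": artifact.name,
        "params": params,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    artifact.with_suffix(artifact.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1, default=str)
    )


def labels_to_reaction_pairs(
    labels: LabelSet, model: MetabolicModel
) -> LabelSet:
    """Transfer (metabolite, protein) labels onto (metabolite, reaction) pairs.

    A reaction pair is positive if any protein of the reaction interacts
    with the metabolite; it is negative only if some protein is labeled
    negative and none positive (GPR-mediated transfer).
    """
    gene_to_rxns: dict[str, list[str]] = {}
    for rxn in model.reactions:
        for g in rxn.genes():
            gene_to_rxns.setdefault(g, []).append(rxn.id)
    out: dict[tuple[str, str], int] = {}
    for (met, prot), lab in sorted(labels.labels.items()):
        for rxn_id in gene_to_rxns.get(prot, []):
            key = (met, rxn_id)
            out[key] = max(out.get(key, 0), lab)
    return LabelSet(labels=out, strategy=labels.strategy, notes=dict(labels.notes))


@dataclass
class FeatureStack:
    eta: EtaTable
    fluxsums: FluxSumTable
    report: FilterReport
    features: PairFeatureMatrix


def compute_feature_stack(
    model: MetabolicModel,
    fluxes: FluxTable,
    abundance: pd.DataFrame,
    compartment: str = "c",
    cv_threshold: float = 1.0,
    mode: str = "distance",
    constant: float = 0.0,
) -> FeatureStack:
    """fluxes + abundance -> eta, flux sums, CV filter, pair features."""
    enzyme = reaction_enzyme_abundance(model, abundance)
    eta = compute_eta(fluxes, enzyme)
    sums = flux_sum(model, fluxes, compartment)
    report = cv_filter(eta, sums, threshold=cv_threshold)
    features = build_pair_features(
        model, eta, sums, report, mode=mode, constant=constant
    )
    return FeatureStack(eta=eta, fluxsums=sums, report=report, features=features)


def label_pairs(
    config: RunConfig,
    model: MetabolicModel,
    features: PairFeatureMatrix,
    scores=None,
    fingerprints=None,
    direct=None,
) -> LabelSet:
    """Apply the configured labeling strategy on the (met, reaction) universe."""
    universe = set(features.pairs)
    if config.strategy == "direct":
        if direct is None:
            raise ValueError("direct strategy requires a label table")
        return labels_to_reaction_pairs(direct, model)
    if config.strategy == "random":
        return random_labeling(universe, seed=config.seed)
    if scores is None:
        raise ValueError(f"strategy {config.strategy!r} requires interaction scores")
    pair_scores = labels_to_reaction_pairs(
        LabelSet(
            labels={p: 1 for p in positives_from_scores(scores, config.score_threshold)},
            strategy="scores",
        ),
        model,
    )
    positives = {p for p in pair_scores.labels if p in universe}
    if config.strategy == "potential":
        assumed = universe - positives
        label_set, _ = potential_negative_labeling(
            features.values,
            positives,
            assumed,
            seed=config.seed,
        )
        return label_set
    if config.strategy == "random-stitch":
        labels: dict[tuple[str, str], int] = {p: 1 for p in positives}
        pos_mets = {m for m, _ in positives}
        pos_rxns = {r for _, r in positives}
        for pair in sorted(universe - positives):
            if pair[0] in pos_mets and pair[1] in pos_rxns:
                labels[pair] = 0
        return LabelSet(labels=labels, strategy="random-stitch")
    if config.strategy == "tanimoto":
        if fingerprints is None:
            raise ValueError("tanimoto strategy requires fingerprints")
        met_universe = {m for m, _ in universe}
        raw = tanimoto_labeling(positives={(m, r) for m, r in positives},
                                fingerprints=fingerprints,
                                candidates=met_universe)
        labels = {p: l for p, l in raw.labels.items() if p in universe or l == 1}
        return LabelSet(labels=labels, strategy="tanimoto")
    raise ValueError(f"unknown strategy {config.strategy!r}")


def train(
    features: PairFeatureMatrix, labels: LabelSet, config: RunConfig
) -> CVResult:
    cv = CVConfig(
        model_kind=config.classifier,
        folds=config.folds,
        repetitions=config.repetitions,
        grid=config.grid,
        seed=config.seed,
    )
    return balanced_cv(features, labels, cv)


def rank(result: CVResult, model: MetabolicModel, min_fraction: float = 0.5):
    """Aggregate out-of-fold predictions and rank metabolites."""
    positive_pairs = aggregate_predictions(result.oof_predictions, min_fraction)
    triples = map_pairs_to_proteins(model, positive_pairs)
    return rank_metabolites(triples)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages end to end; returns a result manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs (simulated or loaded) -----------------------------------
    scores = fingerprints = direct = None
    if config.simulate is not None:
        from .synthetic_data import generate_dataset

        bundle = generate_dataset(config.simulate, seed=config.seed, out_dir=out)
        model = bundle.model
        fluxes = bundle.fluxes
        abundance = bundle.abundance
        scores = bundle.scores
        fingerprints = bundle.fingerprints
        direct = bundle.labels
        conditions = bundle.conditions
        _write_sidecar(out / "model.json", {"seed": config.seed, **config.simulate},
                       [])
    else:
        for name in ("model_path", "conditions_path", "abundance_path"):
            p = getattr(config, name)
            if name != "conditions_path" or config.fluxes_path is None:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {p}")
        model = model_io.read_model(config.model_path)
        abundance = model_io.read_abundance(config.abundance_path)
        if config.fluxes_path is not None:
            fluxes = read_fluxes(config.fluxes_path)
            conditions = []
        else:
            conditions = model_io.read_conditions(config.conditions_path)
            fluxes = pfba_all(model, conditions)
        if config.scores_path:
            scores = read_scores(config.scores_path)
        if config.fingerprints_path:
            fingerprints = read_fingerprints(config.fingerprints_path)
        if config.labels_path:
            direct = load_direct_labels(config.labels_path)

    write_fluxes(fluxes, out / "fluxes_used.tsv")
    _write_sidecar(out / "fluxes_used.tsv", {"seed": config.seed}, [])

    # --- features --------------------------------------------------------
    mode, constant = config.feature_mode, 0.0
    if mode.startswith("constant"):
        if ":" in mode:
            constant = float(mode.split(":", 1)[1])
        mode = "constant-ablation"
    elif mode == "concat":
        mode = "concatenated"
    stack = compute_feature_stack(
        model,
        fluxes,
        abundance,
        compartment=config.compartment,
        cv_threshold=config.cv_threshold,
        mode=mode,
        constant=constant,
    )
    from .features import write_features

    write_features(stack.features, out / "features.tsv")
    _write_sidecar(
        out / "features.tsv",
        {
            "mode": stack.features.mode,
            "conditions": stack.features.conditions,
            "cv_threshold": config.cv_threshold,
            "compartment": config.compartment,
        },
        [out / "fluxes_used.tsv"],
    )

    # --- labels ----------------------------------------------------------
    labels = label_pairs(config, model, stack.features,
                         scores=scores, fingerprints=fingerprints, direct=direct)
    write_labels(labels, out / "labels_used.tsv")
    _write_sidecar(out / "labels_used.tsv",
                   {"strategy": config.strategy, "seed": config.seed},
                   [out / "features.tsv"])

    # --- train / evaluate -------------------------------------------------
    result = train(stack.features, labels, config)
    summary = result.summary()
    (out / "metrics.json").write_text(json.dumps(summary, indent=1))
    result.per_fold.to_csv(out / "metrics_per_fold.tsv", sep="\t", index=False)
    _write_sidecar(out / "metrics.json",
                   {"classifier": config.classifier, "folds": config.folds,
                    "repetitions": config.repetitions, "seed": config.seed},
                   [out / "features.tsv", out / "labels_used.tsv"])

    # --- rank -------------------------------------------------------------
    ranking = rank(result, model, config.min_positive_fraction)
    write_ranking(ranking, out / "ranking.tsv")
    _write_sidecar(out / "ranking.tsv",
                   {"min_positive_fraction": config.min_positive_fraction},
                   [out / "metrics.json"])
    return {
        "metrics": summary,
        "n_pairs": len(labels.labels),
        "n_features": stack.features.values.shape[1],
        "ranking_rows": len(ranking),
        "out_dir": str(out),
    }
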
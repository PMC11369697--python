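"""Shared fixtures: toy models and the default synthetic study."""

from __future__ import annotations

import pytest

from mpiflux.labeling import LabelSet
from mpiflux.model_io import MetabolicModel, Reaction
from mpiflux.pipeline import compute_feature_stack, labels_to_reaction_pairs
from mpiflux.synthetic_data import generate_dataset

# CV filter threshold used throughout the synthetic study (decouples filter
# strictness from signal recovery; see docs/methods.md).
SYNTH_CV_THRESHOLD = 0.5

# Random-forest settings used for the synthetic-study evaluations.
RF_GRID = {"n_estimators": [300], "min_samples_leaf": [2]}


def make_chain_model(uptake_ub: float = 10.0) -> MetabolicModel:
    """Linear chain: EX -> A -> B -> biomass, single gene per step."""
    return MetabolicModel(
        metabolites=(("A", "c"), ("B", "c")),
        reactions=(
            Reaction("EX", {"A": 1.0}, 0.0, uptake_ub),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, gpr="g1"),
            Reaction("BM", {"B": -1.0}, 0.0, 1000.0, objective_weight=1.0),
        ),
        genes=("g1",),
        id="chain",
    )


@pytest.fixture(scope="session")
def chain_model() -> MetabolicModel:
    return make_chain_model()


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study (J=12, 4 branches, 40 planted pairs)."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_stack(default_bundle):
    return compute_feature_stack(
        default_bundle.model,
        default_bundle.fluxes,
        default_bundle.abundance,
        cv_threshold=SYNTH_CV_THRESHOLD,
    )


@pytest.fixture(scope="session")
def direct_reaction_labels(default_bundle, default_stack) -> LabelSet:
    """Truth-mirroring labels restricted to the retained pair universe."""
    mapped = labels_to_reaction_pairs(default_bundle.labels, default_bundle.model)
    universe = set(default_stack.features.pairs)
    return LabelSet(
        labels={p: l for p, l in mapped.labels.items() if p in universe},
        strategy="direct",
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Same study with zero abundance noise, for closed-loop identities."""
    return generate_dataset({"sigma": 0.0}, seed=5)
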
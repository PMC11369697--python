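"""Flux sums, eta values, CV filter and pair-feature construction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpiflux.features import (
    build_pair_features,
    compute_eta,
    concatenated_features,
    constant_ablation_features,
    cv_filter,
    distance_features,
    flux_sum,
    max_normalize,
)
from mpiflux.flux_estimation import FluxTable
from mpiflux.model_io import MetabolicModel, Reaction


def _flux_table(values: dict[str, list[float]], conditions: list[str]) -> FluxTable:
    return FluxTable(values=pd.DataFrame(values, index=conditions).T)


# ---------------------------------------------------------------------------
# Flux sums
# ---------------------------------------------------------------------------


def test_flux_sum_balanced_metabolite():
    model = MetabolicModel(
        metabolites=(("B", "c"),),
        reactions=(
            Reaction("prod", {"B": 1.0}, 0.0, 100.0),
            Reaction("cons", {"B": -1.0}, 0.0, 100.0, objective_weight=1.0),
        ),
        genes=(),
    )
    table = _flux_table({"prod": [10.0], "cons": [10.0]}, ["c1"])
    sums = flux_sum(model, table, "c")
    assert sums.raw.loc["B", "c1"] == pytest.approx(10.0)


def test_flux_sum_weighted_coefficients():
    model = MetabolicModel(
        metabolites=(("M", "c"),),
        reactions=(
            Reaction("r1", {"M": 2.0}, 0.0, 100.0),
            Reaction("r2", {"M": -1.0}, 0.0, 100.0),
            Reaction("r3", {"M": -1.0}, 0.0, 100.0, objective_weight=1.0),
        ),
        genes=(),
    )
    table = _flux_table({"r1": [3.0], "r2": [4.0], "r3": [2.0]}, ["c1"])
    # half of (|2|*3 + |-1|*4 + |-1|*2) = 6
    assert flux_sum(model, table, "c").raw.loc["M", "c1"] == pytest.approx(6.0)


def test_flux_sum_untouched_metabolite_flagged(chain_model):
    table = _flux_table({"EX": [0.0], "R1": [0.0], "BM": [0.0]}, ["c1"])
    sums = flux_sum(chain_model, table, "c")
    assert set(sums.dropped) == {"A", "B"}


def test_flux_sum_unknown_compartment(chain_model):
    table = _flux_table({"EX": [1.0], "R1": [1.0], "BM": [1.0]}, ["c1"])
    with pytest.raises(ValueError, match="'c'"):
        flux_sum(chain_model, table, "nucleus")


def test_flux_sum_equals_production_and_consumption(default_bundle):
    """At steady state, M is both total production and total consumption."""
    model = default_bundle.model
    fluxes = default_bundle.fluxes
    sums = flux_sum(model, fluxes, "c")
    S = model.stoichiometric_matrix()
    V = fluxes.values.loc[S.columns]
    for met in ("hub", "pre", "tl1"):
        contrib = S.loc[met].to_numpy()[:, None] * V.to_numpy()
        production = np.clip(contrib, 0, None).sum(axis=0)
        consumption = -np.clip(contrib, None, 0).sum(axis=0)
        assert production == pytest.approx(consumption, abs=1e-6)
        assert sums.raw.loc[met].to_numpy() == pytest.approx(production, abs=1e-6)


# ---------------------------------------------------------------------------
# Eta
# ---------------------------------------------------------------------------


def test_eta_basic_profile():
    fluxes = _flux_table({"R": [2.0, 4.0, 1.0]}, ["a", "b", "c"])
    E = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]}, index=["R"])
    eta = compute_eta(fluxes, E)
    assert eta.kcat["R"] == pytest.approx(4.0)
    assert eta.eta.loc["R"].tolist() == pytest.approx([0.5, 1.0, 0.25])


def test_eta_zero_flux_and_zero_abundance():
    fluxes = _flux_table({"R": [0.0, 4.0]}, ["a", "b"])
    E = pd.DataFrame({"a": [0.0], "b": [2.0]}, index=["R"])
    eta = compute_eta(fluxes, E)
    assert np.isnan(eta.eta.loc["R", "a"])  # E = 0: undefined
    assert eta.eta.loc["R", "b"] == pytest.approx(1.0)


def test_eta_drops_dead_reactions():
    fluxes = _flux_table({"R": [0.0, 0.0], "Q": [1.0, 2.0]}, ["a", "b"])
    E = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]}, index=["R", "Q"])
    eta = compute_eta(fluxes, E)
    assert eta.dropped == ["R"]
    assert list(eta.eta.index) == ["Q"]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_eta_matches_elementwise_oracle(seed):
    rng = np.random.default_rng(seed)
    conds = [f"c{j}" for j in range(6)]
    rxns = [f"r{i}" for i in range(5)]
    v = pd.DataFrame(rng.uniform(0, 10, (5, 6)), index=rxns, columns=conds)
    E = pd.DataFrame(rng.uniform(0.1, 5, (5, 6)), index=rxns, columns=conds)
    eta = compute_eta(FluxTable(values=v), E)
    for r in rxns:
        kapp = [abs(v.loc[r, c]) / E.loc[r, c] for c in conds]
        kcat = max(kapp)
        for c, ka in zip(conds, kapp):
            assert eta.eta.loc[r, c] == pytest.approx(ka / kcat)
        assert eta.eta.loc[r].max() == pytest.approx(1.0)


def test_max_normalize():
    assert max_normalize([2.0, 4.0, 1.0]).tolist() == pytest.approx([0.5, 1.0, 0.25])
    assert max_normalize([1.0, 1.0]).tolist() == [1.0, 1.0]
    with pytest.raises(ValueError, match="drop"):
        max_normalize([0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# CV filter
# ---------------------------------------------------------------------------


def _tables_for_cv(eta_rows: dict, m_rows: dict, conds: list[str]):
    fluxes = FluxTable(values=pd.DataFrame(eta_rows, index=conds).T)
    E = pd.DataFrame(1.0, index=list(eta_rows), columns=conds)
    eta = compute_eta(fluxes, E)

    class Sums:
        pass

    sums = Sums()
    sums.normalized = pd.DataFrame(m_rows, index=conds).T
    return eta, sums


def test_cv_filter_hand_computed_values():
    conds = ["a", "b", "c", "d"]
    eta, sums = _tables_for_cv(
        {"spiky": [1.0, 0.0, 0.0, 0.0], "flat": [1.0, 1.0, 1.0, 1.0]},
        {"m": [1.0, 0.0, 0.0, 0.0]},
        conds,
    )
    report = cv_filter(eta, sums, threshold=1.0)
    # profile (1,0,0,0): mean 0.25, sample sd 0.5 -> CV = 2
    assert report.cv_eta["spiky"] == pytest.approx(2.0)
    assert report.cv_eta["flat"] == pytest.approx(0.0)
    assert ("m", "spiky") in report.retained
    assert all(rxn != "flat" for _, rxn in report.retained)


def test_cv_filter_zero_threshold_keeps_everything():
    conds = ["a", "b", "c"]
    eta, sums = _tables_for_cv(
        {"r1": [1.0, 0.5, 0.2], "r2": [0.3, 0.3, 0.31]},
        {"m1": [1.0, 0.9, 0.8]},
        conds,
    )
    report = cv_filter(eta, sums, threshold=0.0)
    assert len(report.retained) == 2
    assert report.removed == []


def test_cv_filter_monotone_in_threshold(default_stack, default_bundle):
    eta, sums = default_stack.eta, default_stack.fluxsums
    kept_sets = []
    for thr in (0.0, 0.5, 1.0, 2.0):
        kept_sets.append(set(cv_filter(eta, sums, threshold=thr).retained))
    for lo, hi in zip(kept_sets, kept_sets[1:]):
        assert hi <= lo


def test_cv_filter_needs_two_conditions():
    eta, sums = _tables_for_cv({"r": [1.0]}, {"m": [1.0]}, ["only"])
    with pytest.raises(ValueError, match="2"):
        cv_filter(eta, sums)


# ---------------------------------------------------------------------------
# Pair features
# ---------------------------------------------------------------------------


def test_distance_single_pair_is_sqrt2():
    out = distance_features([0.0, 1.0], [0.0, 1.0])
    assert out.tolist() == pytest.approx([np.sqrt(2)])


def test_distance_identical_profiles_zero():
    out = distance_features([0.3] * 5, [0.7] * 5)
    assert out.tolist() == pytest.approx([0.0] * 10)


@pytest.mark.parametrize("J, length", [(12, 66), (19, 171), (26, 325), (31, 465)])
def test_distance_feature_lengths(J, length):
    rng = np.random.default_rng(J)
    out = distance_features(rng.uniform(size=J), rng.uniform(size=J))
    assert len(out) == length
    assert (out >= 0).all() and (out <= np.sqrt(2) + 1e-12).all()


def test_distance_matches_double_loop_oracle():
    rng = np.random.default_rng(42)
    e, m = rng.uniform(size=5), rng.uniform(size=5)
    out = distance_features(e, m)
    expected = [
        np.sqrt((e[n] - e[k]) ** 2 + (m[n] - m[k]) ** 2)
        for n in range(5)
        for k in range(n + 1, 5)
    ]
    assert out.tolist() == pytest.approx(expected)


def test_constant_ablation():
    e = np.array([1.0, 0.4, 0.4])
    assert constant_ablation_features(e, 0.0).tolist() == pytest.approx([0.6, 0.6, 0.0])
    flat = constant_ablation_features(np.full(4, 0.5), 0.3)
    assert flat.tolist() == pytest.approx([0.3] * 6)
    rng = np.random.default_rng(7)
    e = rng.uniform(size=6)
    out = constant_ablation_features(e, 0.5)
    expected = [
        np.sqrt((e[n] - e[k]) ** 2 + 0.25) for n in range(6) for k in range(n + 1, 6)
    ]
    assert out.tolist() == pytest.approx(expected)


def test_concatenated_features_layout():
    out = concatenated_features([1.0, 0.5, 0.25], [0.2, 1.0, 0.4])
    assert out.tolist() == [1.0, 0.5, 0.25, 0.2, 1.0, 0.4]
    with pytest.raises(ValueError, match="mismatch"):
        concatenated_features([1.0], [1.0, 2.0])


def test_distance_invariant_under_condition_reordering():
    rng = np.random.default_rng(3)
    e, m = rng.uniform(size=6), rng.uniform(size=6)
    perm = rng.permutation(6)
    base = set(np.round(distance_features(e, m), 12))
    permuted = set(np.round(distance_features(e[perm], m[perm]), 12))
    assert base == permuted


def test_build_pair_features_matches_single_pair_ops(default_stack):
    feats = default_stack.features
    eta_n = default_stack.eta.eta_normalized
    m_n = default_stack.fluxsums.normalized
    conds = feats.conditions
    rng = np.random.default_rng(0)
    pairs = feats.pairs
    for i in rng.choice(len(pairs), size=10, replace=False):
        met, rxn = pairs[i]
        expected = distance_features(
            eta_n.loc[rxn, conds].to_numpy(float), m_n.loc[met, conds].to_numpy(float)
        )
        got = feats.values.loc[f"{met}:{rxn}"].to_numpy()
        assert got == pytest.approx(expected)


def test_build_pair_features_counts(default_stack):
    feats = default_stack.features
    mets = {m for m, _ in feats.pairs}
    rxns = {r for _, r in feats.pairs}
    assert len(feats.pairs) == len(mets) * len(rxns)  # Cartesian pairing
    J = len(feats.conditions)
    assert feats.values.shape[1] == J * (J - 1) // 2


def test_eta_normalized_max_is_one(default_stack):
    maxima = default_stack.eta.eta_normalized.max(axis=1)
    assert maxima.to_numpy() == pytest.approx(np.ones(len(maxima)))
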
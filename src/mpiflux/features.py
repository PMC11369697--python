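"""Flux-sum and eta feature engineering for metabolite-reaction pairs.

The two condition profiles behind every pair feature are

* the flux sum ``M[k, j] = 1/2 * sum_r |S[k, r]| * v[r, j]`` of metabolite
  ``k`` — half the total absolute flux through the metabolite, a proxy for
  its turnover / concentration, computed per cellular compartment; and
* the capacity-utilization fraction ``eta[i, j] = v[i, j] / (E[i, j] *
  kcat[i])`` of reaction ``i``, where the in-vivo turnover proxy ``kcat[i]``
  is the maximum apparent catalytic rate ``kapp = |v| / E`` across
  conditions, so ``eta`` lies in [0, 1] and carries the signature of
  metabolite-level regulation of the enzyme.

Both profiles are max-normalized across conditions, flat profiles are
removed by a coefficient-of-variation filter, and each retained
(metabolite, reaction) pair is turned into a feature vector: the pairwise
Euclidean distances between its per-condition points ``(eta~, M~)`` in the
unit square (upper triangle of the distance matrix, diagonal excluded),
or one of the ablation variants (constant replacement, plain concatenation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .flux_estimation import FluxTable
from .model_io import MetabolicModel

__all__ = [
    "FluxSumTable",
    "EtaTable",
    "FilterReport",
    "PairFeatureMatrix",
    "flux_sum",
    "compute_eta",
    "max_normalize",
    "cv_filter",
    "distance_features",
    "constant_ablation_features",
    "concatenated_features",
    "build_pair_features",
]


@dataclass
class FluxSumTable:
    raw: pd.DataFrame  # metabolite x condition, >= 0
    normalized: pd.DataFrame  # max-normalized rows, in [0, 1]
    compartment: str
    dropped: list[str] = field(default_factory=list)  # all-zero metabolites


@dataclass
class EtaTable:
    kapp: pd.DataFrame  # reaction x condition, NaN where E undefined/zero
    kcat: pd.Series  # per reaction, max kapp across conditions
    eta: pd.DataFrame  # kapp / kcat, in [0, 1]
    eta_normalized: pd.DataFrame  # equals eta up to float tolerance
    dropped: list[str] = field(default_factory=list)  # kcat == 0 or all-NaN


@dataclass
class FilterReport:
    cv_eta: pd.Series  # per reaction
    cv_fluxsum: pd.Series  # per metabolite
    retained: list[tuple[str, str]]  # (metabolite, reaction)
    removed: list[tuple[str, str, str]]  # (metabolite, reaction, reason)
    threshold: float = 1.0
    conditions: list[str] = field(default_factory=list)


@dataclass
class PairFeatureMatrix:
    values: pd.DataFrame  # index "metabolite:reaction", feature columns
    mode: str  # distance | concatenated | constant-ablation
    conditions: list[str]
    constant: float | None = None

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(key.split(":", 1)) for key in self.values.index]


def flux_sum(model: MetabolicModel, fluxes: FluxTable, compartment: str) -> FluxSumTable:
    """Raw and max-normalized flux sums for one compartment's metabolites."""
    if compartment not in model.compartments:
        raise ValueError(
            f"unknown compartment {compartment!r}; model has {model.compartments}"
        )
    mets = [m for m, c in model.metabolites if c == compartment]
    v = fluxes.values
    raw = pd.DataFrame(0.0, index=mets, columns=v.columns)
    for rxn in model.reactions:
        if rxn.id not in v.index:
            continue
        flux_row = v.loc[rxn.id].abs()
        for met, coef in rxn.stoich.items():
            if met in raw.index:
                raw.loc[met] += 0.5 * abs(coef) * flux_row
    dropped = [m for m in mets if (raw.loc[m] == 0).all()]
    kept = raw.drop(index=dropped)
    normalized = kept.div(kept.max(axis=1), axis=0)
    return FluxSumTable(
        raw=raw, normalized=normalized, compartment=compartment, dropped=dropped
    )


def compute_eta(fluxes: FluxTable, enzyme_abundance: pd.DataFrame) -> EtaTable:
    """Apparent catalytic rates, per-reaction kcat proxies, and eta values.

    ``kapp = |v| / E`` where the enzyme abundance is positive (NaN
    elsewhere); ``kcat`` is the per-reaction maximum of ``kapp`` across
    conditions; ``eta = kapp / kcat``. Reactions with no defined ``kapp``
    entry or with ``kcat == 0`` are dropped and reported.
    """
    shared = [c for c in fluxes.values.columns if c in enzyme_abundance.columns]
    if not shared:
        raise ValueError("flux and abundance tables share no conditions")
    rxns = [r for r in fluxes.values.index if r in enzyme_abundance.index]
    v = fluxes.values.loc[rxns, shared].abs()
    E = enzyme_abundance.loc[rxns, shared]
    kapp = v.where(E > 0) / E.where(E > 0)
    kcat = kapp.max(axis=1)
    dropped = list(kapp.index[(kcat.isna()) | (kcat == 0)])
    kapp = kapp.drop(index=dropped)
    kcat = kcat.drop(index=dropped)
    if kapp.empty:
        raise ValueError("no reaction has a defined, nonzero kcat proxy")
    eta = kapp.div(kcat, axis=0)
    # kcat is the row maximum, so eta is already max-normalized
    eta_normalized = eta.div(eta.max(axis=1), axis=0)
    return EtaTable(
        kapp=kapp, kcat=kcat, eta=eta, eta_normalized=eta_normalized, dropped=dropped
    )


def max_normalize(profile: np.ndarray | pd.Series) -> np.ndarray:
    """Divide a non-negative profile by its maximum; all-zero profiles raise.

    An all-zero profile carries no information and must be dropped by the
    caller rather than silently normalized.
    """
    arr = np.asarray(profile, dtype=float)
    top = np.nanmax(arr) if arr.size else 0.0
    if not top > 0:
        raise ValueError("all-zero profile cannot be max-normalized; drop it")
    return arr / top


def _cv(profile: np.ndarray) -> float:
    """Coefficient of variation with sample standard deviation (ddof=1)."""
    mean = profile.mean()
    if mean == 0:
        return np.inf
    return float(profile.std(ddof=1) / mean)


def cv_filter(
    eta: EtaTable, fluxsums: FluxSumTable, threshold: float = 1.0
) -> FilterReport:
    """Retain (metabolite, reaction) pairs whose both profiles vary enough.

    The coefficient of variation (sample sd / mean, over conditions) is
    computed on the normalized profiles; a pair survives iff both its eta
    CV and its flux-sum CV are >= threshold. Pairs with incomplete eta
    profiles (NaN in some retained condition) are removed: the distance
    features need every coordinate.
    """
    conditions = [c for c in eta.eta_normalized.columns if c in fluxsums.normalized.columns]
    if len(conditions) < 2:
        raise ValueError("CV undefined with fewer than 2 shared conditions")
    etan = eta.eta_normalized[conditions]
    msn = fluxsums.normalized[conditions]
    cv_eta = etan.apply(lambda row: _cv(row.to_numpy()) if not row.isna().any() else np.nan, axis=1)
    cv_m = msn.apply(lambda row: _cv(row.to_numpy()), axis=1)
    retained: list[tuple[str, str]] = []
    removed: list[tuple[str, str, str]] = []
    for met in msn.index:
        for rxn in etan.index:
            if np.isnan(cv_eta[rxn]):
                removed.append((met, rxn, "incomplete eta profile"))
            elif cv_eta[rxn] < threshold:
                removed.append((met, rxn, f"cv_eta {cv_eta[rxn]:.3f} < {threshold}"))
            elif cv_m[met] < threshold:
                removed.append((met, rxn, f"cv_fluxsum {cv_m[met]:.3f} < {threshold}"))
            else:
                retained.append((met, rxn))
    return FilterReport(
        cv_eta=cv_eta,
        cv_fluxsum=cv_m,
        retained=retained,
        removed=removed,
        threshold=threshold,
        conditions=conditions,
    )


def _check_profiles(*profiles: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = tuple(np.asarray(p, dtype=float) for p in profiles)
    lengths = {a.shape[0] for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"profile length mismatch: {sorted(lengths)}")
    for a in arrs:
        if np.isnan(a).any():
            raise ValueError("profile contains undefined (NaN) entries")
    return arrs


def distance_features(eta_profile, fluxsum_profile) -> np.ndarray:
    """Upper-triangle pairwise distances of the per-condition unit-square points.

    For conditions n < m the feature is the Euclidean distance between
    points (eta~[n], M~[n]) and (eta~[m], M~[m]); entries are concatenated
    row-major and bounded by sqrt(2).
    """
    e, m = _check_profiles(eta_profile, fluxsum_profile)
    de = e[:, None] - e[None, :]
    dm = m[:, None] - m[None, :]
    D = np.sqrt(de**2 + dm**2)
    iu = np.triu_indices(len(e), k=1)
    return D[iu]


def constant_ablation_features(eta_profile, c: float = 0.0) -> np.ndarray:
    """Distance features with the flux-sum difference replaced by a constant."""
    (e,) = _check_profiles(eta_profile)
    de = e[:, None] - e[None, :]
    D = np.sqrt(de**2 + c**2)
    iu = np.triu_indices(len(e), k=1)
    return D[iu]


def concatenated_features(eta_profile, fluxsum_profile) -> np.ndarray:
    """Plain concatenation [eta~_1..J, M~_1..J] in condition order."""
    e, m = _check_profiles(eta_profile, fluxsum_profile)
    return np.concatenate([e, m])


def build_pair_features(
    model: MetabolicModel,
    eta: EtaTable,
    fluxsums: FluxSumTable,
    report: FilterReport,
    mode: str = "distance",
    constant: float = 0.0,
) -> PairFeatureMatrix:
    """One feature row per retained (metabolite, reaction) pair."""
    if not report.retained:
        raise ValueError("no pair survived the CV filter")
    conditions = report.conditions
    J = len(conditions)
    if mode == "distance":
        ncols = J * (J - 1) // 2
        names = [f"d_{conditions[n]}_{conditions[m]}" for n in range(J) for m in range(n + 1, J)]
    elif mode == "constant-ablation":
        ncols = J * (J - 1) // 2
        names = [f"d_{conditions[n]}_{conditions[m]}" for n in range(J) for m in range(n + 1, J)]
    elif mode == "concatenated":
        ncols = 2 * J
        names = [f"eta_{c}" for c in conditions] + [f"M_{c}" for c in conditions]
    else:
        raise ValueError(f"unknown feature mode {mode!r}")

    rows = np.empty((len(report.retained), ncols))
    keys = []
    for i, (met, rxn) in enumerate(report.retained):
        e = eta.eta_normalized.loc[rxn, conditions].to_numpy(dtype=float)
        m = fluxsums.normalized.loc[met, conditions].to_numpy(dtype=float)
        if mode == "distance":
            rows[i] = distance_features(e, m)
        elif mode == "constant-ablation":
            rows[i] = constant_ablation_features(e, constant)
        else:
            rows[i] = concatenated_features(e, m)
        keys.append(f"{met}:{rxn}")
    values = pd.DataFrame(rows, index=keys, columns=names)
    return PairFeatureMatrix(
        values=values,
        mode=mode,
        conditions=conditions,
        constant=constant if mode == "constant-ablation" else None,
    )


def write_features(matrix: PairFeatureMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="pair")


def read_features(path: str | Path, mode: str, conditions: list[str]) -> PairFeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairFeatureMatrix(values=df, mode=mode, conditions=conditions)
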
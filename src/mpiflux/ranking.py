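"""Ranking metabolites by the number of distinct reactions they regulate.

A metabolite's regulatory reach is summarized as the count of distinct
reactions appearing among its predicted-positive (metabolite, protein,
reaction) triples: a metabolite interacting with several isozymes of one
reaction is counted once for that reaction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["rank_metabolites", "aggregate_predictions", "write_ranking"]


def rank_metabolites(
    predicted_positives: Iterable[tuple[str, str, str]]
) -> pd.DataFrame:
    """Count distinct regulated reactions per metabolite.

    Returns a DataFrame with columns ``metabolite``, ``n_reactions`` and
    ``reactions`` (semicolon-joined sorted ids), sorted by descending
    count with ties broken by metabolite id.
    """
    by_met: dict[str, set[str]] = {}
    for met, _protein, rxn in predicted_positives:
        by_met.setdefault(met, set()).add(rxn)
    rows = [
        (met, len(rxns), ";".join(sorted(rxns)))
        for met, rxns in by_met.items()
    ]
    df = pd.DataFrame(rows, columns=["metabolite", "n_reactions", "reactions"])
    return df.sort_values(
        ["n_reactions", "metabolite"], ascending=[False, True], ignore_index=True
    )


def aggregate_predictions(
    oof_predictions: pd.DataFrame, min_fraction: float = 0.5
) -> list[tuple[str, str]]:
    """Pairs predicted positive in at least ``min_fraction`` of repetitions.

    ``oof_predictions`` is the pair x repetition out-of-fold 0/1 matrix of
    a CV run (entries -1 where a pair was never tested are ignored).
    """
    pairs: list[tuple[str, str]] = []
    for key, row in oof_predictions.iterrows():
        valid = row[row >= 0]
        if len(valid) and (valid == 1).mean() >= min_fraction:
            met, prot = key.split(":", 1)
            pairs.append((met, prot))
    return pairs


def write_ranking(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
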
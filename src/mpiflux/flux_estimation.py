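"""Condition-specific flux estimation with parsimonious FBA.

pFBA is a two-stage linear program: stage 1 fixes the biomass flux (to the
measured growth rate when given, otherwise to the maximal achievable
objective value); stage 2 minimizes the total absolute flux sum over all
reactions at that biomass, using the standard split of each flux into
non-negative forward and reverse parts (v = v+ - v-, minimize sum(v+ + v-)).

Both LPs are solved with the HiGHS solver through scipy. Feasibility is
checked to FEASIBILITY_TOL; LP optimality to OPTIMALITY_TOL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model_io import Condition, MetabolicModel, gpr_is_active

__all__ = [
    "FEASIBILITY_TOL",
    "OPTIMALITY_TOL",
    "InfeasibleError",
    "PfbaSolution",
    "FluxTable",
    "apply_condition",
    "pfba",
    "pfba_all",
    "read_fluxes",
    "write_fluxes",
]

FEASIBILITY_TOL = 1e-6
OPTIMALITY_TOL = 1e-9


class InfeasibleError(RuntimeError):
    """The constrained model admits no feasible flux distribution."""

    def __init__(self, message: str, status: str = "infeasible"):
        super().__init__(message)
        self.status = status


@dataclass(frozen=True)
class PfbaSolution:
    fluxes: pd.Series  # indexed by reaction id
    biomass: float  # stage-1 objective value (fixed growth if measured)
    total_flux: float  # stage-2 objective sum |v|
    status: str  # "optimal"


@dataclass
class FluxTable:
    """Reaction-by-condition flux matrix with per-condition solver status."""

    values: pd.DataFrame
    status: dict[str, str] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


def apply_condition(model: MetabolicModel, condition: Condition) -> MetabolicModel:
    """Constrain a model to one condition.

    Knockouts close every reaction whose GPR cannot be satisfied without the
    knocked-out genes; uptake and measured flux bounds overwrite the model
    defaults; a measured growth rate fixes the biomass reaction exactly
    (lb = ub = growth_rate).
    """
    known = set(model.reaction_ids)
    for rxn_id in list(condition.uptake_bounds) + list(condition.measured_flux_bounds):
        if rxn_id not in known:
            raise KeyError(f"condition {condition.id!r}: unknown reaction {rxn_id!r}")
    new_reactions = []
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if condition.knockouts and not gpr_is_active(rxn.gpr_units, condition.knockouts):
            lb, ub = 0.0, 0.0
        if rxn.id in condition.uptake_bounds:
            lb, ub = condition.uptake_bounds[rxn.id]
        if rxn.id in condition.measured_flux_bounds:
            lb, ub = condition.measured_flux_bounds[rxn.id]
        if condition.growth_rate is not None and rxn.objective_weight != 0:
            lb = ub = condition.growth_rate
        if lb > ub:
            raise ValueError(
                f"condition {condition.id!r}: reaction {rxn.id!r} gets lb {lb} > ub {ub}"
            )
        new_reactions.append(replace(rxn, lower_bound=lb, upper_bound=ub))
    return model.with_reactions(new_reactions)


def _stoich_csr(model: MetabolicModel) -> sparse.csr_matrix:
    rows, cols, data = [], [], []
    met_index = {m: i for i, (m, _) in enumerate(model.metabolites)}
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoich.items():
            rows.append(met_index[met])
            cols.append(j)
            data.append(coef)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def pfba(model: MetabolicModel, fixed_biomass: float | None = None) -> PfbaSolution:
    """Two-stage parsimonious FBA on an (already constrained) model.

    Parameters
    ----------
    model
        Constrained model (e.g. from :func:`apply_condition`).
    fixed_biomass
        Skip stage 1 and fix the biomass flux directly (used when the
        growth rate is measured). When ``None`` the biomass bound structure
        decides: if biomass lb == ub the value is already fixed, otherwise
        stage 1 maximizes the objective.
    """
    n = len(model.reactions)
    S = _stoich_csr(model)
    b = np.zeros(S.shape[0])
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c_obj = np.array([r.objective_weight for r in model.reactions])

    # stage 1: maximal (or fixed) biomass
    if fixed_biomass is None:
        res1 = linprog(
            -c_obj,
            A_eq=S,
            b_eq=b,
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={"primal_feasibility_tolerance": OPTIMALITY_TOL},
        )
        if res1.status == 3:
            raise InfeasibleError("stage-1 objective unbounded", status="unbounded")
        if res1.status != 0:
            raise InfeasibleError(
                f"stage-1 FBA infeasible (solver status {res1.status})"
            )
        biomass = float(-res1.fun)
    else:
        biomass = float(fixed_biomass)

    # stage 2: minimize sum |v| at fixed biomass via forward/reverse split
    bio_idx = [i for i, r in enumerate(model.reactions) if r.objective_weight != 0]
    lb2, ub2 = lb.copy(), ub.copy()
    for i in bio_idx:
        w = model.reactions[i].objective_weight
        # single-objective models: fix the flux achieving c.v = biomass
        lb2[i] = ub2[i] = biomass / w if len(bio_idx) == 1 else lb2[i]
    if len(bio_idx) > 1:  # general case: add the objective as an equality row
        S = sparse.vstack([S, sparse.csr_matrix(c_obj)])
        b = np.append(b, biomass)

    # variables [p; m] >= 0 with v = p - m
    Ssplit = sparse.hstack([S, -S], format="csr")
    p_lb = np.maximum(lb2, 0.0)
    p_ub = np.maximum(ub2, 0.0)
    m_lb = np.maximum(-ub2, 0.0)
    m_ub = np.maximum(-lb2, 0.0)
    bounds = np.column_stack(
        [np.concatenate([p_lb, m_lb]), np.concatenate([p_ub, m_ub])]
    )
    res2 = linprog(
        np.ones(2 * n),
        A_eq=Ssplit,
        b_eq=b,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": OPTIMALITY_TOL},
    )
    if res2.status != 0:
        raise InfeasibleError(
            f"stage-2 pFBA infeasible at biomass {biomass:g} "
            f"(solver status {res2.status})"
        )
    v = res2.x[:n] - res2.x[n:]
    fluxes = pd.Series(v, index=model.reaction_ids)

    resid = np.abs(_stoich_csr(model) @ v).max() if n else 0.0
    if resid > FEASIBILITY_TOL:
        raise InfeasibleError(f"steady-state residual {resid:g} above tolerance")
    return PfbaSolution(
        fluxes=fluxes, biomass=biomass, total_flux=float(res2.fun), status="optimal"
    )


def pfba_all(model: MetabolicModel, conditions: Sequence[Condition]) -> FluxTable:
    """One pFBA flux column per condition; failures recorded, not raised.

    Raises only when every condition is infeasible.
    """
    if not conditions:
        raise ValueError("at least one condition required")
    columns: dict[str, pd.Series] = {}
    status: dict[str, str] = {}
    for cond in conditions:
        try:
            constrained = apply_condition(model, cond)
            sol = pfba(constrained)
        except InfeasibleError as exc:
            status[cond.id] = exc.status
            continue
        columns[cond.id] = sol.fluxes
        status[cond.id] = sol.status
    if not columns:
        raise InfeasibleError("all conditions infeasible")
    values = pd.DataFrame(columns)
    return FluxTable(values=values, status=status)


def read_fluxes(path: str | Path) -> FluxTable:
    """Load a flux table from TSV (reaction x condition), bypassing pFBA.

    Mirrors the abundance TSV layout; used when fluxes were estimated
    externally (e.g. by metabolic flux analysis).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FluxTable(values=df, status={c: "loaded" for c in df.columns})


def write_fluxes(table: FluxTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="reaction")
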
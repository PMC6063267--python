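"""Simulation of alignments under null and accelerated models, calibration
of acceleration strength, and the power / false-positive experiment.

Alignments are simulated column by column: the root state is drawn from the
equilibrium frequencies and states are propagated down the tree with the
transition matrix of each branch (neutral, or modified by the lineage's
(S, B) parameters). Columns are independent; there are no indels.

Acceleration strength is calibrated in expected substitutions per 100 bp on
the target branch. For unbiased acceleration the expected substitution rate
scales exactly by the fixation multiplier f(S), so the target is inverted
by monotone root finding; with GC bias the expected rate is computed against
the equilibrium distribution (an approximation to the parent-node state
distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.optimize

from .accel_models import (
    PARAM_BOUNDS,
    fixation_multiplier,
    lineage_rate_matrix,
)
from .model_selection import (
    ElementCall,
    SelectionConfig,
    finalize_call,
    select_model,
)
from .accel_models import enumerate_model_dag
from .phylo_core import (
    BASES,
    GenomicInterval,
    MultipleAlignment,
    NeutralModel,
    read_phast_mod,
    transition_matrix,
)

logger = logging.getLogger(__name__)

#: the five ape terminal branches screened for acceleration
APE_LINEAGES = ("hg19", "panTro4", "gorGor3", "ponAbe2", "nomLeu3")
#: primates excluded from the local GC-content estimate
PRIMATE_SPECIES = APE_LINEAGES + ("rheMac3", "calJac3")


def load_surrogate_model() -> NeutralModel:
    """Bundled 12-taxon neutral model (synthetic stand-in for the UCSC
    100-way model) used for offline simulation studies.

    Branch lengths are chosen so that at tree scale 0.1 — the conserved-
    element rescaling — the neutral expectation is about 0.6 substitutions
    per 100 bp on the human branch and 0.9 on the gorilla branch.
    """
    ref = resources.files("accelscan.data").joinpath("surrogate_12taxa.mod")
    with ref.open() as fh:
        return read_phast_mod(fh)


@dataclass
class SimulationConfig:
    """One power-experiment run: a scaled neutral model plus the simulated
    conditions (per-lineage targets in expected substitutions per 100 bp)."""

    model: NeutralModel
    conditions: Sequence[Mapping[str, float]]
    condition_labels: Optional[Sequence[str]] = None
    n_alignments: int = 100
    length: int = 100
    seed: int = 0
    #: optional per-lineage GC-bias coefficients, per condition
    b_values: Optional[Sequence[Mapping[str, float]]] = None

    def __post_init__(self):
        if self.n_alignments < 1 or self.length < 1:
            raise ValueError("n_alignments and length must be >= 1")
        for cond in self.conditions:
            if any(v < 0 for v in cond.values()):
                raise ValueError("targets must be nonnegative")
        if self.condition_labels is None:
            self.condition_labels = [
                "null" if not c else "+".join(
                    f"{l}@{v:g}" for l, v in sorted(c.items())
                )
                for c in self.conditions
            ]


def _sample_descendants(
    parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized categorical sampling of child states given parent states."""
    cdf = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    return (u[:, None] > cdf[parent_states]).sum(axis=1).astype(np.int64)


def simulate_alignment(
    model: NeutralModel,
    branch_params: Mapping[str, Tuple[float, float]],
    length: int,
    seed,
    return_internal: bool = False,
):
    """Simulate an alignment of ``length`` independent columns.

    ``branch_params`` maps a leaf name to its (S, B) acceleration
    parameters; all other branches evolve neutrally. ``seed`` may be an int
    or a :class:`numpy.random.Generator`. With ``return_internal`` the full
    node-state matrix is returned alongside the alignment.
    """
    tree = model.tree
    for lin in branch_params:
        if lin not in tree.leaf_index:
            raise ValueError(f"unknown lineage {lin!r} in branch_params")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    states = np.empty((len(tree.parent), length), dtype=np.int64)
    states[tree.root] = rng.choice(4, size=length, p=model.pi)
    P_neutral = model.branch_transition_matrices(1.0)
    # preorder = reversed postorder
    for v in reversed(tree.postorder):
        if v == tree.root:
            continue
        name = tree.names[v]
        if name in branch_params:
            S, B = branch_params[name]
            Qmod = lineage_rate_matrix(model.Q, S, B)
            P = transition_matrix(Qmod, tree.lengths[v])
        else:
            P = P_neutral[v]
        P = P / P.sum(axis=1, keepdims=True)
        states[v] = _sample_descendants(states[tree.parent[v]], P, rng)
    seqs = {
        name: "".join(BASES[s] for s in states[tree.leaf_index[name]])
        for name in tree.leaf_names
    }
    aln = MultipleAlignment(seqs, normalize=False)
    if return_internal:
        return aln, states
    return aln


def count_branch_substitutions(
    model: NeutralModel,
    lineage: str,
    S: float,
    B: float,
    n_sites: int,
    seed,
) -> np.ndarray:
    """Exact per-site substitution (jump) counts along one terminal branch.

    The parent-node state is drawn from the equilibrium distribution and the
    continuous-time chain is simulated with exponential waiting times, so
    multiple hits are counted — unlike parent/child state differences.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = model.tree.branch_length(lineage)
    Q = lineage_rate_matrix(model.Q, S, B)
    rates = -np.diag(Q)
    jump_probs = Q / rates[:, None]
    np.fill_diagonal(jump_probs, 0.0)
    counts = np.zeros(n_sites, dtype=np.int64)
    states = rng.choice(4, size=n_sites, p=model.pi)
    elapsed = np.zeros(n_sites)
    active = np.arange(n_sites)
    while active.size:
        waits = rng.exponential(1.0 / rates[states[active]])
        elapsed[active] += waits
        done = elapsed[active] > t
        jumping = active[~done]
        if jumping.size:
            for i in jumping:
                states[i] = rng.choice(4, p=jump_probs[states[i]])
            counts[jumping] += 1
        active = jumping
    return counts


def accel_from_expected_subs(
    model: NeutralModel, lineage: str, target: float
) -> float:
    """Solve for the unbiased coefficient S giving ``target`` expected
    substitutions per 100 bp on the lineage's terminal branch.

    Under unbiased acceleration the branch rate scales exactly by f(S), so
    S solves f(S) * t * 100 = target. A target at or below the neutral
    expectation returns S = 0 (with a warning when strictly below).
    """
    if lineage not in model.tree.leaf_index:
        raise ValueError(f"lineage {lineage!r} is not a leaf")
    t = model.tree.branch_length(lineage)
    if t <= 0:
        if target > 0:
            raise ValueError(
                f"cannot reach {target} substitutions on zero-length branch"
            )
        return 0.0
    neutral = 100.0 * t
    if target <= neutral:
        if target < neutral:
            logger.warning(
                "target %.3g below neutral expectation %.3g on %s; S=0",
                target, neutral, lineage,
            )
        return 0.0
    ratio = target / neutral

    def g(S):
        return fixation_multiplier(S) - ratio

    hi = PARAM_BOUNDS[1]
    if g(hi) < 0:
        raise ValueError(
            f"target {target} needs S > {hi} on branch {lineage}"
        )
    return float(scipy.optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-10))


def expected_subs_per_100bp(model: NeutralModel, lineage: str, S: float = 0.0,
                            B: float = 0.0) -> float:
    """Expected substitutions per 100 bp on a terminal branch, with the
    parent state at equilibrium."""
    t = model.tree.branch_length(lineage)
    Q = lineage_rate_matrix(model.Q, S, B)
    return float(-np.dot(model.pi, np.diag(Q)) * t * 100.0)


NO_ACCEL = "no_acceleration"
OTHER = "other"


def classify_call(call: ElementCall, simulated_lineages: Set[str]) -> str:
    """Category of a call relative to the simulated truth.

    The active-lineage set of the selected model (regardless of S vs. B)
    determines the label: empty -> no acceleration; any lineage outside the
    simulated set -> "other"; otherwise the sorted lineage names joined by
    '+'.
    """
    active = set(call.selected.spec.lineages)
    if not active:
        return NO_ACCEL
    if active - set(simulated_lineages):
        return OTHER
    return "+".join(sorted(active))


def run_power_experiment(
    config: SimulationConfig, selection: SelectionConfig
) -> pd.DataFrame:
    """Simulate each condition, run model selection, and tabulate the
    percentage of alignments annotated to each acceleration category.

    Child RNG streams are derived from (master seed, condition index,
    replicate index), so every condition is independently reproducible.
    Returns a DataFrame of percentages (rows = conditions, columns =
    categories) that sums to 100 per row.
    """
    model = config.model
    dag = enumerate_model_dag(selection.lineages, tree=model.tree)
    rows = {}
    for ci, cond in enumerate(config.conditions):
        params = {
            lin: (accel_from_expected_subs(model, lin, tgt), 0.0)
            for lin, tgt in cond.items()
            if tgt > 0
        }
        if config.b_values is not None:
            for lin, b in config.b_values[ci].items():
                S = params.get(lin, (0.0, 0.0))[0]
                params[lin] = (S, b)
        counts: Dict[str, int] = {}
        for ri in range(config.n_alignments):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, ci, ri])
            )
            aln = simulate_alignment(model, params, config.length, rng)
            result = select_model(aln, dag, model, selection)
            interval = GenomicInterval("sim", ri * config.length,
                                       (ri + 1) * config.length)
            call = finalize_call(
                result.selected, result.null_fit, interval, selection,
                recovered=result.recovered,
            )
            label = classify_call(call, set(params))
            counts[label] = counts.get(label, 0) + 1
        rows[config.condition_labels[ci]] = {
            k: 100.0 * v / config.n_alignments for k, v in counts.items()
        }
        logger.info("condition %s: %s", config.condition_labels[ci], counts)
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    ordered = sorted(c for c in table.columns if c not in (OTHER, NO_ACCEL))
    for tail in (OTHER, NO_ACCEL):
        if tail in table.columns:
            ordered.append(tail)
    return table[ordered]
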
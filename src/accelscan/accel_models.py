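"""Lineage-specific acceleration models and maximum-likelihood fitting.

Each candidate lineage (a terminal branch of the tree) carries two
nonnegative parameters: ``S`` for an unbiased substitution-rate increase
(positive selection or loss of constraint) and ``B`` for a GC-biased
increase (GC-biased gene conversion). Both act on the neutral rate matrix
through the eventual fixation probability of a mutation with
population-scaled coefficient ``x`` under the weak-mutation model,

    f(x) = x / (1 - exp(-x)),      f(0) = 1.

An off-diagonal neutral rate ``Q_ij`` on an accelerated branch becomes
``Q_ij * f(S + B * delta_ij)`` where ``delta_ij`` is +1 for weak->strong
substitutions (A/T -> G/C), -1 for strong->weak, and 0 within a class. The
matrix is deliberately not renormalized: acceleration increases the
expected number of substitutions rather than redistributing them.

The model space for ``n`` lineages is the set of all 2^(2n) subsets of
freed parameters, organised as a DAG whose edges add exactly one parameter.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

from .phylo_core import MultipleAlignment, NeutralModel, log_likelihood

logger = logging.getLogger(__name__)

#: indices of weak (A, T) and strong (C, G) bases in ACGT order
_WEAK = (0, 3)
_STRONG = (1, 2)

#: delta[i, j]: +1 weak->strong, -1 strong->weak, 0 within class
DELTA = np.zeros((4, 4))
for _i in _WEAK:
    for _j in _STRONG:
        DELTA[_i, _j] = 1.0
        DELTA[_j, _i] = -1.0

#: optimizer bounds: tree scale rho and population-scaled coefficients
RHO_BOUNDS = (1e-6, 100.0)
PARAM_BOUNDS = (0.0, 50.0)


def fixation_multiplier(x) -> float:
    """Relative fixation rate f(x) = x / (1 - e^{-x}) with f(0) = 1.

    Evaluated by series expansion near zero for numerical stability; strictly
    increasing and smooth everywhere.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("population-scaled coefficient must be finite")
    small = np.abs(x) < 1e-4
    with np.errstate(over="ignore", invalid="ignore"):
        exact = np.where(small, 1.0, x / -np.expm1(-np.where(small, 1.0, x)))
    series = 1.0 + x / 2.0 + x * x / 12.0
    out = np.where(small, series, exact)
    return float(out) if out.ndim == 0 else out


def lineage_rate_matrix(Q: np.ndarray, S: float, B: float) -> np.ndarray:
    """Rate matrix of an accelerated branch: Q'_ij = Q_ij * f(S + B*delta_ij).

    The diagonal is reset so rows sum to zero. No renormalization: positive
    S or B strictly increases the expected substitution rate.
    """
    if S < 0 or B < 0:
        raise ValueError(f"S and B must be nonnegative, got S={S}, B={B}")
    mult = fixation_multiplier(S + B * DELTA)
    Qp = np.asarray(Q, dtype=float) * mult
    np.fill_diagonal(Qp, 0.0)
    np.fill_diagonal(Qp, -Qp.sum(axis=1))
    return Qp


# ---------------------------------------------------------------------------
# Model specifications and the model DAG
# ---------------------------------------------------------------------------

_KIND_ORDER = {"S": 0, "B": 1}


@dataclass(frozen=True)
class ModelSpec:
    """A subset of freed acceleration parameters: lineages in ``K`` have a
    free unbiased parameter S, lineages in ``M`` a free GC-bias parameter B.
    The null model is the empty spec."""

    K: FrozenSet[str] = frozenset()
    M: FrozenSet[str] = frozenset()

    @property
    def complexity(self) -> int:
        return len(self.K) + len(self.M)

    @property
    def is_null(self) -> bool:
        return not self.K and not self.M

    @property
    def lineages(self) -> FrozenSet[str]:
        """Lineages with at least one active parameter."""
        return self.K | self.M

    def params(self) -> Tuple[Tuple[str, str], ...]:
        """Canonically ordered (kind, lineage) pairs: alphabetical by
        lineage, S before B within a lineage."""
        items = [("S", l) for l in self.K] + [("B", l) for l in self.M]
        return tuple(sorted(items, key=lambda kl: (kl[1], _KIND_ORDER[kl[0]])))

    def spec_string(self) -> str:
        if self.is_null:
            return "null"
        return "+".join(f"{kind}:{lin}" for kind, lin in self.params())

    @classmethod
    def from_string(cls, s: str) -> "ModelSpec":
        if s == "null":
            return cls()
        K, M = set(), set()
        for token in s.split("+"):
            kind, _, lin = token.partition(":")
            if kind == "S":
                K.add(lin)
            elif kind == "B":
                M.add(lin)
            else:
                raise ValueError(f"bad spec token {token!r}")
        return cls(frozenset(K), frozenset(M))

    def issubset(self, other: "ModelSpec") -> bool:
        return self.K <= other.K and self.M <= other.M

    def with_param(self, kind: str, lineage: str) -> "ModelSpec":
        if kind == "S":
            return ModelSpec(self.K | {lineage}, self.M)
        return ModelSpec(self.K, self.M | {lineage})

    def without_param(self, kind: str, lineage: str) -> "ModelSpec":
        if kind == "S":
            return ModelSpec(self.K - {lineage}, self.M)
        return ModelSpec(self.K, self.M - {lineage})

    def sort_key(self):
        return (
            self.complexity,
            tuple((lin, _KIND_ORDER[kind]) for kind, lin in self.params()),
        )

    def __str__(self) -> str:
        return self.spec_string()


class ModelDAG:
    """The DAG of all 2^(2n) acceleration models for ``n`` lineages.

    Nodes are :class:`ModelSpec` objects ordered breadth-first by complexity
    (ties broken by canonical parameter order); edges connect each model to
    every model with exactly one extra free parameter.
    """

    def __init__(self, lineages: Sequence[str]):
        lineages = list(lineages)
        if len(set(lineages)) != len(lineages):
            raise ValueError(f"duplicate lineage names in {lineages}")
        if not lineages:
            raise ValueError("at least one lineage is required")
        self.lineages = lineages
        all_params = [("S", l) for l in lineages] + [("B", l) for l in lineages]
        nodes = []
        for r in range(len(all_params) + 1):
            for combo in itertools.combinations(all_params, r):
                K = frozenset(l for kind, l in combo if kind == "S")
                M = frozenset(l for kind, l in combo if kind == "B")
                nodes.append(ModelSpec(K, M))
        self.nodes = sorted(nodes, key=ModelSpec.sort_key)
        self._node_set = set(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def nodes_at(self, complexity: int) -> List[ModelSpec]:
        return [s for s in self.nodes if s.complexity == complexity]

    def parents(self, spec: ModelSpec) -> List[ModelSpec]:
        """All models with exactly one fewer free parameter."""
        out = [spec.without_param(kind, lin) for kind, lin in spec.params()]
        return sorted(out, key=ModelSpec.sort_key)

    def children(self, spec: ModelSpec) -> List[ModelSpec]:
        """All models with exactly one extra free parameter."""
        out = []
        for lin in self.lineages:
            if lin not in spec.K:
                out.append(spec.with_param("S", lin))
            if lin not in spec.M:
                out.append(spec.with_param("B", lin))
        return sorted(out, key=ModelSpec.sort_key)

    def edges(self) -> List[Tuple[ModelSpec, ModelSpec]]:
        return [(p, c) for c in self.nodes for p in self.parents(c)]

    @property
    def max_complexity(self) -> int:
        return 2 * len(self.lineages)


def enumerate_model_dag(
    lineages: Sequence[str], tree=None
) -> ModelDAG:
    """Build the model DAG for the given target lineages.

    If a tree is supplied, lineage names must be terminal branches (leaves):
    acceleration on internal branches is out of scope for this scan.
    """
    if tree is not None:
        missing = [l for l in lineages if l not in tree.leaf_index]
        if missing:
            raise ValueError(
                f"lineages are not leaves of the tree: {missing}"
            )
    return ModelDAG(lineages)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Maximum-likelihood fit of one model to one alignment."""

    spec: ModelSpec
    tree_scale: float
    s_hat: Dict[str, float]
    b_hat: Dict[str, float]
    logL: float
    converged: bool = True

    @property
    def n_free_params(self) -> int:
        """Tree scale plus the active S and B parameters."""
        return 1 + self.spec.complexity

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.logL

    def branch_matrices(self, Q: np.ndarray) -> Dict[str, np.ndarray]:
        out = {}
        for lin in sorted(self.spec.lineages):
            out[lin] = lineage_rate_matrix(
                Q, self.s_hat.get(lin, 0.0), self.b_hat.get(lin, 0.0)
            )
        return out

    def param_string(self) -> str:
        parts = [f"rho={self.tree_scale:.6g}"]
        for kind, lin in self.spec.params():
            val = self.s_hat[lin] if kind == "S" else self.b_hat[lin]
            parts.append(f"{kind}:{lin}={val:.6g}")
        return ",".join(parts)


def _objective_factory(
    spec: ModelSpec, model: NeutralModel, alignment: MultipleAlignment
):
    param_order = spec.params()
    Q = model.Q
    lineages = sorted(spec.lineages)

    def negloglik(theta: np.ndarray) -> float:
        rho = theta[0]
        svals = {l: 0.0 for l in lineages}
        bvals = {l: 0.0 for l in lineages}
        for val, (kind, lin) in zip(theta[1:], param_order):
            if kind == "S":
                svals[lin] = val
            else:
                bvals[lin] = val
        branch = {
            l: lineage_rate_matrix(Q, svals[l], bvals[l]) for l in lineages
        }
        try:
            ll = log_likelihood(model, alignment, branch or None, tree_scale=rho)
        except FloatingPointError:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    return negloglik, param_order


def fit_model(
    spec: ModelSpec,
    model: NeutralModel,
    alignment: MultipleAlignment,
    warm_start: Optional[FittedModel] = None,
    new_param_init: float = 1e-3,
    max_restarts: int = 2,
) -> FittedModel:
    """Fit tree scale and active S/B parameters by bounded maximization of
    the pruning log-likelihood.

    A warm start (typically the parent model's fit in the DAG traversal)
    seeds the shared parameters; newly freed parameters start near zero so
    the child's likelihood can never fall materially below the parent's.
    Additional cold and boundary starts guard against local optima; if the
    optimizer still fails the result is flagged ``converged=False``.
    """
    for lin in spec.lineages:
        if lin not in model.tree.leaf_index:
            raise ValueError(f"lineage {lin!r} is not a leaf of the tree")
    negloglik, param_order = _objective_factory(spec, model, alignment)
    k = len(param_order)
    bounds = [RHO_BOUNDS] + [PARAM_BOUNDS] * k

    def warm_theta(init: float) -> Optional[np.ndarray]:
        if warm_start is None:
            return None
        theta = np.empty(1 + k)
        theta[0] = np.clip(warm_start.tree_scale, *RHO_BOUNDS)
        for j, (kind, lin) in enumerate(param_order):
            prev = (
                warm_start.s_hat.get(lin)
                if kind == "S"
                else warm_start.b_hat.get(lin)
            )
            theta[1 + j] = np.clip(prev if prev is not None else init, *PARAM_BOUNDS)
        return theta

    starts = []
    wt = warm_theta(new_param_init)
    if wt is not None:
        starts.append(wt)
    cold = np.concatenate([[1.0], np.full(k, new_param_init)])
    starts.append(cold)

    best = None
    best_success = False
    tried = 0
    while True:
        for theta0 in starts:
            res = scipy.optimize.minimize(
                negloglik,
                theta0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
                best_success = bool(res.success)
        tried += 1
        need_restart = (
            warm_start is not None
            and -best.fun < warm_start.logL - 1e-6
            and tried <= max_restarts
        )
        if not need_restart:
            break
        # nesting violated: restart from the parent's optimum exactly
        starts = [warm_theta(0.0), warm_theta(1.0)]
        logger.debug(
            "restarting fit of %s: child logL %.6f < parent %.6f",
            spec, -best.fun, warm_start.logL,
        )

    if not best_success:
        # L-BFGS-B occasionally flags a flat optimum as a line-search
        # failure; a derivative-free polish confirms (or repairs) the fit
        res2 = scipy.optimize.minimize(
            negloglik,
            best.x,
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": 2000},
        )
        if res2.fun <= best.fun + 1e-9:
            if res2.fun < best.fun:
                best = res2
            best_success = bool(res2.success)

    theta = best.x
    s_hat = {l: 0.0 for l in spec.K}
    b_hat = {l: 0.0 for l in spec.M}
    for val, (kind, lin) in zip(theta[1:], param_order):
        if kind == "S":
            s_hat[lin] = float(val)
        else:
            b_hat[lin] = float(val)
    logL = -float(best.fun)
    converged = best_success and np.isfinite(logL)
    if warm_start is not None and logL < warm_start.logL - 1e-6:
        converged = False
        logger.warning(
            "nested fit of %s below parent after restarts (%.6f < %.6f)",
            spec, logL, warm_start.logL,
        )
    return FittedModel(
        spec=spec,
        tree_scale=float(theta[0]),
        s_hat=s_hat,
        b_hat=b_hat,
        logL=logL,
        converged=converged,
    )
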
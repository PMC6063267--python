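"""Forward model selection over the acceleration-model DAG.

The traversal starts at the null model (tree scale only) and walks the DAG
breadth-first, performing a likelihood ratio test (LRT) for every edge whose
parent is the null model or was itself recovered at the ``p_cut`` threshold.
Because each added parameter is constrained to be nonnegative, the df=1 LRT
null distribution is the boundary mixture (1/2)*delta_0 + (1/2)*chi2_1.

Each tested child node is annotated with the *maximum* p-value over its
tested incoming edges, so a model is only recovered if it beats every
simpler model it was compared against. The alignment is finally annotated
with a single model: the most complex recovered model if the recovered set
forms a chain, otherwise the minimum-AIC model among recovered nodes with no
recovered children. A final LRT of the annotated model against the null
yields the p-value used to call a lineage-specific accelerated region
(linAR) at ``alpha_final``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import chi2

from .accel_models import (
    FittedModel,
    ModelDAG,
    ModelSpec,
    enumerate_model_dag,
    fit_model,
)
from .phylo_core import (
    GenomicInterval,
    InsufficientDataError,
    MultipleAlignment,
    NeutralModel,
    adapt_background_gc,
)

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Thresholds and settings for the model-selection scan."""

    lineages: Tuple[str, ...]
    p_cut: float = 0.01
    alpha_final: float = 1e-4
    adapt_gc: bool = True
    #: species excluded from the local GC-content estimate (default: the
    #: target lineages themselves; typically all primates in the alignment)
    gc_exclude: Optional[Tuple[str, ...]] = None
    #: use the chi-bar-squared null for multi-parameter final calls; if
    #: False, the conservative chi-square with k degrees of freedom
    chi_bar_final: bool = True

    def __post_init__(self):
        if not (0.0 < self.p_cut < 1.0):
            raise ValueError(f"p_cut must be in (0,1), got {self.p_cut}")
        if not (0.0 < self.alpha_final < 1.0):
            raise ValueError(
                f"alpha_final must be in (0,1), got {self.alpha_final}"
            )
        if self.gc_exclude is None:
            self.gc_exclude = tuple(self.lineages)


@dataclass
class LRTResult:
    """One likelihood ratio test between nested models."""

    lam: float
    df_extra: int
    p: float


def lrt_pvalue(logL_parent: float, logL_child: float, df_extra: int,
               chi_bar: bool = True) -> LRTResult:
    """P-value for a LRT between models differing in ``df_extra``
    nonnegative parameters.

    For one extra parameter the asymptotic null is the boundary mixture
    (1/2)*delta_0 + (1/2)*chi2_1. For k > 1 (used only for the final call of
    a multi-parameter model against the null) the chi-bar-squared null with
    binomial weights is used: p = sum_j C(k,j) 2^-k P(chi2_j >= lam), where
    the j=0 component contributes nothing for lam > 0. Setting
    ``chi_bar=False`` falls back to a conservative chi2_k tail.
    """
    if df_extra < 1:
        raise ValueError(f"df_extra must be >= 1, got {df_extra}")
    lam = max(0.0, 2.0 * (logL_child - logL_parent))
    if lam == 0.0:
        return LRTResult(lam=0.0, df_extra=df_extra, p=1.0)
    k = df_extra
    if k == 1:
        p = 0.5 * float(chi2.sf(lam, 1))
    elif chi_bar:
        p = sum(
            math.comb(k, j) * 0.5**k * float(chi2.sf(lam, j))
            for j in range(1, k + 1)
        )
    else:
        p = float(chi2.sf(lam, k))
    return LRTResult(lam=lam, df_extra=k, p=min(1.0, max(p, 0.0)))


@dataclass
class SelectionResult:
    """Outcome of the DAG traversal for one alignment."""

    selected: FittedModel
    null_fit: FittedModel
    #: max LRT p over tested incoming edges, per tested node
    annotations: Dict[ModelSpec, float]
    #: tested nodes with annotation < p_cut, in canonical order
    recovered: List[ModelSpec]
    fits: Dict[ModelSpec, FittedModel]
    n_fits: int
    usable: bool = True
    failure_reason: Optional[str] = None


@dataclass
class ElementCall:
    """A conserved element annotated with its selected model."""

    element: GenomicInterval
    selected: FittedModel
    null_fit: FittedModel
    final_p: float
    is_linar: bool
    recovered_specs: List[ModelSpec] = field(default_factory=list)

    @property
    def spec_string(self) -> str:
        return self.selected.spec.spec_string()


def _is_chain(specs: Sequence[ModelSpec]) -> bool:
    """True if the specs are totally ordered by parameter-set inclusion."""
    ordered = sorted(specs, key=lambda s: s.complexity)
    for a, b in zip(ordered, ordered[1:]):
        if not a.issubset(b):
            return False
    return True


def _aic_choice(candidates: Iterable[FittedModel]) -> FittedModel:
    """Minimum AIC; ties toward fewer parameters, then spec string."""
    return min(
        candidates,
        key=lambda f: (round(f.aic, 12), f.spec.complexity, f.spec.spec_string()),
    )


def resolve_selection(
    recovered: Sequence[ModelSpec],
    fits: Dict[ModelSpec, FittedModel],
    dag: ModelDAG,
    null_fit: FittedModel,
) -> FittedModel:
    """Annotation rule shared by the early-stopping and exhaustive
    procedures: the most complex recovered model if the recovered set is a
    chain under inclusion, otherwise minimum AIC among recovered models
    with no recovered children; the null fit if nothing was recovered."""
    if not recovered:
        return null_fit
    ordered = sorted(recovered, key=ModelSpec.sort_key)
    if _is_chain(ordered):
        return fits[ordered[-1]]
    recovered_set = set(ordered)
    leaves = [
        s
        for s in ordered
        if not any(c in recovered_set for c in dag.children(s))
    ]
    return _aic_choice(fits[s] for s in leaves)


def select_model(
    alignment: MultipleAlignment,
    dag: ModelDAG,
    model: NeutralModel,
    config: SelectionConfig,
) -> SelectionResult:
    """Breadth-first early-stopping traversal of the model DAG.

    Edges are tested only when the parent is the null model or was itself
    recovered (annotation < p_cut). Children are fit once, warm-started from
    their best eligible parent, and annotated with the maximum p over all
    tested incoming edges.
    """
    null_spec = ModelSpec()
    null_fit = fit_model(null_spec, model, alignment)
    fits: Dict[ModelSpec, FittedModel] = {null_spec: null_fit}
    annotations: Dict[ModelSpec, float] = {}
    n_fits = 1

    for level in range(1, dag.max_complexity + 1):
        any_recovered = False
        for child in dag.nodes_at(level):
            eligible = [
                p
                for p in dag.parents(child)
                if p.is_null
                or (p in annotations and annotations[p] < config.p_cut)
            ]
            if not eligible:
                continue
            parent_fits = [fits[p] for p in eligible if p in fits]
            if not parent_fits:
                continue
            warm = max(parent_fits, key=lambda f: f.logL)
            child_fit = fit_model(child, model, alignment, warm_start=warm)
            n_fits += 1
            fits[child] = child_fit
            pmax = annotations.get(child, 0.0)
            for pf in parent_fits:
                res = lrt_pvalue(pf.logL, child_fit.logL, df_extra=1)
                pmax = max(pmax, res.p)
            annotations[child] = pmax
            if pmax < config.p_cut:
                any_recovered = True
        if not any_recovered:
            break

    recovered = sorted(
        (s for s, p in annotations.items() if p < config.p_cut),
        key=ModelSpec.sort_key,
    )
    selected = resolve_selection(recovered, fits, dag, null_fit)

    usable = null_fit.converged and selected.converged
    reason = None if usable else "optimizer failed to converge"
    return SelectionResult(
        selected=selected,
        null_fit=null_fit,
        annotations=annotations,
        recovered=recovered,
        fits=fits,
        n_fits=n_fits,
        usable=usable,
        failure_reason=reason,
    )


def exhaustive_select(
    alignment: MultipleAlignment,
    dag: ModelDAG,
    model: NeutralModel,
    config: SelectionConfig,
) -> SelectionResult:
    """Reference procedure without early stopping: fit every model in the
    DAG, test every edge, and apply the same annotation and chain/AIC rule.

    Used to validate that early stopping does not change the outcome; it is
    exponentially more expensive and not intended for production scans.
    """
    fits: Dict[ModelSpec, FittedModel] = {}
    for spec in dag.nodes:
        parents = [p for p in dag.parents(spec) if p in fits]
        warm = (
            max((fits[p] for p in parents), key=lambda f: f.logL)
            if parents
            else None
        )
        fits[spec] = fit_model(spec, model, alignment, warm_start=warm)
    annotations: Dict[ModelSpec, float] = {}
    for spec in dag.nodes:
        if spec.is_null:
            continue
        pmax = 0.0
        for parent in dag.parents(spec):
            res = lrt_pvalue(fits[parent].logL, fits[spec].logL, df_extra=1)
            pmax = max(pmax, res.p)
        annotations[spec] = pmax
    recovered = sorted(
        (s for s, p in annotations.items() if p < config.p_cut),
        key=ModelSpec.sort_key,
    )
    null_fit = fits[ModelSpec()]
    selected = resolve_selection(recovered, fits, dag, null_fit)
    return SelectionResult(
        selected=selected,
        null_fit=null_fit,
        annotations=annotations,
        recovered=recovered,
        fits=fits,
        n_fits=len(fits),
    )


def finalize_call(
    selected: FittedModel,
    null_fit: FittedModel,
    element: GenomicInterval,
    config: SelectionConfig,
    recovered: Optional[List[ModelSpec]] = None,
) -> ElementCall:
    """Final LRT of the annotated model against the null; an element is a
    linAR when a non-null model was selected and the final p-value is below
    ``alpha_final``."""
    if selected.spec.is_null:
        return ElementCall(
            element=element,
            selected=selected,
            null_fit=null_fit,
            final_p=1.0,
            is_linar=False,
            recovered_specs=list(recovered or []),
        )
    res = lrt_pvalue(
        null_fit.logL,
        selected.logL,
        df_extra=selected.spec.complexity,
        chi_bar=config.chi_bar_final,
    )
    return ElementCall(
        element=element,
        selected=selected,
        null_fit=null_fit,
        final_p=res.p,
        is_linar=res.p < config.alpha_final,
        recovered_specs=list(recovered or []),
    )


def scan_elements(
    elements: Sequence[Tuple[GenomicInterval, MultipleAlignment]],
    model: NeutralModel,
    config: SelectionConfig,
) -> List[ElementCall]:
    """Run selection and the final call on each (interval, alignment) pair.

    The background frequencies are adapted to each element's local GC
    content (excluding ``config.gc_exclude``) before fitting. Elements
    lacking a target species, without usable data, or with non-converged
    fits are skipped with a logged reason; output order follows input order.
    """
    dag = enumerate_model_dag(config.lineages, tree=model.tree)
    calls: List[ElementCall] = []
    for interval, alignment in elements:
        label = interval.id or f"{interval.chrom}:{interval.start}-{interval.end}"
        missing = [
            l for l in config.lineages if not alignment.has_nucleotide(l)
        ]
        if missing:
            logger.info("skipping %s: no bases for lineage(s) %s", label, missing)
            continue
        local_model = model
        if config.adapt_gc:
            try:
                local_model = adapt_background_gc(
                    model, alignment, config.gc_exclude
                )
            except InsufficientDataError as exc:
                logger.info("skipping %s: %s", label, exc)
                continue
        result = select_model(alignment, dag, local_model, config)
        if not result.usable:
            logger.warning("skipping %s: %s", label, result.failure_reason)
            continue
        calls.append(
            finalize_call(
                result.selected,
                result.null_fit,
                interval,
                config,
                recovered=result.recovered,
            )
        )
        logger.debug(
            "%s -> %s (final_p=%.3g, %d fits)",
            label,
            result.selected.spec,
            calls[-1].final_p,
            result.n_fits,
        )
    return calls
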
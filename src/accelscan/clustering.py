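"""Spatial statistics on linARs relative to the background element set.

Two complementary analyses quantify whether accelerated elements cluster
along the genome more than conserved elements in general:

* a permutation test on the median nearest-neighbour distance between
  linARs, against random same-size draws from the background set;
* discrete clusters of background elements (consecutive elements within a
  gap threshold), each tested for linAR enrichment with a conditional
  binomial test (conditioning on the cluster containing at least one
  linAR), followed by Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .phylo_core import GenomicInterval

logger = logging.getLogger(__name__)


def _nn_gaps(intervals: Sequence[GenomicInterval]) -> List[float]:
    """Nearest-neighbour gap per element (same chromosome only; overlap ->
    0); elements alone on their chromosome are excluded."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    gaps: List[float] = []
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: (x.start, x.end))
        if len(ivs) < 2:
            continue
        for i, iv in enumerate(ivs):
            cands = []
            if i > 0:
                cands.append(max(0, iv.start - ivs[i - 1].end))
            if i + 1 < len(ivs):
                cands.append(max(0, ivs[i + 1].start - iv.end))
            gaps.append(min(cands))
    return gaps


def median_nn_distance(intervals: Sequence[GenomicInterval]) -> float:
    gaps = _nn_gaps(intervals)
    if not gaps:
        raise ValueError("no nearest-neighbour distances (need >= 2 elements "
                         "sharing a chromosome)")
    return float(np.median(gaps))


@dataclass
class NNTestResult:
    """Permutation test of linAR nearest-neighbour clustering."""

    observed_median: float
    permuted_medians: np.ndarray
    p: float
    #: add-one smoothed p-value, (count + 1) / (n_perm + 1)
    p_smoothed: float
    n_perm: int
    seed: int
    alternative: str

    @property
    def p_display(self) -> str:
        if self.p == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p:g}"


def nn_distance_test(
    linars: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "less",
) -> NNTestResult:
    """Permutation test: is the median nearest-neighbour distance between
    linARs smaller than for random same-size draws from the background?

    ``alternative='less'`` (default) counts permuted medians <= observed,
    i.e. small p means the linARs are *more* clustered than random element
    sets; ``'greater'`` tests the opposite tail.
    """
    if len(linars) < 2:
        raise ValueError("need at least 2 linARs for the clustering test")
    bg_keys = {(iv.chrom, iv.start, iv.end) for iv in background}
    missing = [
        iv for iv in linars if (iv.chrom, iv.start, iv.end) not in bg_keys
    ]
    if missing:
        raise ValueError(
            f"{len(missing)} linARs are not in the background element set"
        )
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    observed = median_nn_distance(linars)
    rng = np.random.default_rng(seed)
    background = list(background)
    k = len(linars)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(background), size=k, replace=False)
        permuted[i] = median_nn_distance([background[j] for j in idx])
    if alternative == "less":
        count = int(np.sum(permuted <= observed))
    else:
        count = int(np.sum(permuted >= observed))
    return NNTestResult(
        observed_median=observed,
        permuted_medians=permuted,
        p=count / n_perm,
        p_smoothed=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


@dataclass
class Cluster:
    interval: GenomicInterval
    member_indices: List[int]

    @property
    def n(self) -> int:
        return len(self.member_indices)


def find_clusters(
    elements: Sequence[GenomicInterval],
    max_gap: int = 100_000,
    inclusive: bool = True,
) -> List[Cluster]:
    """Group consecutive same-chromosome elements separated by at most
    ``max_gap`` bp (strictly less with ``inclusive=False``) into clusters.

    Input must be sorted by (chrom, start); the output is a partition of the
    input in order.
    """
    keys = [(iv.chrom, iv.start) for iv in elements]
    if keys != sorted(keys):
        raise ValueError("elements must be sorted by (chrom, start)")
    clusters: List[Cluster] = []
    current: List[int] = []
    for i, iv in enumerate(elements):
        if current:
            prev = elements[current[-1]]
            gap = iv.start - prev.end
            same = iv.chrom == prev.chrom and (
                gap <= max_gap if inclusive else gap < max_gap
            )
            if not same:
                clusters.append(_make_cluster(elements, current))
                current = []
        current.append(i)
    if current:
        clusters.append(_make_cluster(elements, current))
    return clusters


def _make_cluster(elements, idx: List[int]) -> Cluster:
    ivs = [elements[i] for i in idx]
    span = GenomicInterval(
        ivs[0].chrom, min(i.start for i in ivs), max(i.end for i in ivs)
    )
    return Cluster(interval=span, member_indices=list(idx))


@dataclass
class ClusterResult:
    """Enrichment of one cluster for linARs."""

    interval: GenomicInterval
    n: int
    k: int
    p_raw: float
    p_cond: float
    q: float = float("nan")

    @property
    def enriched(self) -> bool:
        return bool(self.q < self._fdr)

    _fdr: float = 0.05


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cluster_enrichment(
    clusters: Sequence[Cluster],
    linar_flags: Sequence[bool],
    overall_p: float,
    fdr: float = 0.05,
) -> List[ClusterResult]:
    """Conditional binomial enrichment test for each cluster with >= 1 linAR.

    Under the null, each of a cluster's ``n`` elements is a linAR
    independently with the genome-wide proportion ``overall_p``; the raw
    p-value is the upper binomial tail P(X >= k), and the conditional
    p-value divides by P(X >= 1) = 1 - (1 - overall_p)^n to account for
    only testing clusters that contain a linAR. q-values are BH across the
    tested clusters.
    """
    if not (0.0 < overall_p < 1.0):
        raise ValueError(f"overall_p must be in (0,1), got {overall_p}")
    flags = np.asarray(linar_flags, dtype=bool)
    results: List[ClusterResult] = []
    for cl in clusters:
        k = int(flags[cl.member_indices].sum())
        if k == 0:
            continue
        n = cl.n
        p_raw = float(binom.sf(k - 1, n, overall_p))
        # 1 - Bin(0 | p, n), via the same tail function so that a singleton
        # cluster gives p_cond = 1 exactly
        denom = float(binom.sf(0, n, overall_p))
        p_cond = min(1.0, p_raw / denom)
        results.append(
            ClusterResult(
                interval=cl.interval, n=n, k=k, p_raw=p_raw, p_cond=p_cond,
                _fdr=fdr,
            )
        )
    qs = bh_fdr([r.p_cond for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
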
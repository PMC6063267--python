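"""Conserved-element bookkeeping: merging, filtering, masking, and outputs.

The candidate set for the acceleration scan is a list of conserved elements
(intervals with attached alignments). Before testing, elements separated by
less than ``min_gap`` bp are merged, elements shorter than ``min_len`` bp
are dropped, and elements where a required species contributes no
unambiguous base are dropped. Externally supplied per-species interval
masks (repeats, self-chained regions, ...) are applied by replacing bases
with N. Every filtering step is recorded in a provenance log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_selection import ElementCall
from .phylo_core import (
    GenomicInterval,
    MultipleAlignment,
    write_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class ElementSet:
    """An ordered set of elements with optional attached alignments and a
    provenance log of the filters applied so far."""

    records: List[Tuple[GenomicInterval, Optional[MultipleAlignment]]]
    provenance: List[str] = field(default_factory=list)

    @property
    def intervals(self) -> List[GenomicInterval]:
        return [iv for iv, _ in self.records]

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.records)


def _is_sorted(intervals: Sequence[GenomicInterval]) -> bool:
    keys = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    return keys == sorted(keys)


def _concat_alignments(
    members: List[Optional[MultipleAlignment]],
) -> Optional[MultipleAlignment]:
    """Column-wise concatenation over the union of species; species absent
    from a member contribute N (missing) for its columns."""
    if any(m is None for m in members):
        return None
    species: List[str] = []
    for m in members:
        for sp in m.species:
            if sp not in species:
                species.append(sp)
    seqs = {sp: [] for sp in species}
    for m in members:
        n = m.n_columns
        for sp in species:
            seqs[sp].append(m.sequences.get(sp, "N" * n))
    return MultipleAlignment(
        {sp: "".join(parts) for sp, parts in seqs.items()}, normalize=False
    )


def merge_filter_elements(
    elements: ElementSet,
    min_gap: int = 10,
    min_len: int = 50,
    required_species: Optional[Iterable[str]] = None,
) -> ElementSet:
    """Merge nearby elements, drop short ones, then drop elements missing a
    required species.

    Same-chromosome elements whose gap (next.start - prev.end) is smaller
    than ``min_gap`` are merged first; merged elements shorter than
    ``min_len`` are then dropped; finally, when ``required_species`` is
    given, elements whose alignment has no unambiguous base for any one of
    those species are dropped. The operation is idempotent.
    """
    records = list(elements.records)
    prov = list(elements.provenance)
    if not _is_sorted([iv for iv, _ in records]):
        logger.warning("elements not sorted by (chrom, start); sorting")
        records.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))

    merged: List[Tuple[GenomicInterval, Optional[MultipleAlignment]]] = []
    group: List[Tuple[GenomicInterval, Optional[MultipleAlignment]]] = []

    def flush():
        if not group:
            return
        if len(group) == 1:
            merged.append(group[0])
        else:
            ivs = [iv for iv, _ in group]
            iv = GenomicInterval(
                ivs[0].chrom,
                min(i.start for i in ivs),
                max(i.end for i in ivs),
                ivs[0].id,
            )
            merged.append((iv, _concat_alignments([a for _, a in group])))
        group.clear()

    group_end = -1
    for rec in records:
        if group:
            prev_chrom = group[-1][0].chrom
            cur = rec[0]
            if cur.chrom == prev_chrom and cur.start - group_end < min_gap:
                group.append(rec)
                group_end = max(group_end, cur.end)
                continue
            flush()
        group.append(rec)
        group_end = rec[0].end
    flush()
    n_merged = len(records) - len(merged)
    prov.append(f"merge gap<{min_gap}: {len(records)} -> {len(merged)} elements")

    kept = [(iv, a) for iv, a in merged if len(iv) >= min_len]
    prov.append(
        f"drop length<{min_len}: removed {len(merged) - len(kept)} elements"
    )

    if required_species is not None:
        req = list(required_species)
        survivors = []
        for iv, aln in kept:
            if aln is None or all(aln.has_nucleotide(sp) for sp in req):
                survivors.append((iv, aln))
        prov.append(
            f"require species {sorted(req)}: removed {len(kept) - len(survivors)}"
        )
        kept = survivors
    logger.info("merge/filter: %d -> %d elements (%d merged away)",
                len(records), len(kept), n_merged)
    return ElementSet(records=kept, provenance=prov)


def mask_alignment(
    alignment: MultipleAlignment,
    masks: Mapping[str, Sequence[GenomicInterval]],
) -> MultipleAlignment:
    """Replace masked positions with N in the named species' rows.

    Mask intervals are interpreted in reference coordinates when the
    alignment carries a reference interval with a matching chromosome, and
    as column offsets otherwise. Column count never changes; mask species
    absent from the alignment are ignored with a warning.
    """
    seqs = dict(alignment.sequences)
    ncol = alignment.n_columns
    ref = alignment.ref_interval
    for sp, intervals in masks.items():
        if sp not in seqs:
            logger.warning("mask species %r absent from alignment; ignored", sp)
            continue
        row = np.array(list(seqs[sp]))
        for iv in intervals:
            if ref is not None and iv.chrom == ref.chrom:
                lo = max(iv.start, ref.start) - ref.start
                hi = min(iv.end, ref.end) - ref.start
            else:
                lo, hi = iv.start, min(iv.end, ncol)
            if hi > lo >= 0:
                keep_gaps = row[lo:hi] == "-"
                row[lo:hi] = np.where(keep_gaps, "-", "N")
        seqs[sp] = "".join(row)
    return MultipleAlignment(
        seqs, ref_interval=alignment.ref_interval, normalize=False
    )


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "id",
    "chrom",
    "start",
    "end",
    "spec",
    "tree_scale",
    "params",
    "logL_null",
    "logL_selected",
    "final_p",
    "is_linar",
]


def bed_score(final_p: float) -> int:
    """BED score: min(1000, round(-10 log10 p)), floored at p = 1e-300."""
    p = max(final_p, 1e-300)
    return min(1000, int(round(-10.0 * math.log10(p))))


def calls_to_frame(calls: Sequence[ElementCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        iv = call.element
        sel = call.selected
        params = ";".join(
            f"{kind}:{lin}={sel.s_hat[lin] if kind == 'S' else sel.b_hat[lin]:.6g}"
            for kind, lin in sel.spec.params()
        )
        rows.append(
            {
                "id": iv.id or f"{iv.chrom}:{iv.start}-{iv.end}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "spec": sel.spec.spec_string(),
                "tree_scale": sel.tree_scale,
                "params": params,
                "logL_null": call.null_fit.logL,
                "logL_selected": sel.logL,
                "final_p": call.final_p,
                "is_linar": call.is_linar,
            }
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_calls(
    calls: Sequence[ElementCall], tsv_path, bed_path=None
) -> None:
    """Write full call detail as TSV and, optionally, the linARs as BED
    (name = model spec string, score = -10 log10 of the final p-value)."""
    frame = calls_to_frame(calls)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        linars = [c for c in calls if c.is_linar]
        write_bed(
            [c.element for c in linars],
            bed_path,
            extra={
                "name": [c.spec_string for c in linars],
                "score": [bed_score(c.final_p) for c in linars],
            },
        )


def summarize_calls(calls: Sequence[ElementCall]) -> Dict[str, pd.DataFrame]:
    """Cross-tabulate linARs by lineage/parameter combination.

    Returns a dict with:

    * ``pairwise`` — a symmetric matrix over parameter tokens (``S:lin``,
      ``B:lin``): the diagonal counts linARs with that parameter active,
      off-diagonal cells count co-occurrence within one linAR;
    * ``per_lineage`` — total linARs with any active parameter per lineage.
    """
    linars = [c for c in calls if c.is_linar]
    tokens: List[str] = []
    for call in linars:
        for kind, lin in call.selected.spec.params():
            tok = f"{kind}:{lin}"
            if tok not in tokens:
                tokens.append(tok)
    tokens.sort(key=lambda t: (t.split(":")[1], t.split(":")[0] != "S"))
    pair = pd.DataFrame(0, index=tokens, columns=tokens, dtype=int)
    per_lineage: Dict[str, int] = {}
    for call in linars:
        toks = [f"{kind}:{lin}" for kind, lin in call.selected.spec.params()]
        for a in toks:
            for b in toks:
                pair.loc[a, b] += 1
        for lin in sorted(call.selected.spec.lineages):
            per_lineage[lin] = per_lineage.get(lin, 0) + 1
    return {
        "pairwise": pair,
        "per_lineage": pd.Series(per_lineage, dtype=int).sort_index(),
    }
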
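"""Phylogenetic data structures, file I/O, and the likelihood engine.

This module provides the foundation of the acceleration scan: a rooted
phylogenetic tree with branch lengths, a reversible nucleotide substitution
model (the neutral model), readers for PHAST ``.mod`` files and for MAF /
multi-FASTA alignments, GC-content adaptation of the background frequencies,
and the pruning (Felsenstein) algorithm for alignment log-likelihoods with
per-branch rate-matrix overrides.

Conventions
-----------
* Nucleotide order is (A, C, G, T) throughout.
* Branch lengths are expected substitutions per site under the neutral model
  at unit tree scale; the rate matrix is always renormalized so that
  ``-sum_i pi_i Q_ii = 1``.
* ``N`` and ``-`` are treated as fully missing data (all-ones partial
  likelihoods); IUPAC ambiguity codes are mapped to ``N`` on read.
* Genomic intervals are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: code 4 = missing (N or gap)
MISSING_CODE = 4
_AMBIGUITY = set("RYSWKMBDHVN")

#: leaf partial-likelihood rows by character code (A,C,G,T,missing)
_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones(4)])

WEAK = frozenset("AT")
STRONG = frozenset("GC")


class ModelFileError(ValueError):
    """Raised for malformed or unsupported PHAST ``.mod`` files."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates the reversible-model invariants."""


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment input."""


class InsufficientDataError(ValueError):
    """Raised when an alignment has no usable bases for an operation."""


# ---------------------------------------------------------------------------
# Genomic intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp to another interval on the same chromosome (0 if they
        overlap or abut); ``None`` if on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def read_bed(path) -> List[GenomicInterval]:
    """Read intervals from a BED file (first 3-4 columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            name = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, extra: Optional[Mapping[str, Sequence]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if extra:
                cols.append(str(extra["name"][i]))
                if "score" in extra:
                    cols.append(str(extra["score"][i]))
            elif iv.id is not None:
                cols.append(iv.id)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted phylogeny stored as flat arrays for fast postorder sweeps.

    Nodes are indexed 0..n-1 with the root last in postorder. Only leaves
    carry names; a basal multifurcation is accepted as the root.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        names: Sequence[Optional[str]],
        root: int,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.names = list(names)
        self.root = int(root)
        n = len(self.parent)
        self.children: List[List[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        self.leaves = [v for v in range(n) if not self.children[v]]
        leaf_names = [self.names[v] for v in self.leaves]
        if any(nm is None for nm in leaf_names):
            raise ValueError("every leaf must be named")
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("leaf names must be unique")
        if np.any(self.lengths[[v for v in range(n) if v != self.root]] < 0):
            raise ValueError("branch lengths must be nonnegative")
        self.leaf_index = {self.names[v]: v for v in self.leaves}
        # postorder: children before parents
        self.postorder: List[int] = []
        stack = [self.root]
        seen = []
        while stack:
            v = stack.pop()
            seen.append(v)
            stack.extend(self.children[v])
        self.postorder = seen[::-1]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        nodes = list(tree.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        names: List[Optional[str]] = [None] * len(nodes)
        for nd in nodes:
            i = idx[id(nd)]
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                names[i] = nd.taxon.label
            elif nd.is_leaf():
                names[i] = nd.label
        return cls(parent, lengths, names, root=idx[id(tree.seed_node)])

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                s = self.names[v]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return s
            return f"{s}:{self.lengths[v]:.10g}"

        return rec(self.root) + ";"

    def scaled(self, factor: float) -> "PhyloTree":
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        return PhyloTree(self.parent, self.lengths * factor, self.names, self.root)

    @property
    def leaf_names(self) -> List[str]:
        return [self.names[v] for v in self.leaves]

    def total_length(self) -> float:
        mask = np.ones(len(self.parent), dtype=bool)
        mask[self.root] = False
        return float(self.lengths[mask].sum())

    def branch_length(self, leaf_name: str) -> float:
        return float(self.lengths[self.leaf_index[leaf_name]])

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.to_newick() == other.to_newick()

    def __hash__(self):
        return hash(self.to_newick())


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


class MultipleAlignment:
    """An ordered species -> sequence map over the alphabet {A,C,G,T,N,-}."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        ref_interval: Optional[GenomicInterval] = None,
        normalize: bool = True,
    ):
        seqs: Dict[str, str] = {}
        length = None
        for sp, seq in sequences.items():
            if sp in seqs:
                raise AlignmentFormatError(f"duplicate species {sp!r}")
            if normalize:
                seq = _normalize_sequence(seq, sp)
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentFormatError(
                    f"ragged alignment: {sp!r} has length {len(seq)}, expected {length}"
                )
            seqs[sp] = seq
        self.sequences = seqs
        self.ref_interval = ref_interval
        self._codes: Optional[np.ndarray] = None

    @property
    def species(self) -> List[str]:
        return list(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def __len__(self) -> int:
        return self.n_columns

    def codes(self) -> np.ndarray:
        """Integer codes, shape (n_species, n_columns); 0-3 = ACGT, 4 = missing."""
        if self._codes is None:
            lut = np.full(128, -1, dtype=np.int8)
            for b, i in BASE_INDEX.items():
                lut[ord(b)] = i
            lut[ord("N")] = MISSING_CODE
            lut[ord("-")] = MISSING_CODE
            rows = [
                lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
                for seq in self.sequences.values()
            ]
            self._codes = np.vstack(rows) if rows else np.zeros((0, 0), np.int8)
        return self._codes

    def base_counts(self, include: Optional[Iterable[str]] = None) -> np.ndarray:
        """Counts of A,C,G,T over the given species (default: all)."""
        species = list(include) if include is not None else self.species
        counts = np.zeros(4, dtype=np.int64)
        codes = self.codes()
        order = {sp: i for i, sp in enumerate(self.species)}
        for sp in species:
            if sp not in order:
                continue
            row = codes[order[sp]]
            counts += np.bincount(row[row < 4], minlength=4)
        return counts

    def has_nucleotide(self, species: str) -> bool:
        """True if the species row has at least one unambiguous base."""
        if species not in self.sequences:
            return False
        row = self.codes()[self.species.index(species)]
        return bool(np.any(row < 4))

    def subset_columns(self, index: np.ndarray) -> "MultipleAlignment":
        return MultipleAlignment(
            {
                sp: "".join(np.array(list(seq))[index])
                for sp, seq in self.sequences.items()
            },
            ref_interval=self.ref_interval,
            normalize=False,
        )

    def with_sequence(self, species: str, seq: str) -> "MultipleAlignment":
        new = dict(self.sequences)
        new[species] = seq
        return MultipleAlignment(new, ref_interval=self.ref_interval)


def _normalize_sequence(seq: str, species: str) -> str:
    seq = seq.upper().replace(".", "-")
    cleaned = []
    for ch in seq:
        if ch in BASE_INDEX or ch in "N-":
            cleaned.append(ch)
        elif ch in _AMBIGUITY:
            cleaned.append("N")
        else:
            raise AlignmentFormatError(
                f"unknown character {ch!r} in sequence for {species!r}"
            )
    return "".join(cleaned)


def read_alignment(path, format: str = "FASTA") -> List[MultipleAlignment]:
    """Read alignments from multi-FASTA (one alignment per file) or MAF
    (one alignment per ``a`` block).

    MAF sequence sources of the form ``species.chrom`` are split at the first
    dot; the first row of each block provides the reference interval.
    """
    from Bio import AlignIO

    fmt = format.upper()
    if fmt == "FASTA":
        aln = AlignIO.read(path, "fasta")
        return [
            MultipleAlignment({rec.id: str(rec.seq) for rec in aln})
        ]
    if fmt == "MAF":
        out = []
        for block in AlignIO.parse(path, "maf"):
            seqs: Dict[str, str] = {}
            ref: Optional[GenomicInterval] = None
            for rec in block:
                sp, _, chrom = rec.id.partition(".")
                seqs[sp] = str(rec.seq)
                if ref is None:
                    ann = rec.annotations
                    if chrom and "start" in ann:
                        start = int(ann["start"])
                        size = int(ann["size"])
                        ref = GenomicInterval(chrom, start, start + size)
            out.append(MultipleAlignment(seqs, ref_interval=ref))
        return out
    raise ValueError(f"unsupported alignment format {format!r}")


def write_fasta(alignment: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp, seq in alignment.sequences.items():
            fh.write(f">{sp}\n{seq}\n")


# ---------------------------------------------------------------------------
# The neutral model
# ---------------------------------------------------------------------------


@dataclass
class NeutralModel:
    """A reversible nucleotide model: tree, equilibrium frequencies, and a
    rate matrix normalized to one expected substitution per unit branch
    length. The null model's only free parameter is an overall tree scale."""

    tree: PhyloTree
    pi: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self._eig: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None

    def validate(self, tol: float = 1e-9) -> None:
        pi, Q = self.pi, self.Q
        if pi.shape != (4,) or Q.shape != (4, 4):
            raise ModelValidationError("pi must be length 4 and Q 4x4")
        if np.any(pi <= 0):
            raise ModelValidationError("equilibrium frequencies must be positive")
        if abs(pi.sum() - 1.0) > tol:
            raise ModelValidationError(f"pi sums to {pi.sum()}, not 1")
        off = Q[~np.eye(4, dtype=bool)]
        if np.any(off < -tol):
            raise ModelValidationError("Q off-diagonals must be nonnegative")
        if np.max(np.abs(Q.sum(axis=1))) > tol:
            raise ModelValidationError("Q rows must sum to 0")
        flux = pi[:, None] * Q
        if np.max(np.abs(flux - flux.T)) > tol:
            raise ModelValidationError(
                "model is not time-reversible: pi_i Q_ij != pi_j Q_ji"
            )
        rate = -float(np.dot(pi, np.diag(Q)))
        if abs(rate - 1.0) > tol:
            raise ModelValidationError(
                f"Q is not normalized to unit expected rate (got {rate})"
            )

    # -- derived quantities -------------------------------------------------

    def exchangeabilities(self) -> np.ndarray:
        """Symmetric s_ij = Q_ij / pi_j (diagonal zeroed)."""
        s = self.Q / self.pi[None, :]
        np.fill_diagonal(s, 0.0)
        return s

    def _eigendecomposition(self):
        """Symmetric eigendecomposition of D^1/2 Q D^-1/2 for fast expm."""
        if self._eig is None:
            d = np.sqrt(self.pi)
            sym = (d[:, None] * self.Q) / d[None, :]
            w, U = np.linalg.eigh((sym + sym.T) / 2.0)
            left = U / d[:, None]          # D^-1/2 U
            right = U.T * d[None, :]       # U^T D^1/2
            self._eig = (w, left, right)
        return self._eig

    def branch_transition_matrices(self, scale: float) -> np.ndarray:
        """exp(Q * t_v * scale) for every node v, shape (n_nodes, 4, 4)."""
        w, left, right = self._eigendecomposition()
        t = self.tree.lengths * scale
        ew = np.exp(np.outer(t, w))                      # (n, 4)
        P = np.einsum("ik,nk,kj->nij", left, ew, right)
        return np.clip(P, 0.0, 1.0)


def normalize_rate_matrix(Q: np.ndarray, pi: np.ndarray) -> Tuple[np.ndarray, float]:
    """Rescale Q to unit expected rate at pi; returns (Q', factor)."""
    rate = -float(np.dot(pi, np.diag(Q)))
    if rate <= 0:
        raise ModelValidationError(f"nonpositive expected rate {rate}")
    return Q / rate, rate


def build_reversible_q(exchangeabilities: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Q_ij = s_ij * pi_j off-diagonal, diagonal set so rows sum to zero,
    normalized to unit expected rate."""
    Q = exchangeabilities * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q, _ = normalize_rate_matrix(Q, pi)
    return Q


# ---------------------------------------------------------------------------
# PHAST .mod I/O
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "ALPHABET",
    "ORDER",
    "SUBST_MOD",
    "BACKGROUND",
    "RATE_MAT",
    "TREE",
    "NRATECATS",
    "TRAINING_LNL",
}


def read_phast_mod(path) -> NeutralModel:
    """Parse a PHAST ``.mod`` file into a validated :class:`NeutralModel`.

    Supports ORDER 0 reversible nucleotide models (REV and its symmetric
    special cases). The rate matrix is renormalized to unit expected rate;
    the renormalization factor is logged.
    """
    if isinstance(path, (str,)) or hasattr(path, "__fspath__"):
        with open(path) as fh:
            text = fh.read()
    else:
        text = path.read()
    records: Dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        m = re.match(r"^([A-Z_0-9]+):\s*(.*)$", line)
        if not m:
            raise ModelFileError(f"unparseable line in .mod file: {line!r}")
        key, value = m.group(1), m.group(2)
        if key == "RATE_MAT":
            rows = []
            while i < len(lines) and len(rows) < 4:
                row = lines[i].strip()
                i += 1
                if row:
                    rows.append(row)
            records[key] = "\n".join(rows)
        else:
            records[key] = value
        if key not in _KNOWN_KEYS:
            logger.warning("ignoring unrecognized .mod key %s", key)

    for required in ("ALPHABET", "BACKGROUND", "RATE_MAT", "TREE"):
        if required not in records:
            raise ModelFileError(f"missing required record {required}")
    alphabet = records["ALPHABET"].split()
    if alphabet != list(BASES):
        raise ModelFileError(f"unsupported ALPHABET {records['ALPHABET']!r}")
    if records.get("ORDER", "0").strip() != "0":
        raise ModelFileError(
            f"unsupported ORDER {records.get('ORDER')!r}: only ORDER 0 models"
        )
    subst = records.get("SUBST_MOD", "REV").strip()
    if subst not in {"REV", "UNREST", "HKY85", "K80", "JC69", "F81", "SSREV"}:
        raise ModelFileError(f"unsupported SUBST_MOD {subst!r}")

    try:
        pi = np.array([float(x) for x in records["BACKGROUND"].split()])
    except ValueError as exc:
        raise ModelFileError(f"malformed BACKGROUND record: {exc}") from exc
    if pi.shape != (4,):
        raise ModelFileError("BACKGROUND must contain 4 frequencies")

    try:
        Q = np.array(
            [[float(x) for x in row.split()] for row in records["RATE_MAT"].splitlines()]
        )
    except ValueError as exc:
        raise ModelFileError(f"malformed RATE_MAT record: {exc}") from exc
    if Q.shape != (4, 4):
        raise ModelFileError("RATE_MAT must be a 4x4 matrix")

    tree = PhyloTree.from_newick(records["TREE"])
    Q, factor = normalize_rate_matrix(Q, pi)
    if abs(factor - 1.0) > 1e-9:
        logger.info("renormalized rate matrix by factor %.6g", factor)
    model = NeutralModel(tree=tree, pi=pi, Q=Q)
    model.validate()
    return model


def write_phast_mod(model: NeutralModel, path) -> None:
    """Write a model back to PHAST ``.mod`` text."""
    lines = [
        "ALPHABET: A C G T",
        "ORDER: 0",
        "SUBST_MOD: REV",
        "BACKGROUND: " + " ".join(f"{x:.15g}" for x in model.pi),
        "RATE_MAT:",
    ]
    for row in model.Q:
        lines.append("  " + " ".join(f"{x: .15g}" for x in row))
    lines.append("TREE: " + model.tree.to_newick())
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Model transformations
# ---------------------------------------------------------------------------


def scale_tree(model: NeutralModel, factor: float) -> NeutralModel:
    """Multiply every branch length by ``factor`` (pi and Q unchanged)."""
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return NeutralModel(tree=model.tree.scaled(factor), pi=model.pi, Q=model.Q)


def adapt_background_gc(
    model: NeutralModel,
    alignment: MultipleAlignment,
    excluded_species: Iterable[str] = (),
) -> NeutralModel:
    """Adapt the background frequencies to the local GC content of the
    alignment, excluding the given species (e.g. the primates under test).

    Let g be the GC fraction over unambiguous bases in non-excluded rows.
    The new pi preserves the within-class ratios pi_G:pi_C and pi_A:pi_T and
    satisfies pi'_G + pi'_C = g exactly; the rate matrix is rebuilt from the
    exchangeabilities of the input model and renormalized to unit rate.
    """
    excluded = set(excluded_species)
    rows = [sp for sp in alignment.species if sp not in excluded]
    counts = alignment.base_counts(rows)
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError(
            "no unambiguous bases in non-excluded alignment rows"
        )
    g = (counts[BASE_INDEX["G"]] + counts[BASE_INDEX["C"]]) / total
    # keep strictly inside (0,1) so all frequencies stay positive
    eps = 1e-6
    g = min(max(g, eps), 1.0 - eps)
    pi = model.pi
    gc = pi[1] + pi[2]
    at = pi[0] + pi[3]
    new_pi = np.array(
        [
            (1.0 - g) * pi[0] / at,
            g * pi[1] / gc,
            g * pi[2] / gc,
            (1.0 - g) * pi[3] / at,
        ]
    )
    Q = build_reversible_q(model.exchangeabilities(), new_pi)
    out = NeutralModel(tree=model.tree, pi=new_pi, Q=Q)
    out.validate()
    return out


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P = exp(Q t) for a valid rate matrix; rows sum to 1."""
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    P = scipy.linalg.expm(np.asarray(Q, dtype=float) * t)
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def _pattern_compress(
    tree: PhyloTree, alignment: MultipleAlignment
) -> Tuple[np.ndarray, np.ndarray]:
    """Unique site patterns over tree leaves: (patterns[k, leaf], counts[k]).

    Tree leaves absent from the alignment contribute missing data; alignment
    rows absent from the tree raise a name-mismatch error.
    """
    cache = getattr(alignment, "_pattern_cache", None)
    key = id(tree)
    if cache is not None and cache[0] == key:
        return cache[1], cache[2]
    extra = set(alignment.species) - set(tree.leaf_names)
    if extra:
        raise ValueError(
            f"alignment species not in tree: {sorted(extra)}"
        )
    ncol = alignment.n_columns
    codes = alignment.codes()
    order = {sp: i for i, sp in enumerate(alignment.species)}
    mat = np.full((len(tree.leaves), ncol), MISSING_CODE, dtype=np.int8)
    for j, v in enumerate(tree.leaves):
        name = tree.names[v]
        if name in order:
            mat[j] = codes[order[name]]
    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    alignment._pattern_cache = (key, patterns, counts)
    return patterns, counts


def log_likelihood(
    model: NeutralModel,
    alignment: MultipleAlignment,
    branch_matrices: Optional[Mapping[str, np.ndarray]] = None,
    tree_scale: float = 1.0,
) -> float:
    """Pruning log-likelihood of the alignment under the model.

    ``branch_matrices`` maps a leaf name to a replacement rate matrix for
    that terminal branch (used for accelerated lineages); all other branches
    use the model's neutral Q. ``tree_scale`` multiplies every branch length.
    Missing characters (N, -) contribute all-ones partials; an alignment of
    only missing data therefore has log-likelihood exactly 0.
    """
    if tree_scale <= 0:
        raise ValueError(f"tree_scale must be positive, got {tree_scale}")
    tree = model.tree
    patterns, counts = _pattern_compress(tree, alignment)
    if patterns.shape[0] == 0:
        return 0.0

    P = model.branch_transition_matrices(tree_scale)
    if branch_matrices:
        for name, Qmod in branch_matrices.items():
            if name not in tree.leaf_index:
                raise ValueError(f"branch override for unknown leaf {name!r}")
            v = tree.leaf_index[name]
            P[v] = transition_matrix(Qmod, tree.lengths[v] * tree_scale)

    npat = patterns.shape[0]
    leaf_pos = {v: j for j, v in enumerate(tree.leaves)}
    partials = np.empty((len(tree.parent), npat, 4))
    logscale = np.zeros(npat)
    for v in tree.postorder:
        if not tree.children[v]:
            partials[v] = _LEAF_PARTIALS[patterns[:, leaf_pos[v]]]
        else:
            acc = np.ones((npat, 4))
            for c in tree.children[v]:
                acc *= partials[c] @ P[c].T
            m = acc.max(axis=1)
            # rescale to avoid underflow on deep trees / long alignments
            safe = np.where(m > 0, m, 1.0)
            acc /= safe[:, None]
            logscale += np.where(m > 0, np.log(safe), -np.inf)
            partials[v] = acc
    site = partials[tree.root] @ model.pi
    with np.errstate(divide="ignore"):
        site_log = np.log(site) + logscale
    # fully missing columns contribute likelihood exactly 1 by definition
    all_missing = (patterns == MISSING_CODE).all(axis=1)
    site_log[all_missing] = 0.0
    return float(np.dot(counts, site_log))
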
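"""Shared fixtures: small models, random reversible matrices, and the
exhaustive internal-state-enumeration likelihood oracle."""

import itertools

import numpy as np
import pytest

from accelscan.phylo_core import (
    BASE_INDEX,
    MISSING_CODE,
    MultipleAlignment,
    NeutralModel,
    PhyloTree,
    build_reversible_q,
    transition_matrix,
)

APE_MOD_TEXT = """\
ALPHABET: A C G T
ORDER: 0
SUBST_MOD: JC69
BACKGROUND: 0.25 0.25 0.25 0.25
RATE_MAT:
  -1.0  0.333333333333333  0.333333333333333  0.333333333333334
   0.333333333333333 -1.0  0.333333333333333  0.333333333333334
   0.333333333333333  0.333333333333333 -1.0  0.333333333333334
   0.333333333333334  0.333333333333333  0.333333333333333 -1.0
TREE: ((((hg19:0.0066,panTro4:0.0068):0.0022,gorGor3:0.0088):0.0092,ponAbe2:0.018):0.0064,nomLeu3:0.022);
"""


@pytest.fixture()
def ape_mod_path(tmp_path):
    path = tmp_path / "ape.mod"
    path.write_text(APE_MOD_TEXT)
    return path


@pytest.fixture(scope="session")
def surrogate_model():
    from accelscan.simulate import load_surrogate_model

    return load_surrogate_model()


@pytest.fixture(scope="session")
def scaled_surrogate(surrogate_model):
    from accelscan.phylo_core import scale_tree

    return scale_tree(surrogate_model, 0.1)


def jc_q() -> np.ndarray:
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    return Q


def random_reversible_model(rng: np.random.Generator, newick: str) -> NeutralModel:
    """A random reversible model on the given tree."""
    pi = rng.dirichlet(np.full(4, 5.0))
    s = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1, 4):
            s[i, j] = s[j, i] = rng.uniform(0.2, 5.0)
    Q = build_reversible_q(s, pi)
    model = NeutralModel(tree=PhyloTree.from_newick(newick), pi=pi, Q=Q)
    model.validate()
    return model


def random_alignment(
    rng: np.random.Generator, species, n_cols: int, missing_frac: float = 0.15
) -> MultipleAlignment:
    alphabet = "ACGTN-"
    probs = np.array([1, 1, 1, 1, 0, 0], dtype=float)
    probs = (1 - missing_frac) * probs / 4.0
    probs[4] = probs[5] = missing_frac / 2.0
    seqs = {
        sp: "".join(rng.choice(list(alphabet), size=n_cols, p=probs))
        for sp in species
    }
    return MultipleAlignment(seqs)


def brute_force_loglik(
    model: NeutralModel,
    alignment: MultipleAlignment,
    branch_matrices=None,
    tree_scale: float = 1.0,
) -> float:
    """Exhaustive sum over all internal-node (and missing-leaf) state
    assignments; independent of the pruning recursion."""
    tree = model.tree
    n = len(tree.parent)
    P = {}
    for v in range(n):
        if v == tree.root:
            continue
        name = tree.names[v]
        Q = model.Q
        if branch_matrices and name in branch_matrices:
            Q = branch_matrices[name]
        P[v] = transition_matrix(Q, tree.lengths[v] * tree_scale)
    codes = alignment.codes()
    order = {sp: i for i, sp in enumerate(alignment.species)}
    total = 0.0
    for col in range(alignment.n_columns):
        col_like = 0.0
        # allowed states per node
        allowed = []
        for v in range(n):
            name = tree.names[v]
            if not tree.children[v] and name in order:
                c = codes[order[name], col]
                allowed.append(range(4) if c == MISSING_CODE else (int(c),))
            else:
                allowed.append(range(4))
        for assign in itertools.product(*allowed):
            prob = model.pi[assign[tree.root]]
            for v in range(n):
                if v == tree.root:
                    continue
                prob *= P[v][assign[tree.parent[v]], assign[v]]
            col_like += prob
        total += np.log(col_like)
    return float(total)
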
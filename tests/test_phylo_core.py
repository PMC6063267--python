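"""Model file I/O, background adaptation, and the likelihood engine."""

import io

import numpy as np
import pytest

from accelscan.phylo_core import (
    AlignmentFormatError,
    GenomicInterval,
    InsufficientDataError,
    ModelFileError,
    MultipleAlignment,
    NeutralModel,
    PhyloTree,
    adapt_background_gc,
    log_likelihood,
    read_alignment,
    read_phast_mod,
    scale_tree,
    transition_matrix,
    write_phast_mod,
)

from conftest import (
    APE_MOD_TEXT,
    brute_force_loglik,
    random_alignment,
    random_reversible_model,
)


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)
        assert len(GenomicInterval("chr1", 10, 25)) == 15

    def test_gap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.gap_to(GenomicInterval("chr1", 15, 20)) == 5
        assert a.gap_to(GenomicInterval("chr1", 5, 20)) == 0
        assert a.gap_to(GenomicInterval("chr2", 15, 20)) is None


class TestModFile:
    def test_parse_jc_fixture(self, ape_mod_path):
        model = read_phast_mod(ape_mod_path)
        assert np.allclose(model.pi, 0.25)
        off = model.Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])
        assert sorted(model.tree.leaf_names) == [
            "gorGor3", "hg19", "nomLeu3", "panTro4", "ponAbe2",
        ]
        assert model.tree.branch_length("hg19") == pytest.approx(0.0066)
        assert model.tree.branch_length("nomLeu3") == pytest.approx(0.022)

    def test_reversibility_of_parsed_model(self, surrogate_model):
        flux = surrogate_model.pi[:, None] * surrogate_model.Q
        assert np.max(np.abs(flux - flux.T)) < 1e-9

    def test_renormalized_to_unit_rate(self, surrogate_model):
        rate = -np.dot(surrogate_model.pi, np.diag(surrogate_model.Q))
        assert rate == pytest.approx(1.0, abs=1e-9)

    def test_round_trip(self, surrogate_model, tmp_path):
        path = tmp_path / "out.mod"
        write_phast_mod(surrogate_model, path)
        again = read_phast_mod(path)
        assert np.allclose(again.pi, surrogate_model.pi, atol=1e-9)
        assert np.allclose(again.Q, surrogate_model.Q, atol=1e-9)
        assert again.tree.to_newick() == surrogate_model.tree.to_newick()

    @pytest.mark.parametrize(
        "mangle, match",
        [
            (lambda t: t.replace("BACKGROUND: ", "BACKGROUND: junk "),
             "BACKGROUND"),
            (lambda t: t.replace("ORDER: 0", "ORDER: 2"), "ORDER"),
            (lambda t: "\n".join(
                l for l in t.splitlines() if not l.startswith("TREE")
            ), "TREE"),
        ],
    )
    def test_malformed_records(self, mangle, match):
        with pytest.raises(ModelFileError, match=match):
            read_phast_mod(io.StringIO(mangle(APE_MOD_TEXT)))

    def test_non_reversible_matrix_rejected(self):
        bad = APE_MOD_TEXT.replace("BACKGROUND: 0.25 0.25 0.25 0.25",
                                   "BACKGROUND: 0.4 0.1 0.2 0.3")
        from accelscan.phylo_core import ModelValidationError

        with pytest.raises(ModelValidationError):
            read_phast_mod(io.StringIO(bad))


class TestAlignmentIO:
    def test_fasta(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">sp1\nACGTACGTAC\n>sp2\nacgtnacgta\n")
        alns = read_alignment(path, "FASTA")
        assert len(alns) == 1
        assert alns[0].species == ["sp1", "sp2"]
        assert alns[0].n_columns == 10
        assert alns[0].sequences["sp2"] == "ACGTNACGTA"

    def test_maf_blocks_in_order(self, tmp_path):
        path = tmp_path / "a.maf"
        path.write_text(
            "##maf version=1\n"
            "a score=1.0\n"
            "s hg19.chr1 10 4 + 1000 ACGT\n"
            "s panTro4.chr1 20 4 + 900 ACGA\n"
            "\n"
            "a score=2.0\n"
            "s hg19.chr1 50 3 + 1000 GGG\n"
            "s panTro4.chr1 60 3 + 900 GGC\n"
        )
        alns = read_alignment(path, "MAF")
        assert len(alns) == 2
        assert alns[0].ref_interval == GenomicInterval("chr1", 10, 14)
        assert alns[1].sequences["hg19"] == "GGG"

    def test_ambiguity_mapped_to_n(self):
        aln = MultipleAlignment({"a": "ACRT", "b": "AC-T"})
        assert aln.sequences["a"] == "ACNT"

    def test_ragged_rejected(self):
        with pytest.raises(AlignmentFormatError, match="ragged"):
            MultipleAlignment({"a": "ACGT", "b": "ACG"})

    def test_unknown_character_named(self):
        with pytest.raises(AlignmentFormatError, match="'!'"):
            MultipleAlignment({"a": "AC!T"})


class TestScaleTree:
    def test_scaling_and_composition(self, surrogate_model):
        total = surrogate_model.tree.total_length()
        scaled = scale_tree(surrogate_model, 0.1)
        assert scaled.tree.total_length() == pytest.approx(0.1 * total)
        assert np.allclose(scaled.Q, surrogate_model.Q)
        same = scale_tree(surrogate_model, 1.0)
        assert same.tree.to_newick() == surrogate_model.tree.to_newick()
        twice = scale_tree(scale_tree(surrogate_model, 0.5), 0.5)
        once = scale_tree(surrogate_model, 0.25)
        assert np.allclose(twice.tree.lengths, once.tree.lengths)

    def test_nonpositive_factor(self, surrogate_model):
        with pytest.raises(ValueError):
            scale_tree(surrogate_model, 0.0)


class TestGCAdaptation:
    def test_fixed_point(self, surrogate_model):
        gc = surrogate_model.pi[1] + surrogate_model.pi[2]
        n_gc = int(round(gc * 1000))
        aln = MultipleAlignment(
            {"mm10": "G" * n_gc + "A" * (1000 - n_gc)}
        )
        adapted = adapt_background_gc(surrogate_model, aln, excluded_species=())
        assert np.allclose(adapted.pi, surrogate_model.pi, atol=1e-9)
        assert np.allclose(adapted.Q, surrogate_model.Q, atol=1e-9)

    def test_uniform_pi_gc_06(self):
        from accelscan.phylo_core import build_reversible_q

        rng = np.random.default_rng(0)
        s = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                s[i, j] = s[j, i] = rng.uniform(0.5, 3.0)
        pi = np.full(4, 0.25)
        model = NeutralModel(
            tree=PhyloTree.from_newick("(a:0.1,b:0.1);"),
            pi=pi,
            Q=build_reversible_q(s, pi),
        )
        aln = MultipleAlignment({"a": "G" * 6 + "A" * 4})
        adapted = adapt_background_gc(model, aln, excluded_species=())
        assert np.allclose(adapted.pi, [0.2, 0.3, 0.3, 0.2])

    def test_properties_preserved(self, surrogate_model):
        rng = np.random.default_rng(1)
        aln = random_alignment(rng, surrogate_model.tree.leaf_names, 200)
        adapted = adapt_background_gc(
            surrogate_model, aln, excluded_species=("hg19", "panTro4")
        )
        counts = aln.base_counts(
            [s for s in aln.species if s not in ("hg19", "panTro4")]
        )
        g = (counts[1] + counts[2]) / counts.sum()
        assert adapted.pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert adapted.pi[1] + adapted.pi[2] == pytest.approx(g, abs=1e-9)
        adapted.validate()

    def test_excluded_species_ignored(self, surrogate_model):
        aln = MultipleAlignment({"hg19": "GGGG", "mm10": "AATT"})
        adapted = adapt_background_gc(
            surrogate_model, aln, excluded_species=("hg19",)
        )
        # only the AT-rich mouse row counts
        assert adapted.pi[1] + adapted.pi[2] < 0.01

    def test_all_missing_rejected(self, surrogate_model):
        aln = MultipleAlignment({"hg19": "GGGG", "mm10": "NN--"})
        with pytest.raises(InsufficientDataError):
            adapt_background_gc(surrogate_model, aln, excluded_species=("hg19",))


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        from conftest import jc_q

        assert np.allclose(transition_matrix(jc_q(), 0.0), np.eye(4))

    def test_jc_closed_form(self):
        from conftest import jc_q

        for t in (0.01, 0.3, 1.5):
            P = transition_matrix(jc_q(), t)
            expected_off = (1.0 - np.exp(-4.0 * t / 3.0)) / 4.0
            off = P[~np.eye(4, dtype=bool)]
            assert np.allclose(off, expected_off, atol=1e-12)

    def test_rows_stochastic_and_semigroup(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            model = random_reversible_model(rng, "(a:0.1,b:0.1);")
            Q = model.Q
            P = transition_matrix(Q, 0.3)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            s, t = rng.uniform(0.05, 1.0, size=2)
            left = transition_matrix(Q, s + t)
            right = transition_matrix(Q, s) @ transition_matrix(Q, t)
            assert np.allclose(left, right, atol=1e-9)

    def test_negative_time_rejected(self):
        from conftest import jc_q

        with pytest.raises(ValueError):
            transition_matrix(jc_q(), -0.1)


class TestLogLikelihood:
    NEWICKS = [
        "((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.1);",
        "(((a:0.1,b:0.2):0.1,c:0.3):0.2,(d:0.15,e:0.25):0.1);",
        "(a:0.2,b:0.3,(c:0.1,(d:0.4,e:0.2):0.1):0.3);",
    ]

    def test_all_missing_is_zero(self, surrogate_model):
        aln = MultipleAlignment(
            {sp: "N-N-" for sp in surrogate_model.tree.leaf_names}
        )
        assert log_likelihood(surrogate_model, aln) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("idx, newick", list(enumerate(NEWICKS)))
    def test_matches_enumeration_oracle(self, idx, newick):
        rng = np.random.default_rng(1000 + idx)
        model = random_reversible_model(rng, newick)
        species = model.tree.leaf_names
        aln = random_alignment(rng, species, 6)
        for scale in (1.0, 0.37):
            got = log_likelihood(model, aln, tree_scale=scale)
            want = brute_force_loglik(model, aln, tree_scale=scale)
            assert got == pytest.approx(want, abs=1e-10)

    def test_oracle_with_modified_branch(self):
        from accelscan.accel_models import lineage_rate_matrix

        rng = np.random.default_rng(11)
        model = random_reversible_model(rng, self.NEWICKS[0])
        aln = random_alignment(rng, model.tree.leaf_names, 5)
        branch = {"a": lineage_rate_matrix(model.Q, 2.0, 1.5)}
        got = log_likelihood(model, aln, branch_matrices=branch)
        want = brute_force_loglik(model, aln, branch_matrices=branch)
        assert got == pytest.approx(want, abs=1e-10)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        model = random_reversible_model(rng, self.NEWICKS[1])
        aln = random_alignment(rng, model.tree.leaf_names, 40)
        perm = rng.permutation(40)
        shuffled = MultipleAlignment(
            {sp: "".join(seq[j] for j in perm) for sp, seq in aln.sequences.items()}
        )
        assert log_likelihood(model, aln) == pytest.approx(
            log_likelihood(model, shuffled), abs=1e-9
        )

    def test_nonpositive_for_observed_bases(self, surrogate_model):
        rng = np.random.default_rng(5)
        aln = random_alignment(
            rng, surrogate_model.tree.leaf_names, 30, missing_frac=0.0
        )
        assert log_likelihood(surrogate_model, aln) <= 0.0

    def test_unknown_species_rejected(self, surrogate_model):
        aln = MultipleAlignment({"hg19": "ACGT", "unicorn": "ACGT"})
        with pytest.raises(ValueError, match="unicorn"):
            log_likelihood(surrogate_model, aln)

    def test_missing_leaf_equals_masked_leaf(self, surrogate_model):
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, surrogate_model.tree.leaf_names, 25)
        dropped = MultipleAlignment(
            {sp: s for sp, s in aln.sequences.items() if sp != "mm10"}
        )
        masked = aln.with_sequence("mm10", "N" * 25)
        assert log_likelihood(surrogate_model, dropped) == pytest.approx(
            log_likelihood(surrogate_model, masked), abs=1e-10
        )
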
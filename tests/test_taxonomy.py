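"""Taxonomy tree, naive-Bayes classifier, LCA assignment, profiles."""

import numpy as np
import pytest

from amplicomm.read_qc import Read, demultiplex, quality_filter
from amplicomm.taxonomy import (
    RANKS,
    Assignment,
    HitRecord,
    NaiveBayesClassifier,
    TaxonomyError,
    TaxonomyTree,
    build_profile,
    filter_domain,
    kmer_indices,
    lca_assign,
)

from oracles import enumerate_words

LINEAGES = [
    ("Bacteria", "P1", "C1", "O1", "F1", "GenusA"),
    ("Bacteria", "P1", "C1", "O1", "F1", "GenusB"),
    ("Bacteria", "P1", "C1", "O1", "F2", "GenusC"),
    ("Bacteria", "P2", "C2", "O2", "F3", "GenusD"),
]


@pytest.fixture(scope="module")
def tree():
    return TaxonomyTree.from_lineages(LINEAGES)


def _gid(name):
    return TaxonomyTree.node_id("genus", name)


class TestTree:
    def test_lca_of_sibling_genera_is_their_family(self, tree):
        lca = tree.lca([_gid("GenusA"), _gid("GenusB")])
        assert tree.rank_of(lca) == "family" and tree.name_of(lca) == "F1"

    def test_lca_across_phyla_is_the_domain(self, tree):
        lca = tree.lca([_gid("GenusA"), _gid("GenusD")])
        assert tree.name_of(lca) == "Bacteria"

    def test_single_taxon_is_its_own_lca(self, tree):
        assert tree.lca([_gid("GenusC")]) == _gid("GenusC")

    def test_conflicting_parents_rejected(self):
        with pytest.raises(TaxonomyError):
            TaxonomyTree.from_lineages(
                [
                    ("Bacteria", "P1", "C1", "O1", "F1", "GenusA"),
                    ("Bacteria", "P9", "C1", "O1", "F1", "GenusB"),  # F1 under two orders' paths
                ]
            )


class TestTrainNaiveBayes:
    def test_word_counts_match_hand_enumeration(self, rng):
        # three toy references; the model's per-genus word sets must equal
        # brute-force 8-mer enumeration
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(3)]
        refs = [(s, LINEAGES[i]) for i, s in enumerate(seqs)]
        model = NaiveBayesClassifier(8).train(refs)
        for seq, lineage in refs:
            genus_idx = model.genera.index(lineage[-1])
            expected = enumerate_words(seq, 8)
            n_total = len(refs)
            # words present in this genus have probability (1 + prior)/2,
            # absent words prior/2 -- so presence is recoverable by threshold
            probs = np.exp(model._log_prob[genus_idx].astype(np.float64))
            present = set(np.where(probs > 0.5)[0])
            got = {int(w) for w in kmer_indices(seq, 8)}
            assert present == got
            assert len(got) == len(expected)

    def test_duplicate_references_change_nothing_qualitative(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(2)]
        refs = [(s, LINEAGES[i]) for i, s in enumerate(seqs)]
        a = NaiveBayesClassifier(8).train(refs)
        b = NaiveBayesClassifier(8).train(refs + refs)
        query = seqs[0]
        assert (
            a.classify(query, rng=1).taxon_id == b.classify(query, rng=1).taxon_id
        )

    def test_incomplete_lineage_rejected(self):
        with pytest.raises(TaxonomyError):
            NaiveBayesClassifier(8).train([("ACGTACGTACGT", ("Bacteria", "GenusX"))])


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(42)
    refs = [
        ("".join(rng.choice(list("ACGT"), size=150)), lineage)
        for lineage in LINEAGES
    ]
    return NaiveBayesClassifier(8).train(refs), refs


class TestClassify:
    def test_reference_read_gets_full_confidence(self, model):
        clf, refs = model
        asg = clf.classify(refs[0][0], rng=0)
        assert clf.tree.name_of(asg.taxon_id) == "GenusA"
        assert asg.confidences["genus"] == 1.0

    def test_random_read_has_low_genus_confidence(self, model):
        clf, _ = model
        rng = np.random.default_rng(77)
        query = "".join(rng.choice(list("ACGT"), size=150))
        asg = clf.classify(query, rng=5)
        assert asg.confidences["genus"] < 0.5

    def test_identical_references_in_two_genera_split_confidence(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        other = "".join(rng.choice(list("ACGT"), size=150))
        refs = [
            (seq, ("Bacteria", "P1", "C1", "O1", "F1", "GenusA")),
            (seq, ("Bacteria", "P1", "C1", "O1", "F1", "GenusB")),
            (other, ("Bacteria", "P2", "C2", "O2", "F3", "GenusD")),
        ]
        clf = NaiveBayesClassifier(8).train(refs)
        asg = clf.classify(seq, n_bootstrap=400, rng=3)
        assert asg.confidences["family"] == 1.0
        assert 0.3 < asg.confidences["genus"] < 0.7

    def test_confidence_never_increases_with_depth(self, model):
        clf, refs = model
        rng = np.random.default_rng(19)
        for _ in range(10):
            ref_seq = refs[int(rng.integers(len(refs)))][0]
            noisy = list(ref_seq)
            for i in rng.choice(len(noisy), size=15, replace=False):
                noisy[i] = "ACGT"[int(rng.integers(4))]
            asg = clf.classify("".join(noisy), rng=rng)
            confs = [asg.confidences[r] for r in RANKS]
            assert all(a >= b - 1e-12 for a, b in zip(confs, confs[1:]))

    def test_too_short_read_unassigned_with_reason(self, model):
        clf, _ = model
        asg = clf.classify("ACGT", rng=0)
        assert asg.taxon_id is None and asg.reason == "too_short"

    def test_deterministic_for_fixed_seed(self, model):
        clf, refs = model
        noisy = refs[1][0][:100] + refs[2][0][100:]
        a = clf.classify(noisy, n_bootstrap=50, rng=123)
        b = clf.classify(noisy, n_bootstrap=50, rng=123)
        assert a.taxon_id == b.taxon_id and a.confidences == b.confidences


class TestFilterDomain:
    def test_without_archaeal_references_nothing_removed(self, rng):
        refs = [
            ("".join(rng.choice(list("ACGT"), size=120)), LINEAGES[0]),
        ]
        clf = NaiveBayesClassifier(8).train(refs)
        reads = [Read("r1", refs[0][0])]
        kept, removed = filter_domain(reads, clf)
        assert removed == 0 and len(kept) == 1

    def test_all_injected_archaea_removed_without_errors(self, noiseless_run):
        # noiseless fixture has archaea_fraction=0; use a dedicated spec
        from amplicomm.synthetic import default_community_spec, generate
        from amplicomm.taxonomy import NaiveBayesClassifier as NBC

        spec = default_community_spec(
            seed=21, n_reads=400, error_rate=0.0, ambig_rate=0.0,
            chimera_rate=0.0, short_rate=0.0, archaea_fraction=0.05,
        )
        reads, truth = generate(spec)
        clf = NBC(8).train(spec.references())
        assigned, _ = demultiplex(
            reads, {s.sample_id: s.barcode for s in spec.samples}, spec.adaptor
        )
        for sid, sample_reads in assigned.items():
            kept_q, _ = quality_filter(sample_reads, spec.primer)
            kept, removed = filter_domain(kept_q, clf, rng=0)
            truly_archaeal = sum(
                1 for r in kept_q if truth.records[r.read_id].source == "archaea"
            )
            assert removed == truly_archaeal
            assert all(truth.records[r.read_id].source != "archaea" for r in kept)


class TestLcaAssign:
    def _hit(self, genus, score, rid="r1"):
        return HitRecord(rid, f"ref|{genus}", 99.0, 100, score, genus)

    def test_single_strong_hit_assigns_the_genus(self, tree):
        asg = lca_assign([self._hit("GenusC", 100.0)], tree)
        assert asg.taxon_id == _gid("GenusC")

    def test_two_genera_of_one_family_collapse_to_family(self, tree):
        asg = lca_assign([self._hit("GenusA", 100.0), self._hit("GenusB", 100.0)], tree)
        assert tree.name_of(asg.taxon_id) == "F1"
        assert tree.rank_of(asg.taxon_id) == "family"

    def test_hits_below_bitscore_cutoff_are_ignored(self, tree):
        asg = lca_assign([self._hit("GenusA", 85.9), self._hit("GenusB", 50.0)], tree)
        assert asg.taxon_id is None

    def test_top_percent_window_prunes_weak_hits(self, tree):
        # second hit at 88% of best falls outside the 10% window
        asg = lca_assign([self._hit("GenusA", 200.0), self._hit("GenusC", 176.0)], tree)
        assert asg.taxon_id == _gid("GenusA")

    def test_unknown_subject_taxon_raises_with_name(self, tree):
        with pytest.raises(TaxonomyError, match="GenusZ"):
            lca_assign([self._hit("GenusZ", 100.0)], tree)

    def test_adding_hits_only_moves_assignment_rootward(self, tree, rng):
        genera = ["GenusA", "GenusB", "GenusC", "GenusD"]
        for _ in range(25):
            k = int(rng.integers(1, 5))
            hits = [
                self._hit(genera[int(rng.integers(4))], float(rng.uniform(90, 100)))
                for _ in range(k)
            ]
            base = lca_assign(hits, tree, top_percent=1.0)
            extra = hits + [self._hit(genera[int(rng.integers(4))], 95.0)]
            deeper = lca_assign(extra, tree, top_percent=1.0)
            assert base.taxon_id in tree.path(base.taxon_id)
            assert deeper.taxon_id in tree.path(base.taxon_id)  # ancestor-or-self


class TestBuildProfile:
    def _assignments(self, tree, counts):
        out = []
        i = 0
        for taxon, n in counts.items():
            for _ in range(n):
                out.append(Assignment(f"r{i}", taxon, "lca"))
                i += 1
        return out

    def test_dominant_order_share_rounds_to_67_percent(self, tree):
        asgs = self._assignments(
            tree, {_gid("GenusA"): 12594, _gid("GenusD"): 6214}
        )
        profile = build_profile(asgs, tree, "order", min_support=30)
        assert profile.n_reads == 18808
        assert round(100 * profile.fractions["O1"]) == 67

    def test_min_support_zero_reports_everything(self, tree):
        asgs = self._assignments(tree, {_gid("GenusA"): 3, _gid("GenusC"): 2})
        profile = build_profile(asgs, tree, "genus", min_support=0)
        assert profile.fractions == {"GenusA": 0.6, "GenusC": 0.4}
        assert profile.unassigned == 0.0

    def test_all_unassigned_gives_unassigned_mass_one(self, tree):
        asgs = [Assignment(f"r{i}", None, "lca") for i in range(5)]
        profile = build_profile(asgs, tree, "genus", min_support=0)
        assert profile.fractions == {} and profile.unassigned == 1.0

    def test_suppressed_taxa_mass_is_conserved(self, tree):
        asgs = self._assignments(tree, {_gid("GenusA"): 100, _gid("GenusC"): 5})
        profile = build_profile(asgs, tree, "genus", min_support=30)
        assert "GenusC" not in profile.fractions
        total = sum(profile.fractions.values()) + profile.unassigned
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_order_invariance(self, tree, rng):
        asgs = self._assignments(tree, {_gid("GenusA"): 40, _gid("GenusB"): 35, _gid("GenusD"): 31})
        shuffled = list(asgs)
        rng.shuffle(shuffled)
        a = build_profile(asgs, tree, "genus", min_support=30)
        b = build_profile(shuffled, tree, "genus", min_support=30)
        assert a.fractions == b.fractions
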
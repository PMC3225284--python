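import pytest

from cbcmap.ancestral import branch_change_table
from cbcmap.io import Dataset, PairedAlignment, PairTable, read_tree
from cbcmap.pair_events import (
    classify_pair_change,
    pathway_audit,
    phenetic_compare,
    scan_pair_events,
    type_homoplasy,
)
from cbcmap.simulate import SimConfig, simulate


def make_pair_dataset(newick, taxa_states, conserved=True):
    """One base pair (columns 0,1) with per-taxon 2-character states."""
    taxa = tuple(taxa_states)
    alignment = PairedAlignment(taxa=taxa, rows=tuple(taxa_states[t] for t in taxa))
    structure = PairTable(
        pairs=((0, 1),), conserved=(conserved,), helix=(2,), n_columns=2
    )
    tree = read_tree(newick, taxa=list(taxa))
    return Dataset(alignment=alignment, structure=structure, tree=tree)


class TestClassification:
    @pytest.mark.parametrize(
        "parent,child,expected",
        [
            (("G", "C"), ("A", "U"), "CBC"),
            (("G", "C"), ("G", "U"), "hCBC"),
            (("G", "C"), ("G", "A"), "pair_loss"),
            (("U", "U"), ("C", "C"), "mismatch_change"),
            (("G", "A"), ("G", "C"), "pair_gain"),
            (("G", "U"), ("U", "G"), "CBC"),
            (("G", "U"), ("G", "C"), "hCBC"),
            (("G", "C"), ("G", "C"), None),
        ],
    )
    def test_classes(self, parent, child, expected):
        assert classify_pair_change(parent, child) == expected

    def test_missing_side_rejected(self):
        with pytest.raises(ValueError):
            classify_pair_change(("G", "N"), ("G", "C"))

    def test_orientation_matters(self):
        # G-U and U-G are distinct states: swapping sides is a double change
        assert classify_pair_change(("G", "U"), ("U", "G")) == "CBC"


class TestScan:
    def test_double_change_is_one_cbc(self):
        ds = make_pair_dataset(
            "((A,B),(C,D));", {"A": "AU", "B": "GC", "C": "GC", "D": "GC"}
        )
        recon = branch_change_table(ds)
        events, skipped = scan_pair_events(ds, recon)
        assert len(events) == 1
        assert events[0].event_class == "CBC"
        assert events[0].branch == "A"
        assert not skipped

    def test_single_side_change_is_hcbc(self):
        ds = make_pair_dataset(
            "((A,B),(C,D));", {"A": "GU", "B": "GC", "C": "GC", "D": "GC"}
        )
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        assert [e.event_class for e in events] == ["hCBC"]

    def test_missing_partner_skips_event(self):
        ds = make_pair_dataset(
            "((A,B),(C,D));", {"A": "A-", "B": "GC", "C": "GC", "D": "GC"}
        )
        recon = branch_change_table(ds)
        events, skipped = scan_pair_events(ds, recon)
        assert events == []
        assert [s.branch for s in skipped] == ["A"]

    def test_event_class_partition(self):
        # every changed branch x pair cell receives exactly one class
        ds, truth = simulate(SimConfig(seed=3, mode="direct"))
        recon = branch_change_table(ds)
        events, skipped = scan_pair_events(ds, recon)
        keys = [(e.branch, e.pair) for e in events]
        assert len(keys) == len(set(keys))

    def test_planted_cbc_recovered(self):
        ds, truth = simulate(SimConfig(seed=7, mode="no_multihit", n_leaves=6,
                                       r_cbc=0.25, r_hcbc=0.0, r_break=0.0,
                                       r_restore=0.0, r_unpaired=0.0))
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        detected = {(e.branch, e.pair, e.event_class) for e in events}
        assert detected == truth.triples()


class TestHomoplasy:
    def test_parallelism(self):
        # outgroup pair (E,F) anchors the ancestral G-C, so A and C both
        # change G-C -> A-U on independent terminal branches
        ds = make_pair_dataset(
            "(((A,B),(C,D)),(E,F));",
            {"A": "AU", "B": "GC", "C": "AU", "D": "GC", "E": "GC", "F": "GC"},
        )
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        typed = type_homoplasy(events, ds.tree, recon)
        assert {e.branch for e in typed} == {"A", "C"}
        assert {e.homoplasy_label for e in typed} == {"PAR"}
        assert len({e.group_id for e in typed}) == 1

    def test_convergence(self):
        # the same derived state A-U reached from G-C in one family and from
        # U-A in the other
        ds = make_pair_dataset(
            "(((A,A2),(B,B2)),((C,C2),(D,D2)));",
            {
                "A": "AU", "A2": "GC", "B": "GC", "B2": "GC",
                "C": "AU", "C2": "UA", "D": "UA", "D2": "UA",
            },
        )
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        typed = type_homoplasy(events, ds.tree, recon)
        cbc = [e for e in typed if e.event_class == "CBC" and e.child_state == ("A", "U")]
        assert len(cbc) == 2
        assert {e.homoplasy_label for e in cbc} == {"CONV"}
        assert len({e.parent_state for e in cbc}) == 2

    def test_reversal_on_root_path(self):
        # C-G -> U-G on the inner branch, U-G -> C-G again in a descendant
        ds = make_pair_dataset(
            "((((A,B),C),D),(E,F));",
            {"A": "CG", "B": "UG", "C": "UG", "D": "CG", "E": "CG", "F": "CG"},
        )
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        typed = type_homoplasy(events, ds.tree, recon)
        rev = [e for e in typed if e.branch == "A"]
        assert len(rev) == 1
        assert rev[0].homoplasy_label == "REV"
        assert rev[0].child_state == ("C", "G")
        assert rev[0].group_id.startswith("hREV")

    def test_no_event_is_both_par_and_conv(self):
        for seed in range(5):
            ds, _ = simulate(SimConfig(seed=seed, mode="direct", r_cbc=0.3))
            recon = branch_change_table(ds)
            events, _ = scan_pair_events(ds, recon)
            typed = type_homoplasy(events, ds.tree, recon)
            for ev in typed:
                if ev.group_id:
                    assert not ("PAR" in ev.group_id and "CONV" in ev.group_id)

    def test_nested_same_change_not_parallel(self):
        # identical changes on a branch and its own descendant are not
        # independent lineages: they must not join one PAR group
        from cbcmap.pair_events import PairChangeEvent

        ds = make_pair_dataset(
            "((A,B),(C,D));", {"A": "AU", "B": "GC", "C": "GC", "D": "GC"}
        )
        recon = branch_change_table(ds)
        stem = ds.tree.node("A").parent.id
        synthetic = [
            PairChangeEvent(
                branch=b,
                pair=(0, 1),
                parent_state=("G", "C"),
                child_state=("A", "U"),
                event_class="CBC",
                conserved=True,
                helix=2,
            )
            for b in (stem, "A")
        ]
        typed = type_homoplasy(synthetic, ds.tree, recon)
        assert all(e.homoplasy_label == "NHS" for e in typed)


class TestPathwayAudit:
    def test_positive_control(self):
        # C-G -> U-G on the stem, U-G -> U-A at a descendant tip
        ds = make_pair_dataset(
            "(((A,B),C),(D,E));",
            {"A": "UA", "B": "UG", "C": "UG", "D": "CG", "E": "CG"},
        )
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        typed = type_homoplasy(events, ds.tree, recon)
        hits = pathway_audit(typed, ds.tree)
        assert len(hits) == 1
        assert hits[0].start_state == ("C", "G")
        assert hits[0].intermediate_state == ("U", "G")
        assert hits[0].end_state == ("U", "A")
        assert hits[0].second_branch == "A"

    def test_different_pairs_do_not_compose(self):
        alignment = PairedAlignment(
            taxa=("A", "B", "C", "D"),
            rows=("UGGC", "CGGC", "CGGU", "CGGC"),
        )
        structure = PairTable(
            pairs=((0, 1), (2, 3)), conserved=(True, True), helix=(2, 2), n_columns=4
        )
        tree = read_tree("((A,B),(C,D));", taxa=list("ABCD"))
        ds = Dataset(alignment, structure, tree)
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        assert {e.event_class for e in events} == {"hCBC"}
        assert pathway_audit(events, ds.tree) == []

    def test_direct_double_events_leave_no_trace(self):
        # single-hit regime: every CBC is drawn as one double-sided event and
        # detected exactly, so no hCBC couples exist to compose
        ds, truth = simulate(SimConfig(seed=5, mode="no_multihit", r_cbc=0.3,
                                       r_hcbc=0.0, r_break=0.0, r_restore=0.0))
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        assert pathway_audit(events, ds.tree) == []


class TestPhenetic:
    def test_worked_two_taxon_example(self, two_species_dataset):
        counts = phenetic_compare(
            "Acrochaete_viridis", "Acrochaete_heteroclada", two_species_dataset
        )
        assert counts == {"CBC": 0, "hCBC": 1, "other": 0}

    def test_identical_sequences(self, two_species_dataset):
        counts = phenetic_compare("Ulva_outgroup1", "Ulva_outgroup2", two_species_dataset)
        assert counts == {"CBC": 0, "hCBC": 0, "other": 0}

    def test_full_cbc_difference(self):
        ds = make_pair_dataset(
            "((A,B),(C,D));", {"A": "GC", "B": "GC", "C": "AU", "D": "AU"}
        )
        assert phenetic_compare("A", "C", ds)["CBC"] == 1

    def test_unknown_taxon(self, two_species_dataset):
        with pytest.raises(KeyError):
            phenetic_compare("nope", "Ulva_outgroup1", two_species_dataset)

    def test_phenetic_vs_phylogenetic_discrepancy(self, two_species_dataset):
        recon = branch_change_table(two_species_dataset)
        events, _ = scan_pair_events(two_species_dataset, recon)
        classes = {(e.branch, e.event_class) for e in events}
        assert ("Acrochaete_viridis", "CBC") in classes
        assert ("Acrochaete_heteroclada", "hCBC") in classes
        phenetic = phenetic_compare(
            "Acrochaete_viridis", "Acrochaete_heteroclada", two_species_dataset
        )
        assert phenetic["CBC"] == 0
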
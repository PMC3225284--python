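from collections import Counter

import pytest

from cbcmap.ancestral import branch_change_table, fitch_sets
from cbcmap.pair_events import scan_pair_events
from cbcmap.simulate import (
    SimConfig,
    cbc_targets,
    default_structure,
    hcbc_targets,
    make_two_species_fixture,
    replay,
    simulate,
    staged_decompositions,
    yule_tree,
)


class TestTargets:
    def test_cbc_target_counts_sum_to_22(self):
        from cbcmap.pair_events import PAIRED_STATES

        assert sum(len(cbc_targets(s)) for s in PAIRED_STATES) == 22

    def test_hcbc_target_counts_sum_to_8(self):
        from cbcmap.pair_events import PAIRED_STATES

        assert sum(len(hcbc_targets(s)) for s in PAIRED_STATES) == 8

    def test_staged_decomposition_exists_only_for_canonical_swaps(self):
        from cbcmap.pair_events import PAIRED_STATES

        decomposable = {s for s in PAIRED_STATES if staged_decompositions(s)}
        assert decomposable == {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
        assert staged_decompositions(("G", "C")) == [(("G", "U"), ("A", "U"))]


class TestStructureTemplate:
    def test_default_geometry(self):
        table = default_structure()
        assert table.n_columns == 129
        assert table.n_pairs == 45
        assert set(table.helix) == {1, 2, 3, 4}
        # conserved set: all of helix 2 plus the apical part of helix 3
        conserved_helices = {
            h for h, f in zip(table.helix, table.conserved) if f
        }
        assert conserved_helices == {2, 3}

    def test_custom_geometry_falls_back(self):
        table = default_structure(n_columns=40, n_pairs=10)
        assert table.n_pairs == 10


class TestYule:
    def test_leaf_count_and_depth(self):
        tree = yule_tree(12, seed=4, expected_depth=2.0)
        assert len(tree.leaves()) == 12
        for leaf in tree.leaves():
            depth = sum(n.length for n in [leaf] + tree.ancestors(leaf.id) if n.length)
            assert depth == pytest.approx(2.0)

    def test_positive_branch_lengths(self):
        tree = yule_tree(12, seed=1)
        assert all(b.length > 0 for b in tree.branches())


class TestSimulate:
    def test_zero_rates_copy_root(self):
        cfg = SimConfig(
            seed=1, r_cbc=0, r_hcbc=0, r_break=0, r_restore=0, r_unpaired=0
        )
        ds, truth = simulate(cfg)
        assert truth.events == ()
        assert all(row == truth.root_sequence for row in ds.alignment.rows)

    @pytest.mark.parametrize("mode", ["direct", "staged", "no_multihit"])
    def test_replay_identity(self, mode):
        for seed in range(8):
            ds, truth = simulate(SimConfig(seed=seed, mode=mode))
            leaves = replay(truth, ds.tree, ds.structure)
            for taxon, row in zip(ds.alignment.taxa, ds.alignment.rows):
                assert leaves[taxon] == row

    @pytest.mark.parametrize("mode", ["direct", "staged", "no_multihit"])
    def test_determinism(self, mode):
        cfg = SimConfig(seed=5, mode=mode)
        a = simulate(cfg)
        b = simulate(cfg)
        assert a[0].alignment.rows == b[0].alignment.rows
        assert a[1].events == b[1].events

    def test_no_multihit_one_event_per_site(self):
        ds, truth = simulate(SimConfig(seed=3, mode="no_multihit"))
        sites = [ev.site for ev in truth.events]
        assert len(sites) == len(set(sites))

    def test_recovery_losses_explained_by_multihit_or_root(self):
        """In direct mode a missed truth event always has a cause: the pair
        was hit more than once, or the event sits on a root-child branch
        where the parsimony root state is not identifiable."""
        for seed in range(10):
            ds, truth = simulate(SimConfig(seed=seed, mode="direct"))
            recon = branch_change_table(ds)
            events, _ = scan_pair_events(ds, recon)
            detected = {(e.branch, e.pair, e.event_class) for e in events}
            per_site = Counter(ev.site for ev in truth.events)
            for tr in truth.triples():
                if tr in detected:
                    continue
                node = ds.tree.node(tr[0])
                root_child = node.parent is not None and node.parent.parent is None
                assert per_site[tr[1]] >= 2 or root_child, tr

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            SimConfig(mode="bogus")

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            SimConfig(r_cbc=-1)


class TestTwoSpeciesFixture:
    def test_phenetic_counts(self):
        from cbcmap.pair_events import phenetic_compare

        ds = make_two_species_fixture()
        counts = phenetic_compare("Acrochaete_viridis", "Acrochaete_heteroclada", ds)
        assert counts["hCBC"] == 1 and counts["CBC"] == 0

    def test_reconstructed_events(self):
        ds = make_two_species_fixture()
        recon = branch_change_table(ds)
        events, _ = scan_pair_events(ds, recon)
        by_branch = {e.branch: e for e in events}
        assert by_branch["Acrochaete_viridis"].event_class == "CBC"
        assert by_branch["Acrochaete_viridis"].parent_state == ("G", "C")
        assert by_branch["Acrochaete_viridis"].child_state == ("A", "U")
        assert by_branch["Acrochaete_heteroclada"].event_class == "hCBC"
        assert by_branch["Acrochaete_heteroclada"].child_state == ("G", "U")
        assert len(events) == 2

    def test_minimum_steps_at_focal_pair(self):
        # exhaustive-labeling oracle over both focal columns
        import itertools

        ds = make_two_species_fixture()
        tree = ds.tree
        internals = [n for n in tree.preorder() if not n.is_leaf]
        total = 0
        for col in (14, 25):
            states = {l.id: ds.alignment.row(l.id)[col] for l in tree.leaves()}
            best = None
            for labeling in itertools.product("ACGU", repeat=len(internals)):
                assign = dict(zip((n.id for n in internals), labeling))
                assign.update(states)
                cost = sum(
                    assign[n.id] != assign[n.parent.id]
                    for n in tree.preorder()
                    if n.parent is not None
                )
                best = cost if best is None else min(best, cost)
            total += best
        assert total == 3
        _, n14 = fitch_sets(tree, {l.id: ds.alignment.row(l.id)[14] for l in tree.leaves()})
        _, n25 = fitch_sets(tree, {l.id: ds.alignment.row(l.id)[25] for l in tree.leaves()})
        assert n14 + n25 == 3
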
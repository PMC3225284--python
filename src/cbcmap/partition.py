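"""Partition of taxa into CBC clades, CBC grades and the plesiomorphic grade.

Cutting the rooted tree at every branch that carries at least one CBC in the
conserved helix 2+3 region splits the leaves into maximal connected
components.  A component whose member set is exactly the leaf set of some
node's subtree is a (monophyletic) CBC clade; any other non-root component
is a CBC grade — a paraphyletic assemblage whose members nevertheless share
no conserved-region CBC.  The component containing the root is supported by
no synapomorphic conserved CBC at all: unless it is the whole tree it is
the plesiomorphic grade, united merely by ancestral pair states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import Dataset, Phylogeny
from .pair_events import PairChangeEvent, phenetic_compare


@dataclass(frozen=True)
class CBCComponent:
    component_id: int
    members: frozenset[str]
    entry_branch: str  # child-node id of the cut branch above, or "root"
    kind: str  # clade | grade | plesiomorphic_grade
    depleted: bool  # single-leaf remainder of deeper cuts
    nested_ids: tuple[int, ...]
    supporting_events: tuple[PairChangeEvent, ...]


def partition_taxa(
    tree: Phylogeny, events: Iterable[PairChangeEvent]
) -> list[CBCComponent]:
    """Cut at every conserved-CBC branch and classify the leaf components.

    Several qualifying events on one branch create a single cut; they are
    all recorded as that component's support.
    """
    support: dict[str, list[PairChangeEvent]] = {}
    for ev in events:
        if ev.event_class == "CBC" and ev.conserved:
            support.setdefault(ev.branch, []).append(ev)

    # Preorder sweep: a cut branch opens a new component below it.
    comp_of_node: dict[str, int] = {}
    entry: dict[int, str] = {}
    next_id = 0
    for node in tree.preorder():
        if node.parent is None:
            comp_of_node[node.id] = next_id
            entry[next_id] = "root"
            next_id += 1
        elif node.id in support:
            comp_of_node[node.id] = next_id
            entry[next_id] = node.id
            next_id += 1
        else:
            comp_of_node[node.id] = comp_of_node[node.parent.id]

    members: dict[int, set[str]] = {}
    for leaf in tree.leaves():
        members.setdefault(comp_of_node[leaf.id], set()).add(leaf.id)

    # Nesting: parent component of a non-root component is the component of
    # the node just above its entry branch.
    nested: dict[int, list[int]] = {cid: [] for cid in entry}
    for cid, br in entry.items():
        if br == "root":
            continue
        parent_cid = comp_of_node[tree.node(br).parent.id]
        nested[parent_cid].append(cid)

    leaf_sets = set(tree.subtree_leaf_sets().values())
    all_taxa = tree.taxa
    out: list[CBCComponent] = []
    for cid in sorted(entry):
        mem = frozenset(members.get(cid, set()))
        if not mem:
            # every leaf below this cut was claimed by deeper cuts
            continue
        is_root_comp = entry[cid] == "root"
        monophyletic = mem in leaf_sets
        if is_root_comp:
            kind = "clade" if mem == all_taxa else "plesiomorphic_grade"
        else:
            kind = "clade" if monophyletic else "grade"
        out.append(
            CBCComponent(
                component_id=cid,
                members=mem,
                entry_branch=entry[cid],
                kind=kind,
                depleted=False,  # filled in below from the entry subtree
                nested_ids=tuple(sorted(nested[cid])),
                supporting_events=tuple(support.get(entry[cid], ())),
            )
        )
    # depleted: a clade-kind component that lost members to nested cuts,
    # i.e. its member set is smaller than its entry subtree.
    leaf_sets_by_node = tree.subtree_leaf_sets()
    fixed: list[CBCComponent] = []
    for comp in out:
        if comp.entry_branch == "root":
            full = all_taxa
        else:
            full = leaf_sets_by_node[comp.entry_branch]
        depleted = comp.kind == "clade" and comp.members != full
        fixed.append(
            CBCComponent(
                component_id=comp.component_id,
                members=comp.members,
                entry_branch=comp.entry_branch,
                kind=comp.kind,
                depleted=depleted,
                nested_ids=comp.nested_ids,
                supporting_events=comp.supporting_events,
            )
        )
    return fixed


@dataclass(frozen=True)
class AuditRow:
    component_id: int
    taxon1: str
    taxon2: str
    n_cbc: int


def audit_component(component: CBCComponent, dataset: Dataset) -> list[AuditRow]:
    """Check a component against the phenetic CBC-clade definition.

    All member pairs are compared at the conserved pairs only; any nonzero
    CBC difference (possible under homoplasy, e.g. a reversal inside the
    component) is reported as a discrepancy.
    """
    rows: list[AuditRow] = []
    mem = sorted(component.members)
    for a_idx, t1 in enumerate(mem):
        for t2 in mem[a_idx + 1 :]:
            counts = phenetic_compare(t1, t2, dataset, restrict="conserved")
            if counts["CBC"] > 0:
                rows.append(
                    AuditRow(
                        component_id=component.component_id,
                        taxon1=t1,
                        taxon2=t2,
                        n_cbc=counts["CBC"],
                    )
                )
    return rows
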
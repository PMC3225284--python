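"""Classification of base-pair changes on branches: CBC, hCBC, homoplasy.

A pair state is the ordered couple of residues at a base-paired column pair,
read in 5'-3' helix orientation; exactly six ordered states count as paired
(G-C, C-G, A-U, U-A and the G-U / U-G wobbles).  Comparing the reconstructed
parent and child states of a pair on a branch yields one event:

* ``CBC``   — both sides changed, pairing retained (e.g. G-C -> A-U);
* ``hCBC``  — one side changed, pairing retained (e.g. G-C -> G-U);
* ``pair_loss`` / ``pair_gain`` — pairing lost or (re)gained;
* ``mismatch_change`` — neither state paired but the residues changed.

Homoplasy typing follows cladistic usage: a reversal (REV) returns a pair to
a state held by some strict ancestor on its root path; a parallelism (PAR)
is the same change from the same ancestral state on independent branches; a
convergence (CONV) reaches the same derived state from different ancestral
states on independent branches.  Everything else is a non-homoplasious
synapomorphy (NHS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .ancestral import Reconstruction
from .io import Dataset, Phylogeny

#: The six ordered paired states, 5' side first.
PAIRED_STATES: tuple[tuple[str, str], ...] = (
    ("G", "C"),
    ("C", "G"),
    ("A", "U"),
    ("U", "A"),
    ("G", "U"),
    ("U", "G"),
)
_PAIRED = frozenset(PAIRED_STATES)

EVENT_CLASSES = ("CBC", "hCBC", "pair_loss", "pair_gain", "mismatch_change")


def is_paired(state: tuple[str, str]) -> bool:
    return state in _PAIRED


def format_state(state: tuple[str, str]) -> str:
    return f"{state[0]}-{state[1]}"


def classify_pair_change(
    parent: tuple[str, str], child: tuple[str, str]
) -> str | None:
    """Classify a parent->child pair-state difference; None if identical."""
    for side in (*parent, *child):
        if side not in "ACGU":
            raise ValueError(f"cannot classify a pair with missing side: {parent}->{child}")
    if parent == child:
        return None
    p_paired, c_paired = is_paired(parent), is_paired(child)
    if p_paired and c_paired:
        n_changed = (parent[0] != child[0]) + (parent[1] != child[1])
        return "CBC" if n_changed == 2 else "hCBC"
    if p_paired and not c_paired:
        return "pair_loss"
    if not p_paired and c_paired:
        return "pair_gain"
    return "mismatch_change"


@dataclass(frozen=True)
class PairChangeEvent:
    """One reconstructed change of one base pair on one branch."""

    branch: str
    pair: tuple[int, int]  # 0-based column indices (i, j), i < j
    parent_state: tuple[str, str]
    child_state: tuple[str, str]
    event_class: str
    conserved: bool
    helix: int
    homoplasy_label: str = "NHS"
    group_id: str | None = None


@dataclass(frozen=True)
class SkippedPair:
    """A branch x pair cell left unclassified because one side is missing."""

    branch: str
    pair: tuple[int, int]
    reason: str


def _leaf_state(dataset: Dataset, taxon: str, column: int) -> str | None:
    c = dataset.alignment.row(taxon)[column]
    return c if c in "ACGU" else None


def scan_pair_events(
    dataset: Dataset, recon: Reconstruction
) -> tuple[list[PairChangeEvent], list[SkippedPair]]:
    """Compare parent and child pair states on every branch, once per pair.

    Two single-column changes at the two partners of a pair on one branch
    therefore yield one CBC event, not two.  For terminal branches the child
    state is the observed leaf sequence, so a pair with a gap or N in that
    leaf is skipped (and logged) rather than classified.
    """
    tree = dataset.tree
    events: list[PairChangeEvent] = []
    skipped: list[SkippedPair] = []
    for node in tree.branches():
        parent_states = recon.node_states[node.parent.id]
        for (i, j), conserved, helix in zip(
            dataset.structure.pairs, dataset.structure.conserved, dataset.structure.helix
        ):
            parent = (parent_states[i], parent_states[j])
            if node.is_leaf:
                child = (_leaf_state(dataset, node.id, i), _leaf_state(dataset, node.id, j))
            else:
                child_states = recon.node_states[node.id]
                child = (child_states[i], child_states[j])
            if any(s is None or s == "N" for s in (*parent, *child)):
                if child != parent:
                    skipped.append(
                        SkippedPair(branch=node.id, pair=(i, j), reason="missing side")
                    )
                continue
            klass = classify_pair_change(parent, child)  # type: ignore[arg-type]
            if klass is None:
                continue
            events.append(
                PairChangeEvent(
                    branch=node.id,
                    pair=(i, j),
                    parent_state=parent,  # type: ignore[arg-type]
                    child_state=child,  # type: ignore[arg-type]
                    event_class=klass,
                    conserved=conserved,
                    helix=helix,
                )
            )
    return events, skipped


# ---------------------------------------------------------------------------
# Homoplasy typing
# ---------------------------------------------------------------------------

def _independent_groups(
    tree: Phylogeny, candidates: Sequence[PairChangeEvent]
) -> list[list[PairChangeEvent]]:
    """Greedily split candidate events into pairwise-independent groups.

    Independence means neither branch is ancestral to the other on the
    rooted tree; sister relation is not required.  Candidates are taken in
    branch preorder so the result is deterministic.
    """
    ordered = sorted(candidates, key=lambda e: tree.preorder_index(e.branch))
    groups: list[list[PairChangeEvent]] = []
    for ev in ordered:
        for g in groups:
            if all(not tree.related(ev.branch, m.branch) for m in g):
                g.append(ev)
                break
        else:
            groups.append([ev])
    return [g for g in groups if len(g) >= 2]


def type_homoplasy(
    events: Iterable[PairChangeEvent], tree: Phylogeny, recon: Reconstruction
) -> list[PairChangeEvent]:
    """Label every event NHS / PAR / CONV / REV and register groups.

    Strata are (pair, event class): a parallelism of CBCs and one of hCBCs
    at the same pair are distinct groups, numbered PAR-n for the CBC class
    and hPAR-n / hREV-n for the hCBC class as in the field's notation.
    REV takes precedence for the primary label; an event that is a reversal
    and also sits in a PAR/CONV group keeps its group id.
    """
    events = list(events)
    # Reversal: the derived state equals some strict-ancestor state of the
    # same pair above the branch's parent node (full root path).
    reversal: dict[int, bool] = {}
    for idx, ev in enumerate(events):
        i, j = ev.pair
        ancestor_states = set()
        for anc in tree.ancestors(ev.branch)[1:]:  # skip the parent itself
            st = (recon.node_states[anc.id][i], recon.node_states[anc.id][j])
            ancestor_states.add(st)
        reversal[idx] = ev.child_state in ancestor_states

    # PAR / CONV grouping within (pair, class) strata.
    strata: dict[tuple[tuple[int, int], str], list[int]] = {}
    for idx, ev in enumerate(events):
        strata.setdefault((ev.pair, ev.event_class), []).append(idx)

    group_of: dict[int, str] = {}
    counters = {"PAR": 0, "hPAR": 0, "CONV": 0, "hCONV": 0}
    for (pair, klass) in sorted(strata, key=lambda k: (k[0], k[1])):
        idxs = strata[(pair, klass)]
        prefix = "h" if klass == "hCBC" else ""
        # parallelisms: identical (parent, child) change on independent branches
        by_change: dict[tuple, list[int]] = {}
        for idx in idxs:
            ev = events[idx]
            by_change.setdefault((ev.parent_state, ev.child_state), []).append(idx)
        in_par: set[int] = set()
        for change in sorted(by_change):
            members = [events[k] for k in by_change[change]]
            for group in _independent_groups(tree, members):
                counters[prefix + "PAR"] += 1
                gid = f"{prefix}PAR-{counters[prefix + 'PAR']}"
                for ev in group:
                    k = by_change[change][members.index(ev)]
                    group_of[k] = gid
                    in_par.add(k)
        # convergences among the rest: same derived state, >=2 parent states
        by_child: dict[tuple, list[int]] = {}
        for idx in idxs:
            if idx in in_par:
                continue
            by_child.setdefault(events[idx].child_state, []).append(idx)
        for child_state in sorted(by_child):
            members = [events[k] for k in by_child[child_state]]
            if len({ev.parent_state for ev in members}) < 2:
                continue
            for group in _independent_groups(tree, members):
                if len({ev.parent_state for ev in group}) < 2:
                    continue
                counters[prefix + "CONV"] += 1
                gid = f"{prefix}CONV-{counters[prefix + 'CONV']}"
                for ev in group:
                    k = by_child[child_state][members.index(ev)]
                    group_of[k] = gid

    # Reversal numbering, deterministic in (pair, preorder) order.
    rev_counters = {"REV": 0, "hREV": 0}
    rev_id: dict[int, str] = {}
    rev_order = sorted(
        (idx for idx in range(len(events)) if reversal[idx]),
        key=lambda idx: (events[idx].pair, tree.preorder_index(events[idx].branch)),
    )
    for idx in rev_order:
        prefix = "h" if events[idx].event_class == "hCBC" else ""
        rev_counters[prefix + "REV"] += 1
        rev_id[idx] = f"{prefix}REV-{rev_counters[prefix + 'REV']}"

    out: list[PairChangeEvent] = []
    for idx, ev in enumerate(events):
        gid = group_of.get(idx)
        if reversal[idx]:
            label = rev_id[idx]
            primary = "REV"
        elif gid is not None:
            primary = "CONV" if "CONV" in gid else "PAR"
            label = gid
        else:
            primary = "NHS"
            label = "NHS"
        out.append(replace(ev, homoplasy_label=primary, group_id=gid or (rev_id.get(idx))))
    return out


# ---------------------------------------------------------------------------
# 2x hCBC -> CBC pathway audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayHit:
    """An ancestor-descendant couple of hCBCs composing a full CBC."""

    pair: tuple[int, int]
    first_branch: str
    second_branch: str
    start_state: tuple[str, str]
    intermediate_state: tuple[str, str]
    end_state: tuple[str, str]


def pathway_audit(
    events: Iterable[PairChangeEvent], tree: Phylogeny
) -> list[PathwayHit]:
    """Find every completed two-step hCBC composition of a CBC.

    For each pair, every ordered couple of hCBC events where the first
    branch is a strict ancestor of the second, the first event's derived
    state is the second event's ancestral state, and the overall composition
    is a legal CBC, is reported.  An empty result on a dataset means CBCs
    there did not arise via consecutive hemi-changes.
    """
    by_pair: dict[tuple[int, int], list[PairChangeEvent]] = {}
    for ev in events:
        if ev.event_class == "hCBC":
            by_pair.setdefault(ev.pair, []).append(ev)
    hits: list[PathwayHit] = []
    for pair in sorted(by_pair):
        evs = sorted(by_pair[pair], key=lambda e: tree.preorder_index(e.branch))
        for first in evs:
            for second in evs:
                if first is second:
                    continue
                if not tree.is_strict_ancestor(first.branch, second.branch):
                    continue
                if first.child_state != second.parent_state:
                    continue
                if classify_pair_change(first.parent_state, second.child_state) == "CBC":
                    hits.append(
                        PathwayHit(
                            pair=pair,
                            first_branch=first.branch,
                            second_branch=second.branch,
                            start_state=first.parent_state,
                            intermediate_state=first.child_state,
                            end_state=second.child_state,
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# Phenetic (tree-free) comparison
# ---------------------------------------------------------------------------

def phenetic_compare(
    taxon1: str, taxon2: str, dataset: Dataset, restrict: str = "all"
) -> dict[str, int]:
    """Pairwise comparison of two extant sequences at paired columns.

    No tree and no ancestral states are involved; this is the conventional
    two-structure comparison whose blindness to the plesiomorphic state the
    phylogenetic mapping exposes.  ``restrict="conserved"`` limits the scan
    to the conserved helix 2+3 pairs.

    Returns counts ``{"CBC": ..., "hCBC": ..., "other": ...}`` where
    ``other`` covers differences involving a non-paired state; pairs with a
    missing side in either taxon are ignored.
    """
    if restrict not in ("all", "conserved"):
        raise ValueError(f"unknown restriction {restrict!r}")
    row1 = dataset.alignment.row(taxon1)
    row2 = dataset.alignment.row(taxon2)
    counts = {"CBC": 0, "hCBC": 0, "other": 0}
    for (i, j), conserved in zip(dataset.structure.pairs, dataset.structure.conserved):
        if restrict == "conserved" and not conserved:
            continue
        s1 = (row1[i], row1[j])
        s2 = (row2[i], row2[j])
        if any(c not in "ACGU" for c in (*s1, *s2)):
            continue
        if s1 == s2:
            continue
        if is_paired(s1) and is_paired(s2):
            n_changed = (s1[0] != s2[0]) + (s1[1] != s2[1])
            counts["CBC" if n_changed == 2 else "hCBC"] += 1
        else:
            counts["other"] += 1
    return counts
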
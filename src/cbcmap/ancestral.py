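"""Parsimony ancestral reconstruction with delayed-transformation resolution.

Each alignment column is treated as an unordered 4-state character over
{A, C, G, U}.  The bottom-up pass computes, per node, the set of states that
can start a most-parsimonious reconstruction of the subtree, using the
majority-vote (Hartigan) generalization of Fitch's rule: a state belongs to
the node set iff it occurs in a maximal number of child sets, and each node
contributes ``(number of children) - (maximal count)`` steps.  On binary
trees this is exactly Fitch's intersection/union rule; on multifurcations it
still attains the exact parsimony minimum, which the plain iterated
intersection does not.

The top-down pass resolves ambiguity by delayed transformation (DELTRAN):
a child keeps its parent's final state whenever that state is in the child's
first-pass set, pushing changes toward the tips; residual ties (the root
pick, and a child whose set excludes the parent state) break alphabetically
A < C < G < U so that two runs on the same input are bit-identical.

Gap and ``N`` cells are missing data: such a leaf carries the full alphabet
in the bottom-up pass and therefore never receives a change on its terminal
branch; an all-missing column is flagged and contributes no steps.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Dataset, Phylogeny

ALPHABET = ("A", "C", "G", "U")
_FULL = frozenset(ALPHABET)


@dataclass(frozen=True)
class ChangeEvent:
    """One reconstructed substitution on one branch at one column."""

    branch: str  # child-node id of the branch
    column: int  # 0-based alignment column
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("change event with identical states")


@dataclass(frozen=True)
class BranchSteps:
    branch: str
    steps_paired: int
    steps_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.steps_paired <= self.steps_total):
            raise ValueError("inconsistent step counts")


@dataclass(frozen=True)
class Reconstruction:
    """Full output of :func:`branch_change_table`.

    ``node_states[node_id][column]`` holds the DELTRAN final state for every
    node and column ('N' for all-missing columns); leaves keep their
    reconstructed state here even where the observed cell is missing.
    """

    events: tuple[ChangeEvent, ...]
    node_states: dict[str, list[str]]
    branch_steps: dict[str, BranchSteps]
    column_changes: list[int]
    all_missing_columns: tuple[int, ...]


def fitch_sets(
    tree: Phylogeny, states: dict[str, str | None]
) -> tuple[dict[str, frozenset[str]], int]:
    """Bottom-up pass for one column.

    Parameters
    ----------
    tree:
        Rooted phylogeny.
    states:
        Per-leaf state; ``None`` marks missing data (gap/N) and contributes
        the full alphabet.

    Returns
    -------
    (node_sets, minimum)
        Per-node state sets keyed by node id, and the minimal number of
        changes needed for the column on this tree.
    """
    if all(states.get(leaf.id) is None for leaf in tree.leaves()):
        raise ValueError("all-missing column has no parsimony reconstruction")
    sets: dict[str, frozenset[str]] = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            s = states.get(node.id)
            if s is None:
                sets[node.id] = _FULL
            elif s in ALPHABET:
                sets[node.id] = frozenset((s,))
            else:
                raise ValueError(f"illegal state {s!r} at leaf {node.id}")
        else:
            counts = {a: 0 for a in ALPHABET}
            for child in node.children:
                for a in sets[child.id]:
                    counts[a] += 1
            best = max(counts.values())
            sets[node.id] = frozenset(a for a in ALPHABET if counts[a] == best)
            changes += len(node.children) - best
    return sets, changes


def deltran_resolve(
    tree: Phylogeny, sets: dict[str, frozenset[str]], column: int = 0
) -> tuple[dict[str, str], list[ChangeEvent]]:
    """Top-down DELTRAN pass; emits one :class:`ChangeEvent` per change.

    The number of emitted events equals the column's parsimony minimum.
    """
    finals: dict[str, str] = {}
    events: list[ChangeEvent] = []
    for node in tree.preorder():
        if node.parent is None:
            finals[node.id] = min(sets[node.id])
            continue
        parent_state = finals[node.parent.id]
        if parent_state in sets[node.id]:
            finals[node.id] = parent_state
        else:
            finals[node.id] = min(sets[node.id])
            events.append(
                ChangeEvent(
                    branch=node.id,
                    column=column,
                    from_state=parent_state,
                    to_state=finals[node.id],
                )
            )
    return finals, events


def branch_change_table(dataset: Dataset) -> Reconstruction:
    """Reconstruct every column; collate events, step counts, change counts."""
    tree = dataset.tree
    alignment = dataset.alignment
    paired_columns = dataset.structure.paired_columns

    all_events: list[ChangeEvent] = []
    node_states: dict[str, list[str]] = {n.id: [] for n in tree.preorder()}
    column_changes: list[int] = []
    all_missing: list[int] = []
    steps_total: dict[str, int] = {b.id: 0 for b in tree.branches()}
    steps_paired: dict[str, int] = {b.id: 0 for b in tree.branches()}

    for col in range(alignment.n_columns):
        states = alignment.states(col)
        if all(v is None for v in states.values()):
            all_missing.append(col)
            column_changes.append(0)
            for node_id in node_states:
                node_states[node_id].append("N")
            continue
        sets, n_changes = fitch_sets(tree, states)
        finals, events = deltran_resolve(tree, sets, column=col)
        assert len(events) == n_changes, "DELTRAN emitted a non-minimal reconstruction"
        column_changes.append(n_changes)
        for node_id, state in finals.items():
            node_states[node_id].append(state)
        for ev in events:
            all_events.append(ev)
            steps_total[ev.branch] += 1
            if col in paired_columns:
                steps_paired[ev.branch] += 1

    branch_steps = {
        b: BranchSteps(branch=b, steps_paired=steps_paired[b], steps_total=steps_total[b])
        for b in steps_total
    }
    return Reconstruction(
        events=tuple(all_events),
        node_states=node_states,
        branch_steps=branch_steps,
        column_changes=column_changes,
        all_missing_columns=tuple(all_missing),
    )
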
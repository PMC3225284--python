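"""Paired-sequence evolution simulator with a ground-truth event log.

Sequences evolve along a rooted tree under independent Poisson processes per
site and event class.  Sites are the base pairs of a structure template plus
its unpaired columns; classes and their per-unit-branch-length rates are

* ``r_cbc``      — full compensatory change: both sides switch, the pair
  stays one of the six legal states (uniform over the 3-4 legal targets);
* ``r_hcbc``     — hemi-compensatory change: one side switches through the
  G-U wobble (uniform over the 1-2 legal targets);
* ``r_break``    — pairing lost: the pair jumps to a uniform mismatch;
* ``r_restore``  — a mismatched pair jumps to a uniform legal pair;
* ``r_unpaired`` — single-residue change at an unpaired column.

Events that are illegal for the current state (a CBC drawn on a mismatch, a
restore drawn on an intact pair) are discarded, which simply thins the
process.  The random stream is partitioned per (branch, site) from the
master seed, so enlarging the template does not perturb the histories of
earlier sites.

Modes
-----
``direct``
    CBCs happen as one two-sided event (the default).
``staged``
    A CBC is realized as two consecutive hemi-changes through its wobble
    intermediate; only the four categories with a legal two-step path exist
    (G-C<->A-U via G-U, C-G<->U-A via U-G).  The second stage lands on one
    randomly chosen child branch of the first (same branch at a leaf), so
    completed stagings lie on one root-to-tip path.
``no_multihit``
    At most one event per site over the whole tree, and the two branches
    incident to the root stay event-free.  Both restrictions keep every
    event identifiable from the tips: parallel changes in sibling subtrees
    or a change on a root branch can make the parsimony root state
    ambiguous, re-attributing the event to the wrong branch.  Under this
    mode a detector must recover the truth log exactly.

No indels are generated: every simulated column is universal, matching an
analysis that concerns substitutions only.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    Dataset,
    PairedAlignment,
    PairTable,
    Phylogeny,
    TreeNode,
    write_alignment,
    write_structure,
)
from .pair_events import PAIRED_STATES, classify_pair_change, format_state, is_paired

MODES = ("direct", "staged", "no_multihit")

_BASES = "ACGU"
_MISMATCHES: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in _BASES for b in _BASES if not is_paired((a, b))
)


def cbc_targets(state: tuple[str, str]) -> list[tuple[str, str]]:
    """Legal full-CBC targets of a paired state (3 or 4 of them)."""
    return [
        t
        for t in PAIRED_STATES
        if t[0] != state[0] and t[1] != state[1]
    ] if is_paired(state) else []


def hcbc_targets(state: tuple[str, str]) -> list[tuple[str, str]]:
    """Legal hemi-CBC targets of a paired state (1 or 2, via the wobble)."""
    if not is_paired(state):
        return []
    return [
        t
        for t in PAIRED_STATES
        if t != state and ((t[0] == state[0]) != (t[1] == state[1]))
    ]


def staged_decompositions(
    state: tuple[str, str]
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """(intermediate, final) couples realizing a CBC as two hemi-changes."""
    out = []
    for mid in hcbc_targets(state):
        for end in hcbc_targets(mid):
            if classify_pair_change(state, end) == "CBC":
                out.append((mid, end))
    return out


# ---------------------------------------------------------------------------
# Configuration and truth log
# ---------------------------------------------------------------------------

#: Root pair-state sampling frequencies. RNA helices under selection are
#: G-C rich; the split below keeps canonical pairs dominant with a modest
#: wobble share.
DEFAULT_PAIR_FREQS: dict[str, float] = {
    "G-C": 0.35,
    "C-G": 0.30,
    "A-U": 0.12,
    "U-A": 0.10,
    "G-U": 0.08,
    "U-G": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation run."""

    n_leaves: int = 12
    tree_newick: str | None = None  # overrides Yule generation when given
    expected_depth: float = 1.0  # mean root-to-tip path length after rescaling
    n_columns: int = 129
    n_pairs: int = 45
    structure: PairTable | None = None  # overrides the default template
    root_sequence: str | None = None
    pair_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PAIR_FREQS))
    r_cbc: float = 0.10
    r_hcbc: float = 0.20
    r_break: float = 0.05
    r_restore: float = 0.10
    r_unpaired: float = 0.30
    mode: str = "direct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        for name in ("r_cbc", "r_hcbc", "r_break", "r_restore", "r_unpaired"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruthEvent:
    branch: str
    site: tuple[int, int] | int  # pair (i, j) or unpaired column
    from_state: str  # "G-C" for pairs, single residue for columns
    to_state: str
    event_class: str  # CBC | hCBC | pair_loss | pair_gain | unpaired
    time: float  # position along the branch, for replay ordering


@dataclass(frozen=True)
class TruthLog:
    events: tuple[TruthEvent, ...]
    root_sequence: str

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.event_class] = out.get(ev.event_class, 0) + 1
        return out

    def triples(self, classes: tuple[str, ...] = ("CBC", "hCBC")) -> set[tuple]:
        """(branch, site, class) keys for detector precision/recall checks."""
        return {
            (ev.branch, ev.site, ev.event_class)
            for ev in self.events
            if ev.event_class in classes
        }


# ---------------------------------------------------------------------------
# Default "ulvales-like" structure template
# ---------------------------------------------------------------------------

def default_structure(n_columns: int = 129, n_pairs: int = 45) -> PairTable:
    """Four-helix template: 129 columns, 45 pairs, conserved H2 + apical H3.

    Helix sizes 9/10/20/6 with short spacers and loops mimic the canonical
    ITS2 layout in which the basal part of helix 2 (all 10 pairs here) and
    the apical part of helix 3 (18 of 20 pairs) are the conserved regions
    used for species delimitation.  Other geometries can be requested but
    must fit the column budget.
    """
    if (n_columns, n_pairs) != (129, 45):
        return _generic_structure(n_columns, n_pairs)
    helices = [  # (n_pairs, loop_len, spacer_before)
        (9, 4, 2),
        (10, 4, 3),
        (20, 5, 3),
        (6, 4, 3),
    ]
    pairs: list[tuple[int, int]] = []
    helix_ids: list[int] = []
    conserved: list[bool] = []
    col = 0
    for hid, (k, loop, spacer) in enumerate(helices, start=1):
        col += spacer
        five = list(range(col, col + k))
        col += k + loop
        three = list(range(col + k - 1, col - 1, -1))
        col += k
        for rank, (i, j) in enumerate(zip(five, three)):
            pairs.append((i, j))
            helix_ids.append(hid)
            if hid == 2:
                flag = True  # basal helix 2: fully conserved
            elif hid == 3:
                flag = rank >= 2  # apical 18 of 20 pairs of helix 3
            else:
                flag = False
            conserved.append(flag)
    assert col <= n_columns and len(pairs) == 45
    order = sorted(range(len(pairs)), key=lambda k: pairs[k])
    return PairTable(
        pairs=tuple(pairs[k] for k in order),
        conserved=tuple(conserved[k] for k in order),
        helix=tuple(helix_ids[k] for k in order),
        n_columns=n_columns,
    )


def _generic_structure(n_columns: int, n_pairs: int) -> PairTable:
    """Single-hairpin fallback for non-default geometries."""
    need = 2 * n_pairs + 3
    if n_columns < need:
        raise ValueError(f"{n_pairs} pairs need >= {need} columns, got {n_columns}")
    pairs = tuple((i, 2 * n_pairs + 2 - i) for i in range(n_pairs))
    return PairTable(
        pairs=pairs,
        conserved=tuple(True for _ in pairs),
        helix=tuple(1 for _ in pairs),
        n_columns=n_columns,
    )


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def yule_tree(n_leaves: int, seed: int, expected_depth: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree on ``n_leaves`` tips.

    Unit birth rate per lineage; after the last observed split the tips are
    extended by one more exponential waiting time, so every pendant edge has
    positive length and the tree is ultrametric.  Branch lengths are then
    rescaled so the root-to-tip path length equals ``expected_depth``,
    giving direct control over per-path event expectations.
    """
    if n_leaves < 2:
        raise ValueError("a rooted tree needs at least 2 leaves")
    rng = random.Random(seed)
    root = TreeNode(id="__root__", length=None)
    lineages: list[tuple[TreeNode, float]] = []  # (pendant node, birth time)
    for _ in range(2):
        child = TreeNode(id="", parent=root)
        root.children.append(child)
        lineages.append((child, 0.0))
    t = 0.0
    while len(lineages) < n_leaves:
        t += rng.expovariate(len(lineages))
        idx = rng.randrange(len(lineages))
        node, born = lineages.pop(idx)
        node.length = t - born
        for _ in range(2):
            child = TreeNode(id="", parent=node)
            node.children.append(child)
            lineages.append((child, t))
    t_end = t + rng.expovariate(len(lineages))
    for node, born in lineages:
        node.length = t_end - born
    # rescale and assign stable preorder ids
    scale = expected_depth / t_end
    n_leaf = n_int = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.length is not None:
            node.length *= scale
        if node.is_leaf:
            n_leaf += 1
            node.id = f"T{n_leaf}"
        elif node.parent is not None:
            n_int += 1
            node.id = f"N{n_int}"
        else:
            node.id = "N0"
        stack.extend(reversed(node.children))
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# Simulation proper
# ---------------------------------------------------------------------------

def _sample_root(
    structure: PairTable, pair_freqs: dict[str, float], rng: np.random.Generator
) -> list[str]:
    states = list(pair_freqs)
    probs = np.array([pair_freqs[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    seq = ["A"] * structure.n_columns
    for i, j in structure.pairs:
        s = states[rng.choice(len(states), p=probs)]
        a, b = s.split("-")
        seq[i], seq[j] = a, b
    for c in structure.unpaired_columns:
        seq[c] = _BASES[rng.integers(4)]
    return seq


def _site_rng(seed: int, branch_idx: int, site_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, branch_idx, site_idx])


def simulate(config: SimConfig) -> tuple[Dataset, TruthLog]:
    """Run the simulator; returns the leaf dataset and its truth log."""
    structure = config.structure or default_structure(config.n_columns, config.n_pairs)
    if config.tree_newick is not None:
        from .io import read_tree

        tree = read_tree(config.tree_newick)
    else:
        tree = yule_tree(config.n_leaves, config.seed, config.expected_depth)

    rng_root = np.random.default_rng([config.seed & 0x7FFFFFFF, 4096])
    if config.root_sequence is not None:
        if len(config.root_sequence) != structure.n_columns:
            raise ValueError("root sequence length does not match structure")
        root_seq = list(config.root_sequence)
    else:
        root_seq = _sample_root(structure, config.pair_freqs, rng_root)

    pre = tree.preorder()
    branch_index = {node.id: k for k, node in enumerate(pre)}
    # sites: the pairs, then the unpaired columns; events at different sites
    # touch disjoint columns and therefore commute, so each site evolves on
    # its own substream.
    sites: list[tuple[int, int] | int] = list(structure.pairs) + list(
        structure.unpaired_columns
    )

    log: list[TruthEvent] = []
    sequences: dict[str, list[str]] = {tree.root.id: root_seq}
    used_sites: set[tuple[int, int] | int] = set()  # no_multihit: global one-hit rule
    # staged mode: pending second stages keyed by (child node id, site index)
    pending: dict[tuple[str, int], tuple[tuple[str, str], tuple[str, str]]] = {}

    no_multihit = config.mode == "no_multihit"
    staged = config.mode == "staged"

    for node in pre:
        if node.parent is None:
            continue
        seq = list(sequences[node.parent.id])
        t = node.length or 0.0
        bidx = branch_index[node.id]
        root_adjacent = node.parent.parent is None
        if staged and config.r_cbc > 0 and t == 0:
            import warnings

            warnings.warn(f"zero-length branch {node.id}: no staged events possible")

        branch_events: list[TruthEvent] = []
        for sidx, site in enumerate(sites):
            rng = _site_rng(config.seed, bidx, sidx)
            draws: list[tuple[float, str]] = []
            inherited = pending.pop((node.id, sidx), None)
            if inherited is not None:
                draws.append((float(rng.uniform(0, t)) if t > 0 else 0.0, "stage2"))
            if not (no_multihit and root_adjacent):
                if isinstance(site, tuple):
                    classes = (
                        ("CBC", config.r_cbc),
                        ("hCBC", config.r_hcbc),
                        ("pair_loss", config.r_break),
                        ("pair_gain", config.r_restore),
                    )
                else:
                    classes = (("unpaired", config.r_unpaired),)
                for klass, rate in classes:
                    n = int(rng.poisson(rate * t)) if rate > 0 and t > 0 else 0
                    draws.extend(
                        (float(rng.uniform(0, t)), klass) for _ in range(n)
                    )
            draws.sort(key=lambda d: (d[0], d[1]))
            leaf_stage2: list[tuple[tuple[int, int], tuple[str, str], tuple[str, str]]] = []

            for time, klass in draws:
                if no_multihit and site in used_sites:
                    break
                if klass == "stage2":
                    mid, end = inherited  # type: ignore[misc]
                    i, j = site  # type: ignore[misc]
                    if (seq[i], seq[j]) != mid:
                        continue  # intermediate disturbed; staging abandoned
                    seq[i], seq[j] = end
                    branch_events.append(
                        TruthEvent(
                            node.id, site, format_state(mid), format_state(end), "hCBC", time
                        )
                    )
                    continue
                if isinstance(site, tuple):
                    i, j = site
                    state = (seq[i], seq[j])
                    applied = _apply_pair_event(state, klass, rng, staged)
                    if applied is None:
                        continue
                    if staged and klass == "CBC":
                        mid, end = applied  # type: ignore[misc]
                        seq[i], seq[j] = mid
                        branch_events.append(
                            TruthEvent(
                                node.id, site, format_state(state), format_state(mid), "hCBC", time
                            )
                        )
                        if node.is_leaf:
                            # second stage at the branch end, strictly after
                            # every uniform(0, t) draw, so the log replays
                            # in time order
                            leaf_stage2.append((site, mid, end))
                        else:
                            child = node.children[int(rng.integers(len(node.children)))]
                            pending[(child.id, sidx)] = (mid, end)
                    else:
                        new_state = applied  # type: ignore[assignment]
                        seq[i], seq[j] = new_state
                        branch_events.append(
                            TruthEvent(
                                node.id,
                                site,
                                format_state(state),
                                format_state(new_state),
                                klass,
                                time,
                            )
                        )
                    used_sites.add(site)
                else:
                    current = seq[site]
                    choices = [b for b in _BASES if b != current]
                    new = choices[int(rng.integers(3))]
                    seq[site] = new
                    branch_events.append(
                        TruthEvent(node.id, site, current, new, "unpaired", time)
                    )
                    used_sites.add(site)
            for s2site, mid, end in leaf_stage2:
                i, j = s2site
                if (seq[i], seq[j]) != mid:
                    continue
                seq[i], seq[j] = end
                branch_events.append(
                    TruthEvent(node.id, s2site, format_state(mid), format_state(end), "hCBC", t)
                )
        branch_events.sort(key=lambda e: e.time)
        log.extend(branch_events)
        sequences[node.id] = seq

    leaves = tree.leaves()
    alignment = PairedAlignment(
        taxa=tuple(l.id for l in leaves),
        rows=tuple("".join(sequences[l.id]) for l in leaves),
    )
    dataset = Dataset(alignment=alignment, structure=structure, tree=tree)
    return dataset, TruthLog(events=tuple(log), root_sequence="".join(root_seq))


def _apply_pair_event(
    state: tuple[str, str], klass: str, rng: np.random.Generator, staged: bool
):
    """Resolve an event draw into a new state (or a staged couple); None if
    the class is illegal for the current state."""
    if klass == "CBC":
        if staged:
            decomps = staged_decompositions(state)
            if not decomps:
                return None
            return decomps[int(rng.integers(len(decomps)))]
        targets = cbc_targets(state)
        if not targets:
            return None
        return targets[int(rng.integers(len(targets)))]
    if klass == "hCBC":
        targets = hcbc_targets(state)
        if not targets:
            return None
        return targets[int(rng.integers(len(targets)))]
    if klass == "pair_loss":
        if not is_paired(state):
            return None
        return _MISMATCHES[int(rng.integers(len(_MISMATCHES)))]
    if klass == "pair_gain":
        if is_paired(state):
            return None
        choices = [s for s in PAIRED_STATES if s != state]
        return choices[int(rng.integers(len(choices)))]
    raise ValueError(f"unknown event class {klass!r}")


def replay(truth: TruthLog, tree: Phylogeny, structure: PairTable) -> dict[str, str]:
    """Re-apply the truth log from the root sequence; returns leaf rows.

    Used to verify the log invariant: replay must reproduce every simulated
    leaf sequence exactly.
    """
    by_branch: dict[str, list[TruthEvent]] = {}
    for ev in truth.events:
        by_branch.setdefault(ev.branch, []).append(ev)
    for evs in by_branch.values():
        evs.sort(key=lambda e: e.time)
    seqs: dict[str, list[str]] = {tree.root.id: list(truth.root_sequence)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        seq = list(seqs[node.parent.id])
        for ev in by_branch.get(node.id, []):
            if isinstance(ev.site, tuple):
                i, j = ev.site
                assert (seq[i], seq[j]) == tuple(ev.from_state.split("-")), (
                    f"replay mismatch at {ev}"
                )
                seq[i], seq[j] = ev.to_state.split("-")
            else:
                assert seq[ev.site] == ev.from_state
                seq[ev.site] = ev.to_state
        seqs[node.id] = seq
    return {l.id: "".join(seqs[l.id]) for l in tree.leaves()}


# ---------------------------------------------------------------------------
# The worked two-species fixture
# ---------------------------------------------------------------------------

def make_two_species_fixture() -> Dataset:
    """Deterministic six-taxon dataset for the phenetic-vs-phylogenetic demo.

    Two focal congeners carry A-U and G-U at one conserved helix-2 pair
    whose ancestral state G-C is held by their respective sister taxa and
    the outgroup, so parsimony reconstructs one full CBC (G-C -> A-U) and
    one hemi-CBC (G-C -> G-U) on the two focal terminal branches, while a
    tree-free comparison of the two sees only a single hCBC.  Each focal
    taxon must sit next to a G-C sister: were the two focal taxa strict
    sisters, their shared 3' U would pull the reconstructed ancestor to G-U.
    """
    #           0         1         2
    #           0123456789012345678901234567
    template = "..(((....)))..((((....)))).."
    base =     "GACGGAUCACCGUAGCAGUUCACUGCAG"
    taxa = [
        "Acrochaete_viridis",
        "Acrochaete_sp1",
        "Acrochaete_heteroclada",
        "Acrochaete_sp2",
        "Ulva_outgroup1",
        "Ulva_outgroup2",
    ]
    focal_5p, focal_3p = 14, 25  # first pair of the second (conserved) helix
    rows = {}
    for t in taxa:
        rows[t] = list(base)
    rows["Acrochaete_viridis"][focal_5p] = "A"
    rows["Acrochaete_viridis"][focal_3p] = "U"
    rows["Acrochaete_heteroclada"][focal_3p] = "U"  # 5' side stays G -> G-U

    from .io import read_tree

    alignment = PairedAlignment(
        taxa=tuple(taxa), rows=tuple("".join(rows[t]) for t in taxa)
    )
    pairs = []
    stack: list[int] = []
    for idx, ch in enumerate(template):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            pairs.append((stack.pop(), idx))
    pairs.sort()
    conserved = tuple(i >= 14 for i, _ in pairs)  # second helix only
    helix = tuple(1 if i < 14 else 2 for i, _ in pairs)
    structure = PairTable(
        pairs=tuple(pairs), conserved=conserved, helix=helix, n_columns=len(template)
    )
    tree = read_tree(
        "(((Acrochaete_viridis,Acrochaete_sp1),(Acrochaete_heteroclada,Acrochaete_sp2)),"
        "(Ulva_outgroup1,Ulva_outgroup2));",
        taxa=taxa,
    )
    return Dataset(alignment=alignment, structure=structure, tree=tree)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_simulation(
    dataset: Dataset, truth: TruthLog, config: SimConfig, out_dir: str | Path
) -> None:
    """Write sim.fasta, sim.pairs, sim.nwk, truth.tsv and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_alignment(dataset.alignment, out / "sim.fasta")
    write_structure(dataset.structure, out / "sim.pairs")
    (out / "sim.nwk").write_text(dataset.tree.to_newick() + "\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("branch\tsite\tfrom\tto\tclass\n")
        for ev in truth.events:
            site = (
                f"{ev.site[0] + 1}/{ev.site[1] + 1}"
                if isinstance(ev.site, tuple)
                else str(ev.site + 1)
            )
            fh.write(f"{ev.branch}\t{site}\t{ev.from_state}\t{ev.to_state}\t{ev.event_class}\n")
    with open(out / "config.txt", "w") as fh:
        for key in (
            "n_leaves", "expected_depth", "n_columns", "n_pairs",
            "r_cbc", "r_hcbc", "r_break", "r_restore", "r_unpaired", "mode", "seed",
        ):
            fh.write(f"{key}\t{getattr(config, key)}\n")
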
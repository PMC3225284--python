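"""Input parsing and validation for the three pipeline inputs.

A run binds three files into one :class:`Dataset`:

* an aligned FASTA of ITS2-like RNA sequences (``PairedAlignment``),
* a secondary-structure annotation of the alignment columns — Vienna
  dot-bracket or an explicit whitespace pair table (``PairTable``),
* a rooted Newick phylogeny over the same taxa (``Phylogeny``).

Column indices are 0-based everywhere in memory; every file written by the
package uses 1-based columns, matching the conventional ITS2 position
numbering.  ``T`` is silently read as ``U``; gap ``-`` and ambiguity ``N``
are treated as missing data downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGUN-")
#: IUPAC one-letter ambiguity codes accepted under the lenient policy.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHV")

# Matching bracket tiers accepted in dot-bracket strings.  Several tiers
# allow pseudoknotted annotations, although ITS2 itself is knot-free.
_BRACKET_PAIRS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_UNPAIRED_CHARS = frozenset(".-,_:")


class RnaIOError(ValueError):
    """Base class for input validation failures."""


class AlignmentError(RnaIOError):
    pass


class StructureError(RnaIOError):
    pass


class TreeError(RnaIOError):
    pass


# ---------------------------------------------------------------------------
# PairedAlignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedAlignment:
    """A gap-containing RNA multiple alignment with unique taxon labels."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise AlignmentError("alignment has no sequences")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise AlignmentError(f"duplicate taxon labels: {sorted(dupes)}")
        if any(not t for t in self.taxa):
            raise AlignmentError("empty taxon label")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"rows have unequal lengths {sorted(lengths)}; input is not an alignment"
            )
        bad = set("".join(self.rows)) - RNA_ALPHABET
        if bad:
            raise AlignmentError(f"illegal characters after normalization: {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def column(self, index: int) -> str:
        return "".join(r[index] for r in self.rows)

    def states(self, index: int) -> dict[str, str | None]:
        """Per-taxon state at a column; gap/N map to ``None`` (missing)."""
        return {
            t: (c if c in "ACGU" else None)
            for t, c in zip(self.taxa, self.column(index))
        }


def normalize_sequence(seq: str, alphabet_policy: str = "strict") -> str:
    """Uppercase, map T->U, and apply the ambiguity-code policy."""
    s = seq.upper().replace("T", "U")
    if alphabet_policy == "lenient":
        s = "".join("N" if c in IUPAC_AMBIGUITY else c for c in s)
    out_of_alphabet = set(s) - RNA_ALPHABET
    if out_of_alphabet:
        raise AlignmentError(
            f"illegal characters {sorted(out_of_alphabet)} under policy {alphabet_policy!r}"
        )
    return s


def read_alignment(path: str | Path, alphabet_policy: str = "strict") -> PairedAlignment:
    """Read an aligned FASTA file.

    Parameters
    ----------
    path:
        FASTA file with equal-length records.
    alphabet_policy:
        ``"strict"`` rejects IUPAC ambiguity codes; ``"lenient"`` maps them
        to ``N``.
    """
    if alphabet_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = tuple(r.id for r in records)
    rows = tuple(normalize_sequence(str(r.seq), alphabet_policy) for r in records)
    return PairedAlignment(taxa=taxa, rows=rows)


def write_alignment(alignment: PairedAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(alignment.taxa, alignment.rows):
            fh.write(f">{taxon}\n{row}\n")


# ---------------------------------------------------------------------------
# PairTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTable:
    """Base-paired column pairs, with conserved-region and helix annotation.

    ``pairs`` holds ``(i, j)`` 0-based column indices with ``i < j``;
    ``conserved`` flags membership in the conserved helix 2+3 regions used by
    the CBC-clade species concept; ``helix`` gives a helix id per pair
    (1-4 for the canonical ITS2 helices, 0 for unassigned).
    """

    pairs: tuple[tuple[int, int], ...]
    conserved: tuple[bool, ...]
    helix: tuple[int, ...]
    n_columns: int

    def __post_init__(self) -> None:
        if not (len(self.pairs) == len(self.conserved) == len(self.helix)):
            raise StructureError("pair annotation lengths differ")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.n_columns):
                raise StructureError(f"pair ({i}, {j}) out of range or unordered")
            if i in seen or j in seen:
                raise StructureError(f"column in more than one pair: ({i}, {j})")
            seen.update((i, j))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def paired_columns(self) -> frozenset[int]:
        return frozenset(itertools.chain.from_iterable(self.pairs))

    @property
    def unpaired_columns(self) -> tuple[int, ...]:
        paired = self.paired_columns
        return tuple(c for c in range(self.n_columns) if c not in paired)

    def conserved_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(p for p, f in zip(self.pairs, self.conserved) if f)

    def partner(self, column: int) -> int | None:
        for i, j in self.pairs:
            if column == i:
                return j
            if column == j:
                return i
        return None


def _parse_dot_bracket(text: str, n_columns: int) -> list[tuple[int, int]]:
    if len(text) != n_columns:
        raise StructureError(
            f"dot-bracket length {len(text)} != alignment columns {n_columns}"
        )
    stacks: dict[str, list[int]] = {o: [] for o in _BRACKET_PAIRS}
    closers = {v: k for k, v in _BRACKET_PAIRS.items()}
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(text):
        if ch in _BRACKET_PAIRS:
            stacks[ch].append(idx)
        elif ch in closers:
            opener = closers[ch]
            if not stacks[opener]:
                raise StructureError(f"unbalanced bracket {ch!r} at column {idx + 1}")
            pairs.append((stacks[opener].pop(), idx))
        elif ch not in _UNPAIRED_CHARS:
            raise StructureError(f"illegal structure character {ch!r} at column {idx + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced bracket {opener!r} opened at column {stack[-1] + 1}"
            )
    return sorted(pairs)


def read_conserved_regions(path: str | Path) -> list[tuple[int, int]]:
    """Read 1-based inclusive ``start end`` column ranges, one per line."""
    ranges: list[tuple[int, int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise StructureError(f"bad region line {line!r}; expected 'start end'")
        start, end = int(parts[0]), int(parts[1])
        if start < 1 or end < start:
            raise StructureError(f"bad region range {start}..{end}")
        ranges.append((start - 1, end - 1))
    return ranges


def read_structure(
    path: str | Path,
    n_columns: int,
    conserved_regions: Iterable[tuple[int, int]] | None = None,
) -> PairTable:
    """Read a structure annotation: dot-bracket or 3-column pair table.

    The format is sniffed: a single non-empty line made of bracket/dot
    characters is dot-bracket; otherwise each non-comment line is
    ``i j conserved`` with 1-based columns and a 0/1 conserved flag.
    ``conserved_regions`` (0-based inclusive ranges, e.g. from
    :func:`read_conserved_regions`) marks pairs whose both columns fall in a
    range as conserved; for dot-bracket input this is the only way to flag
    conserved pairs.
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise StructureError(f"empty structure file {path}")
    stripped = lines[0].strip()
    if len(lines) == 1 and set(stripped) <= (set(_BRACKET_PAIRS) | set(_BRACKET_PAIRS.values()) | _UNPAIRED_CHARS):
        pairs = _parse_dot_bracket(stripped, n_columns)
        conserved = [False] * len(pairs)
    else:
        pairs = []
        conserved = []
        for ln in lines:
            parts = ln.split()
            if len(parts) < 2:
                raise StructureError(f"bad pair-table line {ln!r}")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            if j <= i:
                raise StructureError(f"pair table requires i < j, got {i + 1} {j + 1}")
            pairs.append((i, j))
            conserved.append(bool(int(parts[2])) if len(parts) > 2 else False)
        order = sorted(range(len(pairs)), key=lambda k: pairs[k])
        pairs = [pairs[k] for k in order]
        conserved = [conserved[k] for k in order]
    if conserved_regions is not None:
        ranges = list(conserved_regions)

        def in_regions(col: int) -> bool:
            return any(a <= col <= b for a, b in ranges)

        conserved = [in_regions(i) and in_regions(j) for i, j in pairs]
    return PairTable(
        pairs=tuple(pairs),
        conserved=tuple(conserved),
        helix=tuple(_infer_helices(pairs)),
        n_columns=n_columns,
    )


def _infer_helices(pairs: Sequence[tuple[int, int]]) -> list[int]:
    """Assign helix ids 1..k to maximal stacks of (near-)contiguous pairs.

    Consecutive pairs belong to the same helix when the 5' sides advance and
    the 3' sides retreat by small steps (bulges up to 2 nt are absorbed).
    """
    if not pairs:
        return []
    ids = [1]
    for prev, cur in zip(pairs, pairs[1:]):
        same = (0 < cur[0] - prev[0] <= 3) and (0 < prev[1] - cur[1] <= 3)
        ids.append(ids[-1] if same else ids[-1] + 1)
    return ids


def write_structure(table: PairTable, path: str | Path) -> None:
    """Write as a 1-based pair table (round-trips through read_structure)."""
    with open(path, "w") as fh:
        fh.write("# i\tj\tconserved\n")
        for (i, j), flag in zip(table.pairs, table.conserved):
            fh.write(f"{i + 1}\t{j + 1}\t{int(flag)}\n")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TreeNode:
    id: str
    label: str | None = None
    length: float | None = None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id})"


class Phylogeny:
    """A rooted tree whose branches are addressed by their child node id.

    Leaf ids are taxon labels; internal nodes keep their Newick label when
    present and unique, otherwise receive a stable preorder id ``N<k>``.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        self._preorder: list[TreeNode] = []
        self._reindex()

    def _reindex(self) -> None:
        self._index.clear()
        self._preorder = list(self._walk_preorder(self.root))
        for node in self._preorder:
            if node.id in self._index:
                raise TreeError(f"duplicate node id {node.id!r}")
            self._index[node.id] = node

    @staticmethod
    def _walk_preorder(node: TreeNode) -> Iterator[TreeNode]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    # -- traversal -----------------------------------------------------
    def preorder(self) -> list[TreeNode]:
        return list(self._preorder)

    def postorder(self) -> list[TreeNode]:
        return list(reversed(self._preorder))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self._preorder if n.is_leaf]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes; each identifies the branch to its parent."""
        return [n for n in self._preorder if n.parent is not None]

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise TreeError(f"no node {node_id!r} in tree") from None

    def preorder_index(self, node_id: str) -> int:
        return self._preorder.index(self._index[node_id])

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.id for n in self.leaves())

    # -- relations -----------------------------------------------------
    def is_strict_ancestor(self, a: str, b: str) -> bool:
        """True iff node ``a`` lies strictly above node ``b``."""
        node = self._index[b].parent
        target = self._index[a]
        while node is not None:
            if node is target:
                return True
            node = node.parent
        return False

    def related(self, a: str, b: str) -> bool:
        """True iff one branch is ancestral to the other (or identical)."""
        return a == b or self.is_strict_ancestor(a, b) or self.is_strict_ancestor(b, a)

    def ancestors(self, node_id: str) -> list[TreeNode]:
        """Strict ancestors of a node, nearest first, ending at the root."""
        out = []
        node = self._index[node_id].parent
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def subtree_leaf_sets(self) -> dict[str, frozenset[str]]:
        sets: dict[str, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node.id] = frozenset((node.id,))
            else:
                sets[node.id] = frozenset().union(*(sets[c.id] for c in node.children))
        return sets

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            length = "" if node.length is None else f":{node.length:g}"
            if node.is_leaf:
                return f"{node.id}{length}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.label or ""
            return f"({inner}){label}{length}"

        return fmt(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    used: set[str] = set()
    counter = itertools.count(1)

    def convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.is_leaf():
            node_id = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            if not node_id:
                raise TreeError("unlabeled leaf in Newick input")
        else:
            label = dnode.label
            node_id = label if label and label not in used else f"N{next(counter)}"
        if node_id in used:
            raise TreeError(f"duplicate label {node_id!r} in tree")
        used.add(node_id)
        node = TreeNode(id=node_id, label=dnode.label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            cnode = convert(child)
            cnode.parent = node
            node.children.append(cnode)
        return node

    root = convert(tree.seed_node)
    root.length = None
    return Phylogeny(root)


def read_tree(
    path_or_newick: str | Path,
    taxa: Iterable[str] | None = None,
    outgroup: Sequence[str] | None = None,
) -> Phylogeny:
    """Read a rooted Newick tree and bind it to an alignment's taxon set.

    A basal trifurcation is taken as an unrooted tree: ``outgroup`` (one or
    more taxon labels) is then required and the tree is rerooted on the
    branch subtending the outgroup.  Branch lengths are kept but ignored by
    all parsimony machinery.
    """
    text = None
    p = Path(str(path_or_newick))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_newick)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"unparseable Newick: {exc}") from exc

    if len(dtree.seed_node.child_nodes()) > 2:
        if not outgroup:
            raise TreeError(
                "tree root is a multifurcation (unrooted input); an outgroup is required"
            )
        labels = set(outgroup)
        leaves = [l for l in dtree.leaf_node_iter() if l.taxon and l.taxon.label in labels]
        if len(leaves) != len(labels):
            raise TreeError(f"outgroup taxa not all present: {sorted(labels)}")
        if len(leaves) == 1:
            edge = leaves[0].edge
        else:
            mrca = dtree.mrca(taxa=[l.taxon for l in leaves])
            edge = mrca.edge
        if edge.length is not None:
            dtree.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2)
        else:
            dtree.reroot_at_edge(edge)

    phylo = _from_dendropy(dtree)
    if taxa is not None:
        expected = frozenset(taxa)
        got = phylo.taxa
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise TreeError(
                f"tree/alignment taxon mismatch; missing from tree: {missing}; "
                f"not in alignment: {extra}"
            )
    return phylo


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dataset:
    """The bound triple (alignment, structure, tree), cross-validated."""

    alignment: PairedAlignment
    structure: PairTable
    tree: Phylogeny

    def __post_init__(self) -> None:
        if self.structure.n_columns != self.alignment.n_columns:
            raise StructureError(
                f"structure spans {self.structure.n_columns} columns but the "
                f"alignment has {self.alignment.n_columns}"
            )
        if self.tree.taxa != frozenset(self.alignment.taxa):
            raise TreeError("tree leaves do not match alignment taxa")


def load_dataset(
    alignment_path: str | Path,
    structure_path: str | Path,
    tree_path: str | Path,
    alphabet_policy: str = "strict",
    conserved_regions_path: str | Path | None = None,
    outgroup: Sequence[str] | None = None,
) -> Dataset:
    """Read and bind the three inputs into one validated :class:`Dataset`."""
    alignment = read_alignment(alignment_path, alphabet_policy)
    regions = (
        read_conserved_regions(conserved_regions_path)
        if conserved_regions_path is not None
        else None
    )
    structure = read_structure(structure_path, alignment.n_columns, regions)
    tree = read_tree(tree_path, taxa=alignment.taxa, outgroup=outgroup)
    return Dataset(alignment=alignment, structure=structure, tree=tree)
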
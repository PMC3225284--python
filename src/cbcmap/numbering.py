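"""Universal position numbering, consensus sequence and variability map.

A column is "universal" when no taxon has a gap there; universal columns are
numbered consecutively 1..U in alignment order and serve as the backbone of
the position naming scheme.  A non-universal column is labeled by subscript
against the nearest preceding universal position (``7_1``, ``7_2`` after
position 7); columns before the first universal position count backwards
toward it (``1_-2``, ``1_-1`` immediately 5' of position 1).

The variability map bins columns by their parsimony change count over the
whole tree: (1) invariant, (2) a single unique change, (3) 2-5 changes,
(4) >=6 changes.  Two presence-based categories override those: (5)
expansion segments — runs of non-universal columns — and (6) taxon-specific
insertions, non-universal columns present in under half of the taxa.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import Dataset, PairedAlignment


class NumberingError(ValueError):
    pass


@dataclass(frozen=True)
class PositionLabel:
    kind: str  # universal | inserted | leading
    universal_index: int | None  # 1..U for universal columns
    anchor: int | None  # preceding universal index (inserted) or 1 (leading)
    offset: int | None  # 1,2,... inserted; -1,-2,... leading

    @property
    def text(self) -> str:
        if self.kind == "universal":
            return str(self.universal_index)
        return f"{self.anchor}_{self.offset}"

    @property
    def sort_key(self) -> tuple[int, int]:
        if self.kind == "universal":
            return (self.universal_index, 0)
        return (self.anchor, self.offset)


def assign_universal_numbers(alignment: PairedAlignment) -> list[PositionLabel]:
    """Label every column; raises :class:`NumberingError` with no backbone.

    The first universal column is position 1.  (Published ITS2 numbering may
    anchor position 1 elsewhere for dataset-specific reasons; the constant
    offset between conventions is the caller's to apply.)
    """
    universal = [
        col for col in range(alignment.n_columns)
        if all(row[col] != "-" for row in alignment.rows)
    ]
    if not universal:
        raise NumberingError("no universal (gap-free) column; numbering has no backbone")
    labels: list[PositionLabel | None] = [None] * alignment.n_columns
    for rank, col in enumerate(universal, start=1):
        labels[col] = PositionLabel(kind="universal", universal_index=rank, anchor=None, offset=None)

    first = universal[0]
    # leading columns: offsets -k..-1 so that the column adjacent to
    # position 1 is 1_-1 and sorting by (anchor, offset) keeps file order
    for back, col in enumerate(range(first - 1, -1, -1), start=1):
        labels[col] = PositionLabel(kind="leading", universal_index=None, anchor=1, offset=-back)

    anchor_rank = 1
    offset = 0
    for col in range(first + 1, alignment.n_columns):
        if labels[col] is not None and labels[col].kind == "universal":
            anchor_rank = labels[col].universal_index
            offset = 0
        else:
            offset += 1
            labels[col] = PositionLabel(
                kind="inserted", universal_index=None, anchor=anchor_rank, offset=offset
            )
    return labels  # type: ignore[return-value]


def consensus_sequence(alignment: PairedAlignment, threshold: float = 0.70) -> str:
    """Majority-rule consensus over {A,C,G,U,N}.

    The denominator excludes gaps and N, so a column present in only part of
    the taxa still reports the majority residue of the taxa that have it; a
    column with no residue at or above the threshold yields ``N``.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    out = []
    for col in range(alignment.n_columns):
        counts = Counter(c for c in alignment.column(col) if c in "ACGU")
        total = sum(counts.values())
        if total == 0:
            out.append("N")
            continue
        residue, n = max(sorted(counts.items()), key=lambda kv: kv[1])
        out.append(residue if n / total >= threshold else "N")
    return "".join(out)


@dataclass(frozen=True)
class VariabilityRecord:
    column: int  # 0-based
    label: str
    category: int  # 1..6
    n_changes: int
    consensus_char: str


def variability_map(
    dataset: Dataset,
    change_counts: Sequence[int],
    consensus: str | None = None,
    expansion_regions: Iterable[tuple[int, int]] | None = None,
    min_run: int = 3,
    presence_cutoff: float = 0.5,
) -> list[VariabilityRecord]:
    """Assign the six variability categories to every column.

    ``expansion_regions`` (0-based inclusive ranges) overrides the default
    run-length rule for category 5.  Category 6 (insertions present in under
    ``presence_cutoff`` of taxa) takes precedence over category 5.
    """
    alignment = dataset.alignment
    if len(change_counts) != alignment.n_columns:
        raise ValueError(
            f"{len(change_counts)} change counts for {alignment.n_columns} columns"
        )
    if consensus is None:
        consensus = consensus_sequence(alignment)
    labels = assign_universal_numbers(alignment)

    def count_category(n: int) -> int:
        if n == 0:
            return 1
        if n == 1:
            return 2
        if n <= 5:
            return 3
        return 4

    categories = [count_category(n) for n in change_counts]

    non_universal = [lab.kind != "universal" for lab in labels]
    if expansion_regions is not None:
        in_expansion = set()
        for a, b in expansion_regions:
            in_expansion.update(range(a, b + 1))
        for col in range(alignment.n_columns):
            if non_universal[col] and col in in_expansion:
                categories[col] = 5
    else:
        run: list[int] = []
        for col in range(alignment.n_columns + 1):
            if col < alignment.n_columns and non_universal[col]:
                run.append(col)
            else:
                if len(run) >= min_run:
                    for c in run:
                        categories[c] = 5
                run = []

    for col in range(alignment.n_columns):
        if not non_universal[col]:
            continue
        present = sum(1 for row in alignment.rows if row[col] != "-")
        if present / alignment.n_taxa < presence_cutoff:
            categories[col] = 6

    return [
        VariabilityRecord(
            column=col,
            label=labels[col].text,
            category=categories[col],
            n_changes=change_counts[col],
            consensus_char=consensus[col],
        )
        for col in range(alignment.n_columns)
    ]
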
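"""Branch- and molecule-level summary statistics of pair evolution.

Saturation ratios per branch follow the field's definitions: a full CBC
consumes two single-position steps, a hemi-CBC one, so

    CBC_R  = 2 * n_CBC  / steps_paired
    hCBC_R =     n_hCBC / steps_paired

with steps counted at base-paired columns only and branches without paired
steps excluded (ratios undefined).  The category table enumerates all
directed couples of the six paired states: 22 are CBC-class, 8 are
hCBC-class, and with the 6 identity couples that exhausts all 36.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .ancestral import BranchSteps
from .io import Dataset
from .pair_events import (
    PAIRED_STATES,
    PairChangeEvent,
    classify_pair_change,
    format_state,
    is_paired,
)


@dataclass(frozen=True)
class BranchRatioRecord:
    branch: str
    steps_paired: int
    n_cbc: int
    n_hcbc: int
    cbc_r: float  # NaN when steps_paired == 0
    hcbc_r: float


def branch_ratios(
    events: Iterable[PairChangeEvent] | None,
    steps: Mapping[str, BranchSteps],
    counts: Mapping[str, tuple[int, int]] | None = None,
) -> list[BranchRatioRecord]:
    """Per-branch saturation ratios.

    ``counts`` may supply ``{branch: (n_cbc, n_hcbc)}`` directly (e.g. for
    branch data taken from a published table); otherwise the counts are
    tallied from ``events``.
    """
    if counts is None:
        tally: dict[str, list[int]] = {}
        for ev in events or ():
            cell = tally.setdefault(ev.branch, [0, 0])
            if ev.event_class == "CBC":
                cell[0] += 1
            elif ev.event_class == "hCBC":
                cell[1] += 1
        counts = {b: (c[0], c[1]) for b, c in tally.items()}
    out: list[BranchRatioRecord] = []
    for branch, bs in steps.items():
        n_cbc, n_hcbc = counts.get(branch, (0, 0))
        if 2 * n_cbc + n_hcbc > bs.steps_paired:
            raise ValueError(
                f"branch {branch!r}: 2*{n_cbc} CBC + {n_hcbc} hCBC exceed "
                f"{bs.steps_paired} paired steps — classifier/step mismatch"
            )
        if bs.steps_paired == 0:
            cbc_r = hcbc_r = math.nan
        else:
            cbc_r = 2 * n_cbc / bs.steps_paired
            hcbc_r = n_hcbc / bs.steps_paired
        out.append(
            BranchRatioRecord(
                branch=branch,
                steps_paired=bs.steps_paired,
                n_cbc=n_cbc,
                n_hcbc=n_hcbc,
                cbc_r=cbc_r,
                hcbc_r=hcbc_r,
            )
        )
    return out


def single_branch_ratio(n_cbc: int, n_hcbc: int, steps_paired: int) -> tuple[float, float]:
    """(CBC_R, hCBC_R) as percentages for one branch's printed counts."""
    [rec] = branch_ratios(
        None,
        {"b": BranchSteps(branch="b", steps_paired=steps_paired, steps_total=steps_paired)},
        counts={"b": (n_cbc, n_hcbc)},
    )
    return 100.0 * rec.cbc_r, 100.0 * rec.hcbc_r


def enumerate_categories() -> pd.DataFrame:
    """Legality table over all ordered couples of the six paired states.

    Returns one row per ordered couple (from, to) with its class: ``CBC``,
    ``hCBC`` or ``identity``.  Exactly 22 couples are CBC and 8 are hCBC.
    """
    rows = []
    for a, b in itertools.product(PAIRED_STATES, repeat=2):
        klass = "identity" if a == b else classify_pair_change(a, b)
        rows.append(
            {"from": format_state(a), "to": format_state(b), "class": klass}
        )
    return pd.DataFrame(rows)


def category_counts() -> dict[str, int]:
    table = enumerate_categories()
    return table["class"].value_counts().to_dict()


@dataclass(frozen=True)
class TransitionMatrix:
    """Directed transition counts plus extant pair-state frequencies."""

    counts: pd.DataFrame  # index=from, columns=to, paired states + 'mismatch'
    classes: pd.DataFrame  # same shape, class tag per cell
    extant_frequencies: pd.Series  # states + 'mismatch' -> fraction
    extant_counts: pd.Series


_STATE_LABELS = [format_state(s) for s in PAIRED_STATES]


def transition_tally(
    events: Iterable[PairChangeEvent], dataset: Dataset
) -> TransitionMatrix:
    """Tally reconstructed pair-state transitions and extant frequencies.

    Transition counts cover every pair event, with non-paired states pooled
    into a ``mismatch`` margin.  Extant frequencies are the distribution of
    the six paired states (plus mismatch) over taxa x universal pairs —
    pairs whose both columns are gap-free in every taxon — matching the
    convention behind published pair-state percentages.
    """
    labels = _STATE_LABELS + ["mismatch"]
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for ev in events:
        src = format_state(ev.parent_state) if is_paired(ev.parent_state) else "mismatch"
        dst = format_state(ev.child_state) if is_paired(ev.child_state) else "mismatch"
        counts.loc[src, dst] += 1

    classes = pd.DataFrame("other", index=labels, columns=labels)
    for a in PAIRED_STATES:
        for b in PAIRED_STATES:
            if a != b:
                classes.loc[format_state(a), format_state(b)] = classify_pair_change(a, b)
            else:
                classes.loc[format_state(a), format_state(b)] = "identity"

    alignment = dataset.alignment
    universal = {
        c
        for c in range(alignment.n_columns)
        if "-" not in alignment.column(c)
    }
    extant = pd.Series(0, index=labels)
    for i, j in dataset.structure.pairs:
        if i not in universal or j not in universal:
            continue
        for row in alignment.rows:
            state = (row[i], row[j])
            if any(c not in "ACGU" for c in state):
                continue
            extant[format_state(state) if is_paired(state) else "mismatch"] += 1
    total = int(extant.sum())
    freqs = extant / total if total else extant.astype(float)
    return TransitionMatrix(
        counts=counts, classes=classes, extant_frequencies=freqs, extant_counts=extant
    )


def positional_summary(events: Iterable[PairChangeEvent], dataset: Dataset) -> pd.DataFrame:
    """One row per base pair: event counts, homoplasy flags, hosting class."""
    index = [f"{i + 1}/{j + 1}" for i, j in dataset.structure.pairs]
    df = pd.DataFrame(
        {
            "pair": index,
            "helix": dataset.structure.helix,
            "conserved": [int(f) for f in dataset.structure.conserved],
            "n_cbc": 0,
            "n_hcbc": 0,
            "n_noncomp": 0,
            "homoplasious": 0,
        }
    ).set_index("pair")
    for ev in events:
        key = f"{ev.pair[0] + 1}/{ev.pair[1] + 1}"
        if ev.event_class == "CBC":
            df.loc[key, "n_cbc"] += 1
        elif ev.event_class == "hCBC":
            df.loc[key, "n_hcbc"] += 1
        else:
            df.loc[key, "n_noncomp"] += 1
        if ev.homoplasy_label != "NHS":
            df.loc[key, "homoplasious"] = 1

    def hosting(row) -> str:
        if row["n_cbc"] and row["n_hcbc"]:
            return "both"
        if row["n_cbc"]:
            return "CBC-only"
        if row["n_hcbc"]:
            return "hCBC-only"
        return "none"

    df["compensatory_class"] = df.apply(hosting, axis=1)
    return df.reset_index()
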
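"""End-to-end pipeline: number -> reconstruct -> events -> partition -> stats.

All stages run in memory on one :class:`~cbcmap.io.Dataset`; ``write_outputs``
serializes every table as TSV with a header row, 1-based columns, and rows
sorted by (branch preorder index, pair index) so reruns diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .ancestral import Reconstruction, branch_change_table
from .io import Dataset
from .numbering import VariabilityRecord, consensus_sequence, variability_map
from .pair_events import (
    PairChangeEvent,
    PathwayHit,
    SkippedPair,
    format_state,
    pathway_audit,
    scan_pair_events,
    type_homoplasy,
)
from .partition import AuditRow, CBCComponent, audit_component, partition_taxa
from .stats import (
    BranchRatioRecord,
    TransitionMatrix,
    branch_ratios,
    positional_summary,
    transition_tally,
)


@dataclass
class PipelineResult:
    dataset: Dataset
    reconstruction: Reconstruction
    variability: list[VariabilityRecord]
    consensus: str
    events: list[PairChangeEvent]
    skipped: list[SkippedPair]
    pathway_hits: list[PathwayHit]
    components: list[CBCComponent]
    audit: list[AuditRow]
    ratios: list[BranchRatioRecord]
    transitions: TransitionMatrix
    positional: pd.DataFrame


def run_pipeline(
    dataset: Dataset,
    consensus_threshold: float = 0.70,
    expansion_regions=None,
) -> PipelineResult:
    recon = branch_change_table(dataset)
    consensus = consensus_sequence(dataset.alignment, consensus_threshold)
    variability = variability_map(
        dataset, recon.column_changes, consensus, expansion_regions
    )
    raw_events, skipped = scan_pair_events(dataset, recon)
    events = type_homoplasy(raw_events, dataset.tree, recon)
    hits = pathway_audit(events, dataset.tree)
    components = partition_taxa(dataset.tree, events)
    audit = [row for comp in components for row in audit_component(comp, dataset)]
    ratios = branch_ratios(events, recon.branch_steps)
    transitions = transition_tally(events, dataset)
    positional = positional_summary(events, dataset)
    return PipelineResult(
        dataset=dataset,
        reconstruction=recon,
        variability=variability,
        consensus=consensus,
        events=events,
        skipped=skipped,
        pathway_hits=hits,
        components=components,
        audit=audit,
        ratios=ratios,
        transitions=transitions,
        positional=positional,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _branch_order(dataset: Dataset) -> dict[str, int]:
    return {n.id: k for k, n in enumerate(dataset.tree.preorder())}


def events_frame(result: PipelineResult) -> pd.DataFrame:
    order = _branch_order(result.dataset)
    labels = {
        rec.column: rec.label for rec in result.variability
    }
    rows = [
        {
            "branch_id": ev.branch,
            "pair": f"{ev.pair[0] + 1}/{ev.pair[1] + 1}",
            "pair_labels": f"{labels[ev.pair[0]]}/{labels[ev.pair[1]]}",
            "helix": ev.helix,
            "conserved": int(ev.conserved),
            "parent_state": format_state(ev.parent_state),
            "child_state": format_state(ev.child_state),
            "class": ev.event_class,
            "homoplasy_label": ev.homoplasy_label,
            "group_id": ev.group_id or "",
        }
        for ev in result.events
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "branch_id", "pair", "pair_labels", "helix", "conserved",
            "parent_state", "child_state", "class", "homoplasy_label", "group_id",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["branch_id", "pair"],
            key=lambda col: col.map(order) if col.name == "branch_id" else col,
            kind="stable",
        ).reset_index(drop=True)
    return df


def changes_frame(result: PipelineResult) -> pd.DataFrame:
    order = _branch_order(result.dataset)
    labels = {rec.column: rec.label for rec in result.variability}
    paired = result.dataset.structure.paired_columns
    rows = [
        {
            "branch_id": ev.branch,
            "column_1based": ev.column + 1,
            "universal_label": labels[ev.column],
            "from": ev.from_state,
            "to": ev.to_state,
            "paired": int(ev.column in paired),
        }
        for ev in result.reconstruction.events
    ]
    df = pd.DataFrame(
        rows, columns=["branch_id", "column_1based", "universal_label", "from", "to", "paired"]
    )
    if len(df):
        df = df.sort_values(
            ["branch_id", "column_1based"],
            key=lambda col: col.map(order) if col.name == "branch_id" else col,
            kind="stable",
        ).reset_index(drop=True)
    return df


def numbering_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column_1based": [r.column + 1 for r in result.variability],
            "label": [r.label for r in result.variability],
            "consensus_char": [r.consensus_char for r in result.variability],
            "category": [r.category for r in result.variability],
            "n_changes": [r.n_changes for r in result.variability],
        }
    )


def partition_frame(result: PipelineResult) -> pd.DataFrame:
    rows = [
        {
            "component_id": c.component_id,
            "kind": c.kind,
            "entry_branch": c.entry_branch,
            "n_members": len(c.members),
            "members": ",".join(sorted(c.members)),
            "depleted": int(c.depleted),
            "nested_ids": ",".join(map(str, c.nested_ids)),
            "supporting_events": ";".join(
                f"{e.pair[0] + 1}/{e.pair[1] + 1}:{format_state(e.parent_state)}>"
                f"{format_state(e.child_state)}"
                for e in c.supporting_events
            ),
        }
        for c in result.components
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "component_id", "kind", "entry_branch", "n_members", "members",
            "depleted", "nested_ids", "supporting_events",
        ],
    )


def ratios_frame(result: PipelineResult) -> pd.DataFrame:
    order = _branch_order(result.dataset)
    rows = sorted(result.ratios, key=lambda r: order[r.branch])
    return pd.DataFrame(
        {
            "branch_id": [r.branch for r in rows],
            "steps_paired": [r.steps_paired for r in rows],
            "n_cbc": [r.n_cbc for r in rows],
            "n_hcbc": [r.n_hcbc for r in rows],
            "cbc_r": [round(100 * r.cbc_r, 1) if r.steps_paired else "" for r in rows],
            "hcbc_r": [round(100 * r.hcbc_r, 1) if r.steps_paired else "" for r in rows],
        }
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=kwargs.pop("index", False))
        written[name] = path

    emit("numbering.tsv", numbering_frame(result))
    emit("changes.tsv", changes_frame(result))
    emit("pair_events.tsv", events_frame(result))
    emit("partition.tsv", partition_frame(result))
    emit(
        "partition_audit.tsv",
        pd.DataFrame(
            [
                {
                    "component_id": r.component_id,
                    "taxon1": r.taxon1,
                    "taxon2": r.taxon2,
                    "n_cbc": r.n_cbc,
                }
                for r in result.audit
            ],
            columns=["component_id", "taxon1", "taxon2", "n_cbc"],
        ),
    )
    emit("branch_ratios.tsv", ratios_frame(result))
    emit("transition_matrix.tsv", result.transitions.counts, index=True)
    emit("positional_summary.tsv", result.positional)
    emit(
        "pair_frequencies.tsv",
        pd.DataFrame(
            {
                "state": result.transitions.extant_counts.index,
                "count": result.transitions.extant_counts.values,
                "percent": (100 * result.transitions.extant_frequencies).round(1).values,
            }
        ),
    )
    emit(
        "pathway_audit.tsv",
        pd.DataFrame(
            [
                {
                    "pair": f"{h.pair[0] + 1}/{h.pair[1] + 1}",
                    "first_branch": h.first_branch,
                    "second_branch": h.second_branch,
                    "start": format_state(h.start_state),
                    "intermediate": format_state(h.intermediate_state),
                    "end": format_state(h.end_state),
                }
                for h in result.pathway_hits
            ],
            columns=["pair", "first_branch", "second_branch", "start", "intermediate", "end"],
        ),
    )
    return written


def write_manifest(
    out_dir: str | Path,
    input_paths: dict[str, str | Path] | None = None,
    config: dict | None = None,
) -> Path:
    """Record package version, config hash and input checksums."""
    out = Path(out_dir)
    checksums = {}
    for name, path in (input_paths or {}).items():
        p = Path(path)
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    config = config or {}
    manifest = {
        "version": __version__,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": checksums,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
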
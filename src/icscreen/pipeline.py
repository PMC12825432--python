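"""End-to-end orchestration: rounds 1-3, ligand triage, modulation summary.

:func:`run_pipeline` executes the screen in order, persists every
intermediate table when an output directory is given, and returns a
:class:`RunReport` whose counts are, by construction, recomputations
from the artifact tables it emits.  Warnings and discrepancies are
machine-readable dict entries, not free text: a ``recorded`` block of
externally recorded figures (e.g. from the shipped reference-screen
fixture) is reconciled against the computed values and every mismatch
is logged rather than silently reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import DataError, GeneSet, ScreenConfig
from .display import percent_display, percent_value
from .ligands import TriageResult, run_triage
from .screen import (
    CandidateTable,
    DownCallMatrix,
    FOXP3_UP,
    TREG_SPECIFIC,
    build_candidates,
    build_downcall_matrix,
    classify_targets,
    hierarchy_score,
    round2_filter,
    round3_filter,
)
from .summary import altered_fraction

__all__ = ["PipelineInputs", "RunReport", "run_pipeline", "percent_display", "percent_value"]


@dataclass
class PipelineInputs:
    """Everything the end-to-end run consumes (file loading is the caller's job)."""

    membrane: GeneSet
    foxp3_up: GeneSet
    treg_specific: GeneSet
    known_ics: GeneSet
    reference_panel: GeneSet
    ko_datasets: list
    interactions: object = None  # InteractionTable
    apc_markers: dict = field(default_factory=dict)
    tolerogenic_datasets: list = field(default_factory=list)
    modulation_datasets: list = field(default_factory=list)
    scoring_dataset_ids: tuple | None = None  # default: every KO dataset


@dataclass
class RunReport:
    """Self-consistent summary of one pipeline run."""

    config: dict
    counts: dict
    downcalls: pd.DataFrame
    hierarchy: pd.DataFrame
    high_targets: list
    finalists: list
    ligands: pd.DataFrame
    modulation: list
    warnings: list
    discrepancies: list

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "counts": self.counts,
            "downcalls": self.downcalls.to_dict(orient="records"),
            "hierarchy": self.hierarchy.to_dict(orient="records"),
            "high_targets": list(self.high_targets),
            "finalists": list(self.finalists),
            "ligands": self.ligands.to_dict(orient="records"),
            "modulation": self.modulation,
            "warnings": self.warnings,
            "discrepancies": self.discrepancies,
        }


def _reconcile(recorded: dict, downcalls: pd.DataFrame, known_ics: GeneSet,
               candidates: CandidateTable, triage: TriageResult | None) -> list:
    """Compare computed values against externally recorded figures; log mismatches."""
    out = []
    by_dataset = downcalls.set_index("dataset_id") if len(downcalls) else pd.DataFrame()
    for ds, rec_pct in (recorded.get("downcall_percent") or {}).items():
        if ds not in by_dataset.index:
            continue
        computed = float(by_dataset.loc[ds, "percent"])
        if computed != rec_pct:
            out.append(
                {
                    "kind": "downcall_percent_mismatch",
                    "dataset_id": ds,
                    "computed": computed,
                    "recorded": rec_pct,
                    "message": f"{int(by_dataset.loc[ds, 'n_down'])}/"
                    f"{int(by_dataset.loc[ds, 'n_candidates'])} computes to {computed}, "
                    f"recorded as {rec_pct}; the computed value is reported",
                }
            )
    rec_size = recorded.get("known_ic_list_size")
    if rec_size is not None and rec_size != len(known_ics):
        removed = sum(candidates.removal_counts.values())
        out.append(
            {
                "kind": "known_ic_list_size_mismatch",
                "computed": len(known_ics),
                "recorded": rec_size,
                "message": f"exclusion list has {len(known_ics)} members "
                f"(removing {removed} across branches); recorded size is {rec_size}",
            }
        )
    if triage is not None:
        rec_dup = recorded.get("ligand_duplicates_removed")
        computed_dup = triage.n_memberships - triage.n_distinct
        if rec_dup is not None and rec_dup != computed_dup:
            out.append(
                {
                    "kind": "ligand_duplicate_mismatch",
                    "computed": computed_dup,
                    "recorded": rec_dup,
                    "message": f"per-receptor lists hold {triage.n_memberships} memberships "
                    f"over {triage.n_distinct} distinct ligands ({computed_dup} duplicate "
                    f"memberships); recorded as {rec_dup} duplicates removed",
                }
            )
        rec_apc = recorded.get("apc_screen_standalone") or {}
        if rec_apc:
            for receptor, counts in triage.per_receptor.items():
                standalone = triage.apc_standalone[receptor]
                if standalone > counts["membrane"]:
                    out.append(
                        {
                            "kind": "apc_screen_exceeds_membrane_screen",
                            "receptor": receptor,
                            "membrane": counts["membrane"],
                            "apc_standalone": standalone,
                            "message": "the standalone APC screen retains more partners than "
                            "the membrane screen; a chained filter cannot grow, so the "
                            "chained counts are reported alongside the standalone ones",
                        }
                    )
    return out


def run_pipeline(
    inputs: PipelineInputs,
    config: ScreenConfig | None = None,
    outdir=None,
    recorded: dict | None = None,
    aggregation: str = "any",
    counting: str = "targets",
    allow_n_mismatch: bool = False,
) -> RunReport:
    """Execute rounds 1-3 and the ligand triage; return a self-consistent report.

    Any stage failure aborts with the stage name attached to the error.
    """
    config = config or ScreenConfig()
    stage = "round1-candidates"
    try:
        candidates = build_candidates(
            inputs.membrane, inputs.foxp3_up, inputs.treg_specific, inputs.known_ics
        )

        stage = "round2-downcall-matrix"
        matrix = build_downcall_matrix(candidates, inputs.ko_datasets, config)
        candidates = round2_filter(matrix)
        matrix.candidates = candidates

        stage = "round3-hierarchy"
        scoring_ids = (
            set(inputs.scoring_dataset_ids)
            if inputs.scoring_dataset_ids is not None
            else {d.dataset_id for d in inputs.ko_datasets}
        )
        entries = [
            hierarchy_score(d, inputs.reference_panel, config)
            for d in inputs.ko_datasets
            if d.dataset_id in scoring_ids
        ]
        partition = classify_targets(entries, aggregation=aggregation)

        stage = "round3-stringency"
        candidates = round3_filter(
            matrix, partition.high, config, counting=counting, allow_n_mismatch=allow_n_mismatch
        )
        matrix.candidates = candidates
        finalists = candidates.genes("round3")

        stage = "ligand-triage"
        triage = None
        if inputs.interactions is not None and finalists:
            triage = run_triage(
                inputs.interactions,
                finalists,
                inputs.membrane,
                inputs.apc_markers,
                inputs.tolerogenic_datasets,
                config,
            )

        stage = "modulation-summary"
        modulation = []
        if triage is not None and triage.records:
            ligand_panel = GeneSet.from_iterable(
                "final_ligands", inputs.membrane.species, [r.ligand for r in triage.records]
            )
            for ds in inputs.modulation_datasets:
                rep = altered_fraction(ligand_panel, ds, config, direction="any")
                modulation.append(
                    {
                        "dataset_id": rep.dataset_id,
                        "n_altered": rep.n_altered,
                        "n_up": rep.n_up,
                        "n_down": rep.n_down,
                        "n_panel": rep.n_panel,
                        "percent": rep.percent(0),
                        "display": rep.percent_display(0),
                    }
                )
    except DataError as err:
        raise DataError(f"pipeline stage {stage!r} failed: {err}") from err

    downcalls = matrix.down_counts(config.percent_decimals)
    counts = {
        "membrane": len(inputs.membrane),
        "intersections": candidates.intersection_counts,
        "removals": candidates.removal_counts,
        "round1": {
            **candidates.branch_sizes("round1"),
            "total": len(candidates.genes("round1")),
        },
        "round2": {
            **candidates.branch_sizes("round2"),
            "total": len(candidates.genes("round2")),
        },
        "round3": {
            **candidates.branch_sizes("round3"),
            "total": len(finalists),
        },
    }
    if triage is not None:
        counts["ligands"] = {
            "per_receptor": triage.per_receptor,
            "apc_standalone": triage.apc_standalone,
            "memberships": triage.n_memberships,
            "distinct": triage.n_distinct,
        }

    warnings = list(matrix.warnings) + (list(triage.warnings) if triage else [])
    discrepancies = (
        _reconcile(recorded, downcalls, inputs.known_ics, candidates, triage)
        if recorded
        else []
    )

    report = RunReport(
        config=dataclasses.asdict(config),
        counts=counts,
        downcalls=downcalls,
        hierarchy=partition.table,
        high_targets=sorted(partition.high),
        finalists=finalists,
        ligands=triage.to_frame() if triage else pd.DataFrame(),
        modulation=modulation,
        warnings=warnings,
        discrepancies=discrepancies,
    )
    if outdir is not None:
        _write_artifacts(report, candidates, matrix, outdir)
    return report


def _write_artifacts(report: RunReport, candidates: CandidateTable, matrix: DownCallMatrix, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    candidates.frame.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    matrix.calls.to_csv(outdir / "downcall_matrix.tsv", sep="\t")
    report.downcalls.to_csv(outdir / "downcall_counts.tsv", sep="\t", index=False)
    report.hierarchy.to_json(outdir / "hierarchy.json", orient="records", indent=2)
    report.ligands.to_csv(outdir / "ligands.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
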
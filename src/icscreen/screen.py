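"""Rounds 1-3 of the checkpoint discovery screen.

Round 1 intersects the plasma-membrane universe with two Treg signatures
(a Treg-specific list and a FoxP3-upregulated list) and removes known
checkpoints, yielding two candidate branches.  Round 2 builds a
candidates x datasets down-call matrix over a panel of knockout /
blockade differential-expression datasets and keeps candidates
down-called at least once.  Round 3 first classifies the knockout
targets themselves into high and low hierarchy — a target is
high-hierarchy when its knockout down-calls strictly more than a
threshold fraction (default 20%) of a reference panel of established
inhibitory checkpoints — and then keeps candidates down-called under at
least k of the n high-hierarchy targets (default 3 of 5).

A down-call is ``pvalue < alpha and log2fc < lfc_down``, both strict.
A gene absent from a dataset is NOT_MEASURED: it is never treated as
significant, and for filtering it counts the same as NOT_DOWN (absence
of evidence), though candidates unmeasured in every high-hierarchy
dataset are flagged in the report rather than silently failed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DataError,
    DifferentialTable,
    GeneSet,
    OrthologMap,
    ScreenConfig,
    intersect,
    map_orthologs,
    normalize_symbol,
    subtract,
)
from .display import percent_value, round_half_away

DOWN = "DOWN"
NOT_DOWN = "NOT_DOWN"
NOT_MEASURED = "NOT_MEASURED"

TREG_SPECIFIC = "TREG_SPECIFIC"
FOXP3_UP = "FOXP3_UP"

__all__ = [
    "DOWN",
    "NOT_DOWN",
    "NOT_MEASURED",
    "TREG_SPECIFIC",
    "FOXP3_UP",
    "CandidateTable",
    "DownCallMatrix",
    "HierarchyEntry",
    "HierarchyPartition",
    "build_candidates",
    "call_down",
    "call_up",
    "build_downcall_matrix",
    "round2_filter",
    "hierarchy_score",
    "classify_targets",
    "round3_filter",
]


@dataclass
class CandidateTable:
    """Round-1 candidates with per-round survival flags.

    ``frame`` has one row per (gene, branch) with columns ``gene``,
    ``branch`` (TREG_SPECIFIC / FOXP3_UP), ``round1`` (always True),
    ``round2_pass`` and ``round3_pass`` (nullable booleans until the
    corresponding filter has run), and after round 3 a
    ``n_high_targets_down`` support column.
    """

    frame: pd.DataFrame
    species: str
    intersection_counts: dict = field(default_factory=dict)
    removal_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame.duplicated(["gene", "branch"]).any():
            raise DataError("candidate table has a duplicate (gene, branch) row")
        bad = ~(self.frame["round3_pass"].fillna(False) <= self.frame["round2_pass"].fillna(True))
        if bad.any():
            raise DataError("round3_pass implies round2_pass violated")

    def genes(self, round: str = "round1") -> list:
        """Distinct genes surviving the given round ('round1'/'round2'/'round3')."""
        if round == "round1":
            mask = self.frame["round1"]
        elif round == "round2":
            mask = self.frame["round2_pass"].fillna(False)
        elif round == "round3":
            mask = self.frame["round3_pass"].fillna(False)
        else:
            raise DataError(f"unknown round {round!r}")
        return sorted(self.frame.loc[mask.astype(bool), "gene"].unique())

    def branch_sizes(self, round: str = "round1") -> dict:
        """Per-branch survivor counts for the given round."""
        out = {TREG_SPECIFIC: 0, FOXP3_UP: 0}
        sub = self.frame[self.frame["gene"].isin(self.genes(round))]
        for branch, grp in sub.groupby("branch"):
            out[str(branch)] = int(grp["gene"].nunique())
        return out

    def with_flags(self, column: str, passed: set) -> "CandidateTable":
        frame = self.frame.copy()
        frame[column] = frame["gene"].isin(passed)
        return CandidateTable(
            frame=frame,
            species=self.species,
            intersection_counts=dict(self.intersection_counts),
            removal_counts=dict(self.removal_counts),
        )


def build_candidates(
    membrane: GeneSet,
    foxp3_up: GeneSet,
    treg_specific: GeneSet,
    known_ics: GeneSet,
) -> CandidateTable:
    """Round 1: two candidate branches from set algebra.

    FOXP3_UP branch  = (membrane ∩ foxp3_up) \\ known_ics
    TREG_SPECIFIC branch = (membrane ∩ treg_specific) \\ known_ics

    Intersection sizes and per-branch removal counts are recorded on the
    returned table, because the two are not derivable from each other when
    the exclusion list overlaps a branch only partially.
    """
    if len(membrane) == 0:
        raise DataError("membrane universe is empty")
    foxp3_overlap = intersect(membrane, foxp3_up, name="membrane&foxp3_up")
    treg_overlap = intersect(membrane, treg_specific, name="membrane&treg_specific")
    foxp3_branch = subtract(foxp3_overlap, known_ics, name="foxp3_branch")
    treg_branch = subtract(treg_overlap, known_ics, name="treg_branch")

    rows = [(g, FOXP3_UP) for g in foxp3_branch.sorted_members()]
    rows += [(g, TREG_SPECIFIC) for g in treg_branch.sorted_members()]
    frame = pd.DataFrame(rows, columns=["gene", "branch"])
    frame["round1"] = True
    frame["round2_pass"] = pd.Series([pd.NA] * len(frame), dtype="boolean")
    frame["round3_pass"] = pd.Series([pd.NA] * len(frame), dtype="boolean")
    return CandidateTable(
        frame=frame,
        species=membrane.species,
        intersection_counts={
            "membrane&foxp3_up": len(foxp3_overlap),
            "membrane&treg_specific": len(treg_overlap),
        },
        removal_counts={
            FOXP3_UP: len(foxp3_overlap) - len(foxp3_branch),
            TREG_SPECIFIC: len(treg_overlap) - len(treg_branch),
        },
    )


def _check_finite_row(log2fc, pvalue, dataset_id, gene):
    if log2fc is None or pvalue is None or not (math.isfinite(log2fc) and math.isfinite(pvalue)):
        raise DataError(
            f"non-finite differential statistics for gene {gene!r} in dataset "
            f"{dataset_id!r} (log2fc={log2fc}, pvalue={pvalue})"
        )


def call_down(
    log2fc: float,
    pvalue: float,
    config: ScreenConfig,
    *,
    dataset_id: str = "?",
    gene: str = "?",
) -> bool:
    """True iff the gene is significantly down: p < alpha and log2FC < cutoff (strict)."""
    _check_finite_row(log2fc, pvalue, dataset_id, gene)
    return pvalue < config.alpha and log2fc < config.lfc_down


def call_up(
    log2fc: float,
    pvalue: float,
    config: ScreenConfig,
    *,
    dataset_id: str = "?",
    gene: str = "?",
) -> bool:
    """Mirror of :func:`call_down` with the sign reversed: p < alpha and log2FC > cutoff."""
    _check_finite_row(log2fc, pvalue, dataset_id, gene)
    return pvalue < config.alpha and log2fc > config.lfc_up


@dataclass
class DownCallMatrix:
    """Candidates x datasets matrix of {DOWN, NOT_DOWN, NOT_MEASURED} calls.

    ``calls`` is indexed by candidate gene with one column per dataset_id;
    ``targets`` maps each dataset_id to its perturbed target, so the matrix
    can be aggregated per knockout target for the stringency filter.
    """

    calls: pd.DataFrame
    targets: dict
    candidates: CandidateTable
    warnings: list = field(default_factory=list)

    def down_counts(self, decimals: int = 1) -> pd.DataFrame:
        """Per-dataset down-call counts and display percentages over all candidates."""
        n = len(self.calls.index)
        rows = []
        for ds in self.calls.columns:
            n_down = int((self.calls[ds] == DOWN).sum())
            rows.append(
                {
                    "dataset_id": ds,
                    "perturbed_target": self.targets[ds],
                    "n_down": n_down,
                    "n_candidates": n,
                    "percent": percent_value(n_down, n, decimals) if n else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def build_downcall_matrix(
    candidates: CandidateTable,
    datasets,
    config: ScreenConfig,
    ortholog_maps: dict | None = None,
) -> DownCallMatrix:
    """Round-2 scaffolding: evaluate every candidate in every dataset.

    ``ortholog_maps`` optionally maps a dataset species to an
    :class:`OrthologMap` from the candidate species; by default the
    identity-after-uppercasing map reconciles species.  A dataset with no
    measured candidate at all keeps its all-NOT_MEASURED column and raises
    a machine-readable warning.
    """
    datasets = list(datasets)
    if not datasets:
        raise DataError("no differential datasets supplied")
    genes = sorted(candidates.frame["gene"].unique())
    gene_set = GeneSet.from_iterable("candidates", candidates.species, genes)

    columns = {}
    targets = {}
    warnings = []
    for ds in datasets:
        if ds.dataset_id in targets:
            raise DataError(f"duplicate dataset_id {ds.dataset_id!r}")
        if ds.species != candidates.species:
            omap = (ortholog_maps or {}).get(
                ds.species, OrthologMap.identity(candidates.species, ds.species)
            )
            mapped = map_orthologs(gene_set, omap)
            lookup = dict(zip(genes, (omap.pairs.get(g, g) for g in genes)))
            measured = {g for g in genes if lookup[g] in mapped.members and lookup[g] in ds.data.index}
        else:
            lookup = {g: g for g in genes}
            measured = {g for g in genes if g in ds.data.index}

        col = []
        for g in genes:
            if g not in measured:
                col.append(NOT_MEASURED)
                continue
            row = ds.data.loc[lookup[g]]
            is_down = call_down(
                float(row["log2fc"]), float(row["pvalue"]), config,
                dataset_id=ds.dataset_id, gene=g,
            )
            col.append(DOWN if is_down else NOT_DOWN)
        if not measured:
            warnings.append(
                {
                    "kind": "no_overlap",
                    "dataset_id": ds.dataset_id,
                    "message": "dataset shares no measured gene with the candidate list; "
                    "column retained as all NOT_MEASURED",
                }
            )
        columns[ds.dataset_id] = col
        targets[ds.dataset_id] = ds.perturbed_target

    calls = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    return DownCallMatrix(calls=calls, targets=targets, candidates=candidates, warnings=warnings)


def round2_filter(matrix: DownCallMatrix) -> CandidateTable:
    """Round 2: keep candidates with at least one DOWN cell across all datasets."""
    survivors = set(matrix.calls.index[(matrix.calls == DOWN).any(axis=1)])
    return matrix.candidates.with_flags("round2_pass", survivors)


@dataclass(frozen=True)
class HierarchyEntry:
    """Hierarchy score of one knockout dataset against the reference panel."""

    dataset_id: str
    perturbed_target: str
    n_down: int
    n_panel: int
    fraction: float
    score_percent: float  # display rounding; classification uses `fraction`
    high: bool


@dataclass(frozen=True)
class HierarchyPartition:
    """Targets split into high- and low-hierarchy groups, with per-dataset scores."""

    high: frozenset
    low: frozenset
    table: pd.DataFrame


def hierarchy_score(
    dataset: DifferentialTable,
    reference_panel: GeneSet,
    config: ScreenConfig,
) -> HierarchyEntry:
    """Score one knockout dataset: fraction of the reference panel it down-calls.

    The perturbed gene itself is excluded from the count (its deficiency
    should not vouch for itself); the denominator stays the full panel
    size so scores are comparable across datasets.  HIGH requires the
    unrounded fraction to strictly exceed ``hierarchy_threshold``.
    """
    if len(reference_panel) == 0:
        raise DataError("reference panel is empty")
    n_down = 0
    for gene in reference_panel.members:
        if gene == dataset.perturbed_target:
            continue
        hit = dataset.lookup(gene)
        if hit is None:
            continue
        if call_down(hit[0], hit[1], config, dataset_id=dataset.dataset_id, gene=gene):
            n_down += 1
    n_panel = len(reference_panel)
    fraction = n_down / n_panel
    return HierarchyEntry(
        dataset_id=dataset.dataset_id,
        perturbed_target=dataset.perturbed_target,
        n_down=n_down,
        n_panel=n_panel,
        fraction=fraction,
        score_percent=round_half_away(100.0 * fraction, 0),
        high=fraction > config.hierarchy_threshold,
    )


def classify_targets(entries, aggregation: str = "any") -> HierarchyPartition:
    """Partition perturbed targets into high and low hierarchy.

    ``any``: a target is HIGH iff any of its datasets scored HIGH.
    ``max``: a target is HIGH iff its maximum fraction exceeds the
    threshold.  With the strict greater-than rule the two modes coincide;
    both are kept so the aggregation choice is explicit and testable.
    """
    entries = list(entries)
    if aggregation not in ("any", "max"):
        raise DataError(f"unknown aggregation {aggregation!r}")
    by_target: dict = {}
    for e in entries:
        by_target.setdefault(e.perturbed_target, []).append(e)
    high, low = set(), set()
    for target, es in by_target.items():
        if aggregation == "any":
            is_high = any(e.high for e in es)
        else:
            best = max(es, key=lambda e: e.fraction)
            # threshold identical to the per-dataset rule, applied to the max
            is_high = best.high
        (high if is_high else low).add(target)
    table = pd.DataFrame(
        [
            {
                "dataset_id": e.dataset_id,
                "perturbed_target": e.perturbed_target,
                "n_down": e.n_down,
                "n_panel": e.n_panel,
                "score_percent": e.score_percent,
                "high": e.high,
            }
            for e in entries
        ]
    )
    return HierarchyPartition(high=frozenset(high), low=frozenset(low), table=table)


def round3_filter(
    matrix: DownCallMatrix,
    high_targets,
    config: ScreenConfig,
    counting: str = "targets",
    allow_n_mismatch: bool = False,
) -> CandidateTable:
    """Round 3: the >=k-of-n stringency filter over high-hierarchy knockouts.

    Only round-2 survivors are evaluated.  Support is counted per distinct
    high-hierarchy *target* by default (three datasets all knocking out
    CTLA4 count once); ``counting="datasets"`` counts datasets instead.
    Candidates unmeasured in every high-hierarchy dataset are flagged in
    ``warnings`` on the returned table's matrix rather than silently failed.
    """
    high_targets = {normalize_symbol(t) for t in high_targets}
    if len(high_targets) != config.stringency_n and not allow_n_mismatch:
        raise DataError(
            f"expected {config.stringency_n} high-hierarchy targets, got "
            f"{len(high_targets)} ({sorted(high_targets)}); pass "
            "allow_n_mismatch=True to override"
        )
    if counting not in ("targets", "datasets"):
        raise DataError(f"unknown counting mode {counting!r}")

    candidates = matrix.candidates
    if candidates.frame["round2_pass"].isna().any():
        raise DataError("round3_filter requires a table with round-2 flags; run round2_filter first")
    r2_genes = set(candidates.genes("round2"))

    high_cols = [c for c in matrix.calls.columns if matrix.targets[c] in high_targets]
    survivors = set()
    support = {}
    for gene in matrix.calls.index:
        if gene not in r2_genes:
            continue
        row = matrix.calls.loc[gene, high_cols]
        if counting == "targets":
            hit = {matrix.targets[c] for c in high_cols if row[c] == DOWN}
            n_support = len(hit)
        else:
            n_support = int((row == DOWN).sum())
        support[gene] = n_support
        if (row == NOT_MEASURED).all():
            matrix.warnings.append(
                {
                    "kind": "unmeasured_in_high_hierarchy",
                    "gene": gene,
                    "message": "round-2 survivor unmeasured in every high-hierarchy dataset",
                }
            )
        if n_support >= config.stringency_k:
            survivors.add(gene)

    out = candidates.with_flags("round3_pass", survivors)
    # round3 implies round2 by construction; record support for reporting
    out.frame["round3_pass"] = out.frame["round3_pass"] & out.frame["round2_pass"].fillna(False)
    out.frame["n_high_targets_down"] = [
        support.get(g, pd.NA) for g in out.frame["gene"]
    ]
    return out
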
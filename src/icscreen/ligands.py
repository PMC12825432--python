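"""Three-round ligand nomination for finalist checkpoints.

For each finalist receptor, its experimentally reported interaction
partners go through three filters: (a) plasma-membrane localisation,
(b) presence in at least one antigen-presenting-cell (APC) marker set —
macrophage, monocyte, B cell or dendritic cell — with every matching APC
type recorded, and (c) up-regulation in at least one tolerogenic /
anti-inflammatory APC differential dataset (e.g. M2 macrophages vs
control).  Survivors of all three rounds are de-duplicated across
receptors into one record per distinct ligand, receptors merged.

A receptor listed among its own partners (a potential homodimer) is
retained and flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    DataError,
    DifferentialTable,
    GeneSet,
    ScreenConfig,
    intersect,
    normalize_symbol,
)
from .screen import call_up

APC_TYPES = ("macrophage", "monocyte", "B_cell", "dendritic_cell")

ROUND_MEMBRANE = "membrane"
ROUND_APC = "apc"
ROUND_TOLEROGENIC = "tolerogenic"

__all__ = [
    "APC_TYPES",
    "InteractionTable",
    "LigandRecord",
    "TriageResult",
    "filter_membrane",
    "filter_apc",
    "filter_tolerogenic",
    "dedup_union",
    "triage_receptor",
    "run_triage",
]


@dataclass(frozen=True)
class InteractionTable:
    """Receptor -> interaction-partner lists, normalized and de-duplicated."""

    receptors: Mapping  # receptor symbol -> frozenset of partner symbols
    species: str = "human"
    source: str = ""

    @classmethod
    def from_pairs(cls, pairs: Iterable, species: str = "human", source: str = "") -> "InteractionTable":
        table: dict = {}
        for receptor, partner in pairs:
            r = normalize_symbol(receptor, species)
            table.setdefault(r, set()).add(normalize_symbol(partner, species))
        return cls(
            receptors={r: frozenset(ps) for r, ps in table.items()},
            species=species,
            source=source,
        )

    def partners(self, receptor: str) -> GeneSet:
        r = normalize_symbol(receptor, self.species)
        if r not in self.receptors:
            raise DataError(f"no interaction partners recorded for receptor {r!r}")
        return GeneSet(
            name=f"{r}_partners",
            species=self.species,
            members=self.receptors[r],
            provenance=self.source or "interaction table",
        )


@dataclass(frozen=True)
class LigandRecord:
    """One nominated ligand with full triage provenance."""

    ligand: str
    receptors: frozenset
    apc_types: frozenset
    tolerogenic_support: frozenset  # dataset_ids with an up-call
    rounds_passed: frozenset
    self_partner: bool = False  # ligand identical to one of its receptors

    def __post_init__(self):
        if (ROUND_TOLEROGENIC in self.rounds_passed) != bool(self.tolerogenic_support):
            raise DataError(
                f"ligand {self.ligand!r}: tolerogenic support and rounds_passed disagree"
            )
        if (ROUND_APC in self.rounds_passed) != bool(self.apc_types):
            raise DataError(
                f"ligand {self.ligand!r}: apc_types and rounds_passed disagree"
            )


def filter_membrane(partners: GeneSet, membrane: GeneSet) -> GeneSet:
    """Round a: retain partners annotated to the plasma membrane (pure intersection)."""
    return intersect(partners, membrane, name=f"{partners.name}&membrane")


def filter_apc(candidates: GeneSet, apc_markers: Mapping) -> dict:
    """Round b: retain genes present in >=1 APC marker set, recording every match.

    Returns ``{gene: frozenset of matching APC types}``.  Attribution is
    non-exclusive: a ligand found in both the B-cell and dendritic-cell
    marker sets carries both types.
    """
    if not apc_markers:
        raise DataError("at least one APC marker set is required")
    out = {}
    for gene in candidates.members:
        types = frozenset(t for t, s in apc_markers.items() if gene in s.members)
        if types:
            out[gene] = types
    return out


def filter_tolerogenic(
    attributed: Mapping,
    receptor: str,
    tolerogenic_datasets,
    config: ScreenConfig,
) -> list:
    """Round c: keep genes up-called in >=1 tolerogenic APC dataset.

    ``attributed`` is the output of :func:`filter_apc` for one receptor.
    An up-call mirrors the down-call convention with reversed sign:
    p < alpha and log2FC > lfc_up, both strict.
    """
    receptor = normalize_symbol(receptor)
    datasets = list(tolerogenic_datasets)
    if not datasets:
        raise DataError("no tolerogenic datasets supplied")
    records = []
    for gene in sorted(attributed):
        support = set()
        for ds in datasets:
            hit = ds.lookup(gene)
            if hit is None:
                continue
            if call_up(hit[0], hit[1], config, dataset_id=ds.dataset_id, gene=gene):
                support.add(ds.dataset_id)
        if support:
            records.append(
                LigandRecord(
                    ligand=gene,
                    receptors=frozenset({receptor}),
                    apc_types=frozenset(attributed[gene]),
                    tolerogenic_support=frozenset(support),
                    rounds_passed=frozenset({ROUND_MEMBRANE, ROUND_APC, ROUND_TOLEROGENIC}),
                    self_partner=(gene == receptor),
                )
            )
    return records


def dedup_union(per_receptor: Mapping) -> list:
    """Merge per-receptor ligand lists into one record per distinct ligand.

    Receptors, APC types and tolerogenic support are unioned; the output
    is sorted by ligand symbol.  Per-receptor counts stay available to the
    caller through the input mapping.
    """
    merged: dict = {}
    for records in per_receptor.values():
        for rec in records:
            if rec.ligand in merged:
                old = merged[rec.ligand]
                merged[rec.ligand] = LigandRecord(
                    ligand=rec.ligand,
                    receptors=old.receptors | rec.receptors,
                    apc_types=old.apc_types | rec.apc_types,
                    tolerogenic_support=old.tolerogenic_support | rec.tolerogenic_support,
                    rounds_passed=old.rounds_passed | rec.rounds_passed,
                    self_partner=old.self_partner or rec.self_partner,
                )
            else:
                merged[rec.ligand] = rec
    return [merged[k] for k in sorted(merged)]


@dataclass
class TriageResult:
    """Full triage output: final records plus per-receptor round counts."""

    records: list
    per_receptor: dict  # receptor -> {"partners": n, "membrane": n, "apc": n, "final": n}
    apc_standalone: dict  # receptor -> |partners ∩ APC-marker union| (no membrane filter)
    warnings: list = field(default_factory=list)

    @property
    def n_distinct(self) -> int:
        return len(self.records)

    @property
    def n_memberships(self) -> int:
        return sum(c["final"] for c in self.per_receptor.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ligand": r.ligand,
                    "receptors": ",".join(sorted(r.receptors)),
                    "apc_types": ",".join(sorted(r.apc_types)),
                    "tolerogenic_support": ",".join(sorted(r.tolerogenic_support)),
                    "rounds_passed": ",".join(sorted(r.rounds_passed)),
                    "self_partner": r.self_partner,
                }
                for r in self.records
            ]
        )


def triage_receptor(
    receptor: str,
    partners: GeneSet,
    membrane: GeneSet,
    apc_markers: Mapping,
    tolerogenic_datasets,
    config: ScreenConfig,
):
    """Run the three filter rounds for one receptor.

    Returns ``(records, counts)`` where ``counts`` holds the list size
    after each round.
    """
    on_membrane = filter_membrane(partners, membrane)
    attributed = filter_apc(on_membrane, apc_markers)
    records = filter_tolerogenic(attributed, receptor, tolerogenic_datasets, config)
    counts = {
        "partners": len(partners),
        "membrane": len(on_membrane),
        "apc": len(attributed),
        "final": len(records),
    }
    return records, counts


def run_triage(
    interactions: InteractionTable,
    receptors,
    membrane: GeneSet,
    apc_markers: Mapping,
    tolerogenic_datasets,
    config: ScreenConfig,
) -> TriageResult:
    """Triage every finalist receptor and de-duplicate across receptors.

    ``apc_standalone`` additionally records, per receptor, how many raw
    partners carry an APC marker irrespective of membrane annotation —
    a diagnostic count for reconciling externally reported figures that
    applied the APC screen to the unfiltered partner lists.
    """
    per_receptor_records = {}
    per_receptor_counts = {}
    apc_standalone = {}
    warnings = []
    for receptor in receptors:
        r = normalize_symbol(receptor)
        partners = interactions.partners(r)
        records, counts = triage_receptor(
            r, partners, membrane, apc_markers, tolerogenic_datasets, config
        )
        per_receptor_records[r] = records
        per_receptor_counts[r] = counts
        apc_standalone[r] = len(filter_apc(partners, apc_markers))
        if counts["final"] == 0:
            warnings.append(
                {
                    "kind": "no_ligand",
                    "receptor": r,
                    "message": "no partner survived all three triage rounds",
                }
            )
    records = dedup_union(per_receptor_records)
    return TriageResult(
        records=records,
        per_receptor=per_receptor_counts,
        apc_standalone=apc_standalone,
        warnings=warnings,
    )
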
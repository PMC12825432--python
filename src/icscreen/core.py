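"""Gene-set and differential-table primitives shared by every screening round.

The screen works on three kinds of objects: named gene sets (membrane
universe, Treg signature, FoxP3-upregulated signature, exclusion lists,
APC marker sets), per-dataset differential-expression tables (one row per
gene with a log2 fold-change and a p-value), and a configuration object
holding every threshold the rounds use.  Gene symbols are normalized to a
single canon (trimmed, uppercased, internal whitespace removed) so that
human symbols and their capitalised mouse counterparts compare equal after
an explicit ortholog mapping step.

Set algebra keeps provenance: every derived :class:`GeneSet` records its
parents, so the full parentage of, say, the FoxP3 candidate branch can be
reconstructed back to the input files.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SPECIES = ("human", "mouse")

__all__ = [
    "SPECIES",
    "IcscreenError",
    "ConfigError",
    "DataError",
    "normalize_symbol",
    "GeneSet",
    "intersect",
    "subtract",
    "OrthologMap",
    "map_orthologs",
    "DifferentialTable",
    "ScreenConfig",
]


class IcscreenError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(IcscreenError):
    """An invalid threshold, option, or configuration file."""


class DataError(IcscreenError):
    """Malformed or inconsistent input data."""


_WS = re.compile(r"\s+")


def normalize_symbol(raw: str, species: str = "human") -> str:
    """Return the canonical form of a gene symbol.

    The canon is deterministic and idempotent: trim, remove internal
    whitespace, uppercase.  ``species`` is accepted for interface symmetry
    with the ortholog machinery; the canon itself is species-independent
    (mouse ``Pdcd1`` and human ``PDCD1`` both canonicalise to ``PDCD1``,
    which is exactly what the identity ortholog map relies on).

    Raises
    ------
    DataError
        If the symbol is empty or whitespace-only.
    """
    if raw is None:
        raise DataError("gene symbol is None")
    text = str(raw).strip()
    if not text:
        raise DataError(f"empty gene symbol: {raw!r}")
    return _WS.sub("", text).upper()


def _check_species(species: str) -> None:
    if species not in SPECIES:
        raise DataError(f"unknown species {species!r}; expected one of {SPECIES}")


@dataclass(frozen=True)
class GeneSet:
    """A named, species-tagged collection of normalized gene symbols.

    ``provenance`` is a free-text source tag; ``parents`` holds the gene
    sets a derived set was computed from, so :meth:`lineage` can print the
    full derivation tree.
    """

    name: str
    species: str
    members: frozenset
    provenance: str = ""
    parents: tuple = ()

    def __post_init__(self):
        _check_species(self.species)
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))
        for m in self.members:
            if m != normalize_symbol(m):
                raise DataError(
                    f"gene set {self.name!r} contains non-canonical symbol {m!r}"
                )

    @classmethod
    def from_iterable(
        cls,
        name: str,
        species: str,
        raw_members: Iterable[str],
        provenance: str = "",
    ) -> "GeneSet":
        """Build a gene set, normalizing and de-duplicating the symbols."""
        members = frozenset(normalize_symbol(m, species) for m in raw_members)
        return cls(name=name, species=species, members=members, provenance=provenance)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __iter__(self):
        return iter(self.sorted_members())

    def sorted_members(self) -> list:
        return sorted(self.members)

    def lineage(self, _depth: int = 0) -> str:
        """Render the provenance tree of this set (parents recursively)."""
        pad = "  " * _depth
        line = f"{pad}{self.name} [{self.species}, n={len(self)}] {self.provenance}"
        lines = [line]
        for p in self.parents:
            lines.append(p.lineage(_depth + 1))
        return "\n".join(lines)


def _require_same_species(a: GeneSet, b: GeneSet, op: str) -> None:
    if a.species != b.species:
        raise DataError(
            f"{op}: species mismatch between {a.name!r} ({a.species}) and "
            f"{b.name!r} ({b.species}); map orthologs first"
        )


def intersect(a: GeneSet, b: GeneSet, name: str | None = None) -> GeneSet:
    """Set intersection with provenance; both sets must share a species."""
    _require_same_species(a, b, "intersect")
    return GeneSet(
        name=name or f"({a.name} & {b.name})",
        species=a.species,
        members=a.members & b.members,
        provenance="intersect",
        parents=(a, b),
    )


def subtract(a: GeneSet, b: GeneSet, name: str | None = None) -> GeneSet:
    """Set difference a \\ b with provenance; both sets must share a species."""
    _require_same_species(a, b, "subtract")
    return GeneSet(
        name=name or f"({a.name} - {b.name})",
        species=a.species,
        members=a.members - b.members,
        provenance="subtract",
        parents=(a, b),
    )


@dataclass(frozen=True)
class OrthologMap:
    """A one-way symbol mapping between species.

    The mapping is a function: each source symbol maps to at most one
    target symbol.  ``unmapped`` decides what happens to symbols absent
    from ``pairs``: ``"drop"`` removes them, ``"keep"`` carries the
    canonicalised source symbol through unchanged (the identity-after-
    uppercasing default used when no curated table is supplied).
    """

    source_species: str
    target_species: str
    pairs: Mapping
    unmapped: str = "drop"

    def __post_init__(self):
        _check_species(self.source_species)
        _check_species(self.target_species)
        if self.unmapped not in ("drop", "keep"):
            raise ConfigError(f"unmapped policy must be 'drop' or 'keep', got {self.unmapped!r}")

    @classmethod
    def from_pairs(
        cls,
        source_species: str,
        target_species: str,
        pairs: Iterable,
        unmapped: str = "drop",
    ) -> "OrthologMap":
        mapping: dict = {}
        for src, dst in pairs:
            s = normalize_symbol(src, source_species)
            d = normalize_symbol(dst, target_species)
            if s in mapping and mapping[s] != d:
                raise DataError(
                    f"ortholog map is not a function: {s!r} maps to both "
                    f"{mapping[s]!r} and {d!r}"
                )
            mapping[s] = d
        return cls(source_species, target_species, mapping, unmapped)

    @classmethod
    def identity(cls, source_species: str, target_species: str) -> "OrthologMap":
        """Identity-after-uppercasing map (every symbol kept as-is)."""
        return cls(source_species, target_species, {}, unmapped="keep")


def map_orthologs(
    genes: GeneSet,
    omap: OrthologMap,
    target_species: str | None = None,
) -> GeneSet:
    """Translate a gene set into the map's target species.

    Unmapped symbols are handled per the map's policy; the result is
    de-duplicated (two source symbols may collapse onto one target).
    """
    if genes.species != omap.source_species:
        raise DataError(
            f"map_orthologs: gene set {genes.name!r} is {genes.species} but the "
            f"map expects {omap.source_species}"
        )
    if target_species is not None and target_species != omap.target_species:
        raise DataError(
            f"map_orthologs: requested target {target_species!r} but the map "
            f"targets {omap.target_species!r}"
        )
    out = set()
    for m in genes.members:
        if m in omap.pairs:
            out.add(omap.pairs[m])
        elif omap.unmapped == "keep":
            out.add(m)
    return GeneSet(
        name=f"{genes.name}->{omap.target_species}",
        species=omap.target_species,
        members=frozenset(out),
        provenance=f"ortholog-map ({omap.unmapped} unmapped)",
        parents=(genes,),
    )


@dataclass
class DifferentialTable:
    """One perturbation dataset: per-gene log2FC and p-value plus metadata.

    ``data`` is indexed by normalized gene symbol with float columns
    ``log2fc`` and ``pvalue``.  Construction validates that p-values lie in
    [0, 1], log2FC is finite, and each symbol appears once (duplicates are
    rejected by default; ``duplicate_policy="keep_most_significant"`` keeps
    the row with the smallest p-value, breaking ties by larger |log2FC|).
    """

    dataset_id: str
    perturbed_target: str
    species: str
    comparison: str
    data: pd.DataFrame

    REQUIRED_COLUMNS = ("gene", "log2fc", "pvalue")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        dataset_id: str,
        perturbed_target: str,
        species: str,
        comparison: str = "",
        duplicate_policy: str = "error",
    ) -> "DifferentialTable":
        _check_species(species)
        missing = [c for c in cls.REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(
                f"dataset {dataset_id!r}: missing required column(s) {missing}"
            )
        df = frame.loc[:, ["gene", "log2fc", "pvalue"]].copy()
        df["gene"] = [normalize_symbol(g, species) for g in df["gene"]]
        df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
        df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")

        bad = df[~np.isfinite(df["log2fc"])]
        if len(bad):
            raise DataError(
                f"dataset {dataset_id!r}: non-finite log2fc for gene(s) "
                f"{sorted(bad['gene'].head(5))}"
            )
        bad = df[df["pvalue"].isna() | (df["pvalue"] < 0) | (df["pvalue"] > 1)]
        if len(bad):
            raise DataError(
                f"dataset {dataset_id!r}: p-value outside [0,1] for gene(s) "
                f"{sorted(bad['gene'].head(5))}"
            )

        if df["gene"].duplicated().any():
            dupes = sorted(df.loc[df["gene"].duplicated(), "gene"].unique()[:5])
            if duplicate_policy == "error":
                raise DataError(
                    f"dataset {dataset_id!r}: duplicate gene row(s) {dupes}; "
                    "pass duplicate_policy='keep_most_significant' to merge"
                )
            elif duplicate_policy == "keep_most_significant":
                df = (
                    df.assign(_abs=df["log2fc"].abs())
                    .sort_values(["pvalue", "_abs"], ascending=[True, False], kind="mergesort")
                    .drop_duplicates("gene", keep="first")
                    .drop(columns="_abs")
                )
            else:
                raise ConfigError(f"unknown duplicate_policy {duplicate_policy!r}")

        data = df.set_index("gene").sort_index()
        return cls(
            dataset_id=dataset_id,
            perturbed_target=normalize_symbol(perturbed_target, species),
            species=species,
            comparison=comparison,
            data=data,
        )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def lookup(self, gene: str):
        """Return (log2fc, pvalue) for a gene, or None if not measured."""
        g = normalize_symbol(gene)
        if g not in self.data.index:
            return None
        row = self.data.loc[g]
        return float(row["log2fc"]), float(row["pvalue"])


@dataclass(frozen=True)
class ScreenConfig:
    """Every threshold the screening rounds use, in one place.

    alpha
        Significance threshold; a call requires ``pvalue < alpha`` (strict).
    lfc_down / lfc_up
        Log2FC cutoffs for down-/up-calls, both strict; the defaults (0)
        require only the sign, with no magnitude threshold.
    hierarchy_threshold
        Fraction of the reference panel a knockout must down-call (strict
        greater-than) to classify as high-hierarchy; default 0.20.
    stringency_k / stringency_n
        The round-3 rule: down-called under at least k of the n
        high-hierarchy knockout targets (defaults 3 of 5).
    percent_decimals
        Decimals for displayed percentages (half-away-from-zero rounding);
        classification always uses unrounded fractions.
    seed
        Seed for every stochastic operation (fixture generation).
    """

    alpha: float = 0.05
    lfc_down: float = 0.0
    lfc_up: float = 0.0
    hierarchy_threshold: float = 0.20
    stringency_k: int = 3
    stringency_n: int = 5
    percent_decimals: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0.0 <= self.hierarchy_threshold < 1.0):
            raise ConfigError(
                f"hierarchy_threshold must be in [0,1), got {self.hierarchy_threshold}"
            )
        if not (1 <= self.stringency_k <= self.stringency_n):
            raise ConfigError(
                f"need 1 <= stringency_k <= stringency_n, got "
                f"k={self.stringency_k}, n={self.stringency_n}"
            )
        if self.percent_decimals < 0:
            raise ConfigError("percent_decimals must be >= 0")
        if not math.isfinite(self.lfc_down) or not math.isfinite(self.lfc_up):
            raise ConfigError("lfc thresholds must be finite")
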
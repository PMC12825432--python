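"""Readers and writers for the screen's plain-text interchange formats.

Gene sets travel as GMT (one set per line: name, description, members)
or single-column TSV with a header; differential tables as TSV with
columns ``gene``, ``log2fc``, ``pvalue`` plus a JSON (or YAML) metadata
sidecar ``<stem>.meta.json`` carrying dataset_id, perturbed_target,
species and comparison; ortholog maps and interaction tables as
two-column TSV.  Everything round-trips through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .core import DataError, DifferentialTable, GeneSet, OrthologMap
from .ligands import InteractionTable

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_de_table",
    "write_de_table",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_interactions",
    "write_interactions",
    "read_expression_matrix",
    "write_expression_matrix",
]


def read_gmt(path, species: str = "human") -> dict:
    """Read a GMT file into ``{set name: GeneSet}`` (description -> provenance)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, desc, members = fields[0], fields[1], fields[2:]
            out[name] = GeneSet.from_iterable(name, species, members, provenance=desc)
    return out


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.provenance or "-"] + gs.sorted_members()) + "\n")


def read_gene_list(path, name: str | None = None, species: str = "human") -> GeneSet:
    """Single-column TSV with a header row."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] != 1:
        raise DataError(f"{path}: expected a single-column gene list, got {frame.shape[1]} columns")
    return GeneSet.from_iterable(
        name or Path(path).stem, species, frame.iloc[:, 0].astype(str), provenance=str(path)
    )


def write_gene_list(gene_set: GeneSet, path, header: str = "gene") -> None:
    pd.DataFrame({header: gene_set.sorted_members()}).to_csv(path, sep="\t", index=False)


def _sidecar(path) -> dict:
    path = Path(path)
    for suffix, loader in ((".meta.json", json.load), (".meta.yaml", yaml.safe_load)):
        cand = path.parent / (path.stem + suffix)
        if cand.exists():
            with open(cand) as fh:
                return loader(fh)
    raise DataError(f"no metadata sidecar found for {path} (expected {path.stem}.meta.json or .meta.yaml)")


def read_de_table(path, meta: dict | None = None, duplicate_policy: str = "error") -> DifferentialTable:
    """Read a DE TSV; metadata from ``meta`` or the ``<stem>.meta.json`` sidecar."""
    if meta is None:
        meta = _sidecar(path)
    for key in ("dataset_id", "perturbed_target", "species"):
        if key not in meta:
            raise DataError(f"{path}: metadata missing required key {key!r}")
    frame = pd.read_csv(path, sep="\t")
    return DifferentialTable.from_frame(
        frame,
        dataset_id=meta["dataset_id"],
        perturbed_target=meta["perturbed_target"],
        species=meta["species"],
        comparison=meta.get("comparison", ""),
        duplicate_policy=duplicate_policy,
    )


def write_de_table(table: DifferentialTable, path) -> None:
    path = Path(path)
    table.data.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "dataset_id": table.dataset_id,
        "perturbed_target": table.perturbed_target,
        "species": table.species,
        "comparison": table.comparison,
    }
    with open(path.parent / (path.stem + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_ortholog_map(path, source_species: str, target_species: str, unmapped: str = "drop") -> OrthologMap:
    """Two-column TSV (source symbol, target symbol) with a header row."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] != 2:
        raise DataError(f"{path}: ortholog map needs exactly two columns")
    return OrthologMap.from_pairs(
        source_species, target_species, frame.itertuples(index=False), unmapped=unmapped
    )


def write_ortholog_map(omap: OrthologMap, path) -> None:
    pd.DataFrame(
        sorted(omap.pairs.items()), columns=[omap.source_species, omap.target_species]
    ).to_csv(path, sep="\t", index=False)


def read_interactions(path, species: str = "human", source: str = "") -> InteractionTable:
    """Two-column TSV (receptor, partner) with a header row."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] != 2:
        raise DataError(f"{path}: interaction table needs exactly two columns")
    return InteractionTable.from_pairs(
        frame.itertuples(index=False), species=species, source=source or str(path)
    )


def write_interactions(table: InteractionTable, path) -> None:
    rows = [
        (receptor, partner)
        for receptor in sorted(table.receptors)
        for partner in sorted(table.receptors[receptor])
    ]
    pd.DataFrame(rows, columns=["receptor", "partner"]).to_csv(path, sep="\t", index=False)


def read_expression_matrix(matrix_path, labels_path):
    """Dense cell x gene TSV plus a two-column cell-label TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels_frame = pd.read_csv(labels_path, sep="\t")
    if labels_frame.shape[1] != 2:
        raise DataError(f"{labels_path}: cell label table needs columns (cell, cell_type)")
    labels = labels_frame.set_index(labels_frame.columns[0]).iloc[:, 0]
    return matrix, labels


def write_expression_matrix(matrix: pd.DataFrame, labels: pd.Series, matrix_path, labels_path) -> None:
    matrix.to_csv(matrix_path, sep="\t", float_format="%.6g")
    labels.rename("cell_type").rename_axis("cell").reset_index().to_csv(
        labels_path, sep="\t", index=False
    )
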
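"""Post-hoc characterisation of gene panels under further perturbations.

Two readouts mirror the downstream validation steps of the screen: the
fraction of a panel significantly altered in a perturbation dataset
(e.g. the nominated ligands under PD-L1 knock-down), and per-cell-type
mean expression summaries of a labelled cell x gene matrix (argmax cell
type per gene, CD8-to-CD4 mean ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, DifferentialTable, GeneSet, ScreenConfig
from .display import percent_display, percent_value

__all__ = [
    "ModulationReport",
    "CellTypeExpressionSummary",
    "altered_fraction",
    "celltype_means",
]


@dataclass(frozen=True)
class ModulationReport:
    """Fraction of a gene panel significantly altered in one dataset.

    Unmeasured panel genes stay in the denominator (they cannot be called
    altered) and are reported separately in ``n_unmeasured``.
    """

    panel_name: str
    dataset_id: str
    direction: str
    n_panel: int
    n_altered: int
    n_up: int
    n_down: int
    n_unmeasured: int

    @property
    def fraction_altered(self) -> float:
        return self.n_altered / self.n_panel

    def percent(self, decimals: int = 0) -> float:
        return percent_value(self.n_altered, self.n_panel, decimals)

    def percent_display(self, decimals: int = 0) -> str:
        return percent_display(self.n_altered, self.n_panel, decimals)


def altered_fraction(
    panel: GeneSet,
    dataset: DifferentialTable,
    config: ScreenConfig,
    direction: str = "any",
) -> ModulationReport:
    """Count panel genes with p < alpha (and the sign constraint, if any).

    ``direction="any"`` counts either sign — significance alone; ``"up"``
    additionally requires log2FC > lfc_up, ``"down"`` log2FC < lfc_down
    (strict, mirroring the screen's call conventions).
    """
    if len(panel) == 0:
        raise DataError("altered_fraction: empty panel")
    if direction not in ("any", "up", "down"):
        raise DataError(f"unknown direction {direction!r}")
    n_altered = n_up = n_down = n_unmeasured = 0
    for gene in panel.members:
        hit = dataset.lookup(gene)
        if hit is None:
            n_unmeasured += 1
            continue
        log2fc, pvalue = hit
        if not pvalue < config.alpha:
            continue
        is_up = log2fc > config.lfc_up
        is_down = log2fc < config.lfc_down
        if direction == "any":
            n_altered += 1
            n_up += int(is_up)
            n_down += int(is_down)
        elif direction == "up" and is_up:
            n_altered += 1
            n_up += 1
        elif direction == "down" and is_down:
            n_altered += 1
            n_down += 1
    return ModulationReport(
        panel_name=panel.name,
        dataset_id=dataset.dataset_id,
        direction=direction,
        n_panel=len(panel),
        n_altered=n_altered,
        n_up=n_up,
        n_down=n_down,
        n_unmeasured=n_unmeasured,
    )


@dataclass
class CellTypeExpressionSummary:
    """Per-(gene, cell type) mean expression in the matrix's own units.

    ``means`` is cell_type x gene.  Ratios between two cell types are
    flagged undefined (NaN with an entry in ``undefined_ratios``) when the
    denominator mean is zero.
    """

    means: pd.DataFrame
    n_cells: pd.Series  # cells per type
    undefined_ratios: list

    def argmax_type(self) -> pd.Series:
        """Cell type with the highest mean, per gene (ties: first by type order)."""
        return self.means.idxmax(axis=0)

    def ratio(self, numerator_type: str, denominator_type: str) -> pd.Series:
        """Per-gene mean ratio between two cell types (e.g. CD8 over CD4)."""
        for t in (numerator_type, denominator_type):
            if t not in self.means.index:
                raise DataError(f"unknown cell type {t!r}")
        num = self.means.loc[numerator_type]
        den = self.means.loc[denominator_type]
        out = pd.Series(np.where(den == 0, np.nan, num / den), index=num.index)
        for gene in out.index[den == 0]:
            self.undefined_ratios.append(
                {
                    "gene": gene,
                    "numerator": numerator_type,
                    "denominator": denominator_type,
                    "message": "denominator mean is zero; ratio undefined",
                }
            )
        return out


def celltype_means(
    matrix: pd.DataFrame,
    labels: pd.Series,
    genes: GeneSet | None = None,
) -> CellTypeExpressionSummary:
    """Arithmetic per-cell-type means of a cell x gene expression matrix.

    ``labels`` maps every cell (matrix row) to a cell type.  Values are
    averaged in the matrix's own units — any normalisation is the
    caller's responsibility.  Restricting to ``genes`` requires all of
    them to be matrix columns.
    """
    missing_cells = matrix.index.difference(labels.index)
    if len(missing_cells):
        raise DataError(f"unlabeled cell(s): {sorted(missing_cells[:5])}")
    cell_labels = labels.loc[matrix.index]
    if cell_labels.isna().any():
        raise DataError("cell label table contains missing labels")
    if genes is not None:
        wanted = sorted(genes.members)
        absent = [g for g in wanted if g not in matrix.columns]
        if absent:
            raise DataError(f"gene(s) absent from expression matrix: {absent[:5]}")
        matrix = matrix.loc[:, wanted]
    means = matrix.groupby(cell_labels).mean().sort_index()
    n_cells = cell_labels.value_counts().sort_index()
    return CellTypeExpressionSummary(means=means, n_cells=n_cells, undefined_ratios=[])
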
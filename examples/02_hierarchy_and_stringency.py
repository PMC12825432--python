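"""Hierarchy scoring of knockout targets and the k-of-n stringency filter.

A knockout is "high-hierarchy" when it down-calls strictly more than 20%
of a 25-member panel of established inhibitory checkpoints (the knocked-
out gene itself is excluded from its own count).  A small hand-built
instance shows the strict boundary at exactly 20% and how the 3-of-5
target rule counts distinct knockout targets, not datasets.
"""

from icscreen import (
    GeneSet,
    ScreenConfig,
    build_candidates,
    build_downcall_matrix,
    classify_targets,
    hierarchy_score,
    round2_filter,
    round3_filter,
)
from icscreen.core import DifferentialTable
import pandas as pd

cfg = ScreenConfig()
panel_genes = [f"IC{i:02d}" for i in range(24)] + ["CTLA4"]
panel = GeneSet.from_iterable("panel", "human", panel_genes)


def ko_dataset(dataset_id, target, n_panel_down, candidate_down):
    rows = []
    planted = [g for g in panel_genes if g != target][:n_panel_down]
    for g in panel_genes:
        rows.append((g, -1.0 if g in planted else 0.3, 0.01 if g in planted else 0.8))
    rows.append(("CAND1", -1.0 if candidate_down else 0.2, 0.01 if candidate_down else 0.9))
    return DifferentialTable.from_frame(
        pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"]),
        dataset_id=dataset_id, perturbed_target=target, species="human",
    )


datasets = [
    ko_dataset("CTLA4_KO", "CTLA4", 6, True),   # 6/25 = 24%  -> HIGH
    ko_dataset("PDCD1_KO", "PDCD1", 7, True),   # 7/25 = 28%  -> HIGH
    ko_dataset("LAG3_KO", "LAG3", 8, True),     # 8/25 = 32%  -> HIGH
    ko_dataset("TIGIT_KO", "TIGIT", 8, False),  # 8/25 = 32%  -> HIGH
    ko_dataset("KLRG1_KO", "KLRG1", 8, False),  # 8/25 = 32%  -> HIGH
    ko_dataset("CD47_KO", "CD47", 5, False),    # 5/25 = 20% exactly -> LOW (strict >)
]

entries = [hierarchy_score(d, panel, cfg) for d in datasets]
for e in entries:
    print(f"{e.dataset_id}: {e.n_down}/{e.n_panel} panel down-calls "
          f"= {e.score_percent:.0f}% -> {'HIGH' if e.high else 'LOW'}")
partition = classify_targets(entries)
print("high-hierarchy targets:", sorted(partition.high))

# one candidate, down-called under CTLA4, PDCD1 and LAG3 = 3 distinct
# high-hierarchy targets, so it passes the 3-of-5 stringency rule
candidates = build_candidates(
    GeneSet.from_iterable("membrane", "human", ["CAND1"]),
    GeneSet.from_iterable("foxp3_up", "human", ["CAND1"]),
    GeneSet.from_iterable("treg_specific", "human", []),
    GeneSet.from_iterable("known", "human", []),
)
matrix = build_downcall_matrix(candidates, datasets, cfg)
matrix.candidates = round2_filter(matrix)
result = round3_filter(matrix, partition.high, cfg)
print("finalists:", result.genes("round3"),
      "(supported by", int(result.frame["n_high_targets_down"].iloc[0]), "of 5 high-hierarchy targets)")
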
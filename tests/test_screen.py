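"""Rounds 1-3: candidate generation, down-calls, hierarchy, stringency."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from icscreen import (
    DOWN,
    DataError,
    GeneSet,
    NOT_DOWN,
    NOT_MEASURED,
    ScreenConfig,
    build_candidates,
    build_downcall_matrix,
    call_down,
    call_up,
    classify_targets,
    hierarchy_score,
    round2_filter,
    round3_filter,
)
from conftest import make_de

CFG = ScreenConfig()


def gs(name, members, species="human"):
    return GeneSet.from_iterable(name, species, members)


class TestCallDown:
    @pytest.mark.parametrize(
        "log2fc, pvalue, expected",
        [
            (-1.2, 0.01, True),
            (-1.2, 0.05, False),  # p = alpha is not significant (strict)
            (0.0, 0.001, False),  # zero fold-change is not down (strict)
            (-1e-9, 0.049, True),
            (1.2, 0.01, False),
        ],
    )
    def test_strict_boundaries(self, log2fc, pvalue, expected):
        assert call_down(log2fc, pvalue, CFG) is expected

    def test_up_call_mirrors_down_call(self):
        assert call_up(1.2, 0.01, CFG) and not call_up(1.2, 0.05, CFG)
        assert not call_up(0.0, 0.001, CFG)

    def test_nan_rejected_with_context(self):
        with pytest.raises(DataError, match="GENEX.*DSY|DSY.*GENEX"):
            call_down(float("nan"), 0.01, CFG, dataset_id="DSY", gene="GENEX")


class TestBuildCandidates:
    def test_empty_exclusion_gives_raw_intersections(self):
        membrane = gs("m", ["A1", "A2", "B1", "B2", "C1"])
        foxp3 = gs("f", ["A1", "A2", "X1"])
        treg = gs("t", ["B1", "B2", "X2"])
        table = build_candidates(membrane, foxp3, treg, gs("k", []))
        assert table.branch_sizes() == {"TREG_SPECIFIC": 2, "FOXP3_UP": 2}
        assert table.removal_counts == {"FOXP3_UP": 0, "TREG_SPECIFIC": 0}

    def test_empty_membrane_rejected(self):
        with pytest.raises(DataError):
            build_candidates(gs("m", []), gs("f", ["A1"]), gs("t", ["A1"]), gs("k", []))

    def test_matches_brute_force_on_random_universe(self):
        rng = np.random.default_rng(7)
        pool = [f"G{i:03d}" for i in range(100)]
        membrane = set(rng.choice(pool, 50, replace=False))
        foxp3 = set(rng.choice(pool, 40, replace=False))
        treg = set(rng.choice(pool, 30, replace=False))
        known = set(rng.choice(pool, 15, replace=False))
        table = build_candidates(
            gs("m", membrane), gs("f", foxp3), gs("t", treg), gs("k", known)
        )
        frame = table.frame
        expect_f = {g for g in pool if g in membrane and g in foxp3 and g not in known}
        expect_t = {g for g in pool if g in membrane and g in treg and g not in known}
        assert set(frame.loc[frame["branch"] == "FOXP3_UP", "gene"]) == expect_f
        assert set(frame.loc[frame["branch"] == "TREG_SPECIFIC", "gene"]) == expect_t


def random_instance(rng, n_genes=20, n_datasets=4, measured_frac=0.8):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    table = build_candidates(
        gs("m", genes), gs("f", genes[: n_genes // 2]), gs("t", genes[n_genes // 2 :]), gs("k", [])
    )
    datasets = []
    for d in range(n_datasets):
        rows = {}
        for g in genes:
            if rng.random() < measured_frac:
                rows[g] = (float(rng.normal()), float(rng.random()))
        datasets.append(make_de(rows, dataset_id=f"D{d}", target=f"T{d % 2}"))
    return genes, table, datasets


class TestDownCallMatrix:
    def test_counts_match_naive_recount(self):
        rng = np.random.default_rng(11)
        genes, table, datasets = random_instance(rng)
        matrix = build_downcall_matrix(table, datasets, CFG)
        for ds in datasets:
            naive = sum(
                1
                for g in genes
                if ds.lookup(g) is not None
                and ds.lookup(g)[1] < CFG.alpha
                and ds.lookup(g)[0] < CFG.lfc_down
            )
            col = matrix.calls[ds.dataset_id]
            assert int((col == DOWN).sum()) == naive
            unmeasured = {g for g in genes if ds.lookup(g) is None}
            assert set(col.index[col == NOT_MEASURED]) == unmeasured

    def test_all_null_pvalues_give_no_down(self):
        genes = ["G1", "G2", "G3"]
        table = build_candidates(gs("m", genes), gs("f", genes), gs("t", []), gs("k", []))
        ds = make_de({g: (-2.0, 1.0) for g in genes}, dataset_id="D0")
        matrix = build_downcall_matrix(table, [ds], CFG)
        assert (matrix.calls["D0"] == NOT_DOWN).all()

    def test_zero_overlap_warns_and_keeps_column(self):
        table = build_candidates(gs("m", ["G1"]), gs("f", ["G1"]), gs("t", []), gs("k", []))
        ds = make_de({"OTHER": (-2.0, 0.01)}, dataset_id="D0")
        matrix = build_downcall_matrix(table, [ds], CFG)
        assert (matrix.calls["D0"] == NOT_MEASURED).all()
        assert any(w["kind"] == "no_overlap" for w in matrix.warnings)

    def test_duplicate_dataset_id_rejected(self):
        table = build_candidates(gs("m", ["G1"]), gs("f", ["G1"]), gs("t", []), gs("k", []))
        ds = make_de({"G1": (-2.0, 0.01)}, dataset_id="D0")
        with pytest.raises(DataError):
            build_downcall_matrix(table, [ds, ds], CFG)


class TestRound2:
    def test_survivors_match_naive_any_scan(self):
        rng = np.random.default_rng(13)
        genes, table, datasets = random_instance(rng)
        matrix = build_downcall_matrix(table, datasets, CFG)
        result = round2_filter(matrix)
        naive = {
            g
            for g in genes
            if any(
                ds.lookup(g) is not None
                and ds.lookup(g)[1] < CFG.alpha
                and ds.lookup(g)[0] < CFG.lfc_down
                for ds in datasets
            )
        }
        assert set(result.genes("round2")) == naive

    def test_all_not_down_gives_zero_survivors(self):
        genes = ["G1", "G2"]
        table = build_candidates(gs("m", genes), gs("f", genes), gs("t", []), gs("k", []))
        ds = make_de({g: (0.5, 0.9) for g in genes}, dataset_id="D0")
        matrix = build_downcall_matrix(table, [ds], CFG)
        assert round2_filter(matrix).genes("round2") == []


def panel_dataset(n_down, target="CTLA4", include_self=False, dataset_id="KO"):
    """25-gene panel dataset with n_down planted down-calls (self optionally planted)."""
    panel = [f"IC{i:02d}" for i in range(24)] + [target]
    rows = {}
    planted = [g for g in panel if g != target][:n_down]
    if include_self:
        planted = planted + [target]
    for g in panel:
        rows[g] = (-1.0, 0.01) if g in planted else (0.3, 0.8)
    return make_de(rows, dataset_id=dataset_id, target=target), gs("panel", panel)


class TestHierarchy:
    @pytest.mark.parametrize("n_down, percent, high", [(6, 24, True), (8, 32, True), (7, 28, True), (0, 0, False)])
    def test_score_and_class(self, n_down, percent, high):
        ds, panel = panel_dataset(n_down)
        entry = hierarchy_score(ds, panel, CFG)
        assert entry.n_down == n_down and entry.n_panel == 25
        assert entry.score_percent == percent
        assert entry.high is high

    def test_exactly_20_percent_is_low(self):
        ds, panel = panel_dataset(5)
        entry = hierarchy_score(ds, panel, CFG)
        assert math.isclose(entry.fraction, 0.20) and not entry.high

    def test_self_excluded_from_own_panel_count(self):
        ds, panel = panel_dataset(6, include_self=True)
        assert hierarchy_score(ds, panel, CFG).n_down == 6

    def test_invariant_to_orderings(self):
        ds, panel = panel_dataset(6)
        shuffled = GeneSet.from_iterable("p2", "human", reversed(panel.sorted_members()))
        resorted = make_de(
            {g: (float(r["log2fc"]), float(r["pvalue"])) for g, r in ds.data.iloc[::-1].iterrows()},
            dataset_id="KO",
        )
        assert hierarchy_score(ds, shuffled, CFG) == hierarchy_score(resorted, panel, CFG)

    def test_empty_panel_rejected(self):
        ds, _ = panel_dataset(6)
        with pytest.raises(DataError):
            hierarchy_score(ds, gs("empty", []), CFG)

    def test_classify_both_aggregation_modes(self):
        high_ds, panel = panel_dataset(6, target="CTLA4", dataset_id="KO1")
        low_ds, _ = panel_dataset(3, target="CTLA4", dataset_id="KO2")
        other_low, _ = panel_dataset(2, target="CD47", dataset_id="KO3")
        entries = [hierarchy_score(d, panel, CFG) for d in (high_ds, low_ds, other_low)]
        for mode in ("any", "max"):
            part = classify_targets(entries, aggregation=mode)
            assert part.high == frozenset({"CTLA4"})
            assert part.low == frozenset({"CD47"})

    def test_reference_screen_partition(self, fixture_report):
        table = fixture_report.hierarchy
        scores = dict(zip(table["dataset_id"], table["score_percent"]))
        assert scores["CTLA4_KO_1"] == 24 and scores["PDCD1_KO_1"] == 28
        assert scores["TIGIT_KO_1"] == scores["KLRG1_KO"] == scores["LAG3_KO"] == 32
        assert len(fixture_report.high_targets) == 5


def tiny_matrix(pattern, k=3, n=5):
    """One candidate down under the targets flagged in `pattern` (length n)."""
    targets = [f"T{i}" for i in range(n)]
    genes = ["CAND"]
    table = build_candidates(gs("m", genes), gs("f", genes), gs("t", []), gs("k", []))
    datasets = [
        make_de(
            {"CAND": (-1.0, 0.01) if bit else (0.2, 0.9)},
            dataset_id=f"D{i}",
            target=targets[i],
        )
        for i, bit in enumerate(pattern)
    ]
    matrix = build_downcall_matrix(table, datasets, CFG)
    matrix.candidates = round2_filter(matrix)
    return matrix, targets


class TestRound3:
    def test_exhaustive_support_patterns(self):
        for pattern in itertools.product([0, 1], repeat=5):
            matrix, targets = tiny_matrix(pattern)
            result = round3_filter(matrix, targets, CFG)
            expected = sum(pattern) >= CFG.stringency_k and sum(pattern) >= 1
            assert (result.genes("round3") == ["CAND"]) is expected, pattern

    def test_k_minus_one_fails(self):
        matrix, targets = tiny_matrix([1, 1, 0, 0, 0])
        assert round3_filter(matrix, targets, CFG).genes("round3") == []

    def test_distinct_targets_not_datasets(self):
        genes = ["CAND"]
        table = build_candidates(gs("m", genes), gs("f", genes), gs("t", []), gs("k", []))
        datasets = [
            make_de({"CAND": (-1.0, 0.01)}, dataset_id=f"D{i}", target="T0")
            for i in range(3)
        ] + [
            make_de({"CAND": (0.2, 0.9)}, dataset_id=f"D{i+3}", target=t)
            for i, t in enumerate(["T1", "T2", "T3", "T4"])
        ]
        matrix = build_downcall_matrix(table, datasets, CFG)
        matrix.candidates = round2_filter(matrix)
        targets = ["T0", "T1", "T2", "T3", "T4"]
        assert round3_filter(matrix, targets, CFG).genes("round3") == []
        per_dataset = round3_filter(matrix, targets, CFG, counting="datasets")
        assert per_dataset.genes("round3") == ["CAND"]

    def test_wrong_target_count_rejected_unless_overridden(self):
        matrix, targets = tiny_matrix([1, 1, 1, 0, 0])
        with pytest.raises(DataError):
            round3_filter(matrix, targets[:4], CFG)
        result = round3_filter(matrix, targets[:4], CFG, allow_n_mismatch=True)
        assert result.genes("round3") == ["CAND"]

    def test_requires_round2_flags(self):
        matrix, targets = tiny_matrix([1, 1, 1, 0, 0])
        matrix.candidates.frame["round2_pass"] = pd.array(
            [pd.NA] * len(matrix.candidates.frame), dtype="boolean"
        )
        with pytest.raises(DataError, match="round-2"):
            round3_filter(matrix, targets, CFG)


class TestMonotonicity:
    def test_nesting_and_threshold_monotonicity(self):
        rng = np.random.default_rng(17)
        genes, table, datasets = random_instance(rng, n_genes=40, n_datasets=6)
        matrix = build_downcall_matrix(table, datasets, CFG)
        r2 = round2_filter(matrix)
        matrix.candidates = r2
        targets = sorted({d.perturbed_target for d in datasets})
        loose = ScreenConfig(stringency_k=1, stringency_n=len(targets))
        tight = ScreenConfig(stringency_k=2, stringency_n=len(targets))
        fin_tight = set(round3_filter(matrix, targets, tight).genes("round3"))
        fin_loose = set(round3_filter(matrix, targets, loose).genes("round3"))
        # finalists ⊆ round-2 survivors ⊆ round-1 candidates
        assert fin_tight <= fin_loose <= set(r2.genes("round2")) <= set(r2.genes("round1"))

        # raising alpha never shrinks any DOWN set
        wide = ScreenConfig(alpha=0.25)
        m_narrow = build_downcall_matrix(table, datasets, CFG)
        m_wide = build_downcall_matrix(table, datasets, wide)
        assert ((m_narrow.calls == DOWN) <= (m_wide.calls == DOWN)).all().all()
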
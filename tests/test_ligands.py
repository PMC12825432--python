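"""Three-round ligand triage: membrane, APC attribution, tolerogenic, dedup."""

import numpy as np
import pytest

from icscreen import (
    DataError,
    GeneSet,
    InteractionTable,
    LigandRecord,
    ScreenConfig,
    dedup_union,
    filter_apc,
    filter_membrane,
    filter_tolerogenic,
    run_triage,
    triage_receptor,
)
from conftest import make_de

CFG = ScreenConfig()


def gs(name, members, species="human"):
    return GeneSet.from_iterable(name, species, members)


class TestFilterMembrane:
    def test_subset_is_identity(self):
        partners = gs("p", ["L1", "L2"])
        membrane = gs("m", ["L1", "L2", "L3"])
        assert filter_membrane(partners, membrane).members == partners.members

    def test_species_mismatch_rejected(self):
        with pytest.raises(DataError):
            filter_membrane(gs("p", ["L1"]), gs("m", ["L1"], species="mouse"))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pool = [f"L{i:03d}" for i in range(80)]
        partners = set(rng.choice(pool, 30, replace=False))
        membrane = set(rng.choice(pool, 40, replace=False))
        out = filter_membrane(gs("p", partners), gs("m", membrane))
        assert out.members == {g for g in partners if g in membrane}


class TestFilterApc:
    def test_multi_type_attribution(self):
        markers = {
            "B_cell": gs("b", ["L1", "L2"]),
            "dendritic_cell": gs("dc", ["L2", "L3"]),
        }
        out = filter_apc(gs("c", ["L1", "L2", "L9"]), markers)
        assert out == {
            "L1": frozenset({"B_cell"}),
            "L2": frozenset({"B_cell", "dendritic_cell"}),
        }

    def test_requires_marker_sets(self):
        with pytest.raises(DataError):
            filter_apc(gs("c", ["L1"]), {})

    def test_attribution_matches_naive_membership(self):
        rng = np.random.default_rng(5)
        pool = [f"L{i:03d}" for i in range(60)]
        markers = {
            t: gs(t, set(rng.choice(pool, 20, replace=False)))
            for t in ("macrophage", "monocyte", "B_cell", "dendritic_cell")
        }
        cands = gs("c", set(rng.choice(pool, 30, replace=False)))
        out = filter_apc(cands, markers)
        for g in cands.members:
            expected = frozenset(t for t in markers if g in markers[t].members)
            assert out.get(g, frozenset()) == expected


class TestFilterTolerogenic:
    def test_up_call_passes_with_support(self):
        attributed = {"L1": frozenset({"B_cell"})}
        ds = make_de({"L1": (2.0, 0.001)}, dataset_id="M2")
        records = filter_tolerogenic(attributed, "R1", [ds], CFG)
        assert len(records) == 1
        assert records[0].tolerogenic_support == frozenset({"M2"})

    def test_down_or_insignificant_fails(self):
        attributed = {"L1": frozenset({"B_cell"}), "L2": frozenset({"B_cell"})}
        ds = make_de({"L1": (-2.0, 0.001), "L2": (2.0, 0.5)}, dataset_id="M2")
        assert filter_tolerogenic(attributed, "R1", [ds], CFG) == []

    def test_self_partner_flagged(self):
        attributed = {"R1": frozenset({"B_cell"})}
        ds = make_de({"R1": (2.0, 0.001)}, dataset_id="M2")
        (rec,) = filter_tolerogenic(attributed, "R1", [ds], CFG)
        assert rec.self_partner

    def test_pass_set_matches_naive_scan(self):
        rng = np.random.default_rng(9)
        pool = [f"L{i:03d}" for i in range(40)]
        attributed = {g: frozenset({"B_cell"}) for g in pool}
        rows = {g: (float(rng.normal()), float(rng.random())) for g in pool}
        ds = make_de(rows, dataset_id="M2")
        got = {r.ligand for r in filter_tolerogenic(attributed, "R1", [ds], CFG)}
        naive = {g for g, (lfc, p) in rows.items() if p < CFG.alpha and lfc > 0}
        assert got == naive


class TestLigandRecordInvariants:
    def test_support_round_consistency_enforced(self):
        with pytest.raises(DataError):
            LigandRecord(
                ligand="L1",
                receptors=frozenset({"R1"}),
                apc_types=frozenset({"B_cell"}),
                tolerogenic_support=frozenset(),
                rounds_passed=frozenset({"membrane", "apc", "tolerogenic"}),
            )
        with pytest.raises(DataError):
            LigandRecord(
                ligand="L1",
                receptors=frozenset({"R1"}),
                apc_types=frozenset(),
                tolerogenic_support=frozenset({"M2"}),
                rounds_passed=frozenset({"membrane", "apc", "tolerogenic"}),
            )


def _rec(ligand, receptor, support=("M2",)):
    return LigandRecord(
        ligand=ligand,
        receptors=frozenset({receptor}),
        apc_types=frozenset({"B_cell"}),
        tolerogenic_support=frozenset(support),
        rounds_passed=frozenset({"membrane", "apc", "tolerogenic"}),
    )


class TestDedupUnion:
    def test_disjoint_lists_sum(self):
        per = {"R1": [_rec("L1", "R1"), _rec("L2", "R1")], "R2": [_rec("L3", "R2")]}
        assert len(dedup_union(per)) == 3

    def test_shared_ligand_merges_receptors(self):
        per = {"R1": [_rec("L1", "R1")], "R2": [_rec("L1", "R2", support=("PDC",))]}
        (merged,) = dedup_union(per)
        assert merged.receptors == frozenset({"R1", "R2"})
        assert merged.tolerogenic_support == frozenset({"M2", "PDC"})

    def test_union_size_matches_naive(self):
        rng = np.random.default_rng(21)
        pool = [f"L{i:02d}" for i in range(30)]
        per = {
            f"R{r}": [_rec(g, f"R{r}") for g in rng.choice(pool, 10, replace=False)]
            for r in range(4)
        }
        assert len(dedup_union(per)) == len({rec.ligand for recs in per.values() for rec in recs})


class TestTriageProperties:
    def test_membrane_and_apc_commute(self):
        rng = np.random.default_rng(23)
        pool = [f"L{i:03d}" for i in range(80)]
        partners = gs("p", set(rng.choice(pool, 40, replace=False)))
        membrane = gs("m", set(rng.choice(pool, 40, replace=False)))
        markers = {"B_cell": gs("b", set(rng.choice(pool, 40, replace=False)))}
        mem_then_apc = set(filter_apc(filter_membrane(partners, membrane), markers))
        apc_then_mem = set(
            filter_membrane(gs("a", filter_apc(partners, markers)), membrane).members
        )
        assert mem_then_apc == apc_then_mem

    def test_every_output_ligand_fully_supported(self, fixture_report):
        frame = fixture_report.ligands
        assert (frame["receptors"].str.len() > 0).all()
        assert (frame["apc_types"].str.len() > 0).all()
        assert (frame["tolerogenic_support"].str.len() > 0).all()

    def test_removing_tolerogenic_dataset_never_grows_result(self):
        attributed = {"L1": frozenset({"B_cell"}), "L2": frozenset({"B_cell"})}
        ds1 = make_de({"L1": (2.0, 0.001)}, dataset_id="M2")
        ds2 = make_de({"L2": (2.0, 0.001)}, dataset_id="PDC")
        full = {r.ligand for r in filter_tolerogenic(attributed, "R1", [ds1, ds2], CFG)}
        reduced = {r.ligand for r in filter_tolerogenic(attributed, "R1", [ds1], CFG)}
        assert reduced <= full

    def test_triage_receptor_counts_are_chained(self):
        partners = gs("p", ["L1", "L2", "L3", "L4"])
        membrane = gs("m", ["L1", "L2", "L3"])
        markers = {"B_cell": gs("b", ["L1", "L2"])}
        ds = make_de({"L1": (2.0, 0.001), "L2": (0.1, 0.9)}, dataset_id="M2")
        records, counts = triage_receptor("R1", partners, membrane, markers, [ds], CFG)
        assert counts == {"partners": 4, "membrane": 3, "apc": 2, "final": 1}
        assert records[0].ligand == "L1"

    def test_run_triage_warns_on_empty_receptor(self):
        interactions = InteractionTable.from_pairs([("R1", "L9")])
        membrane = gs("m", ["L1"])
        markers = {"B_cell": gs("b", ["L1"])}
        ds = make_de({"L1": (2.0, 0.001)}, dataset_id="M2")
        result = run_triage(interactions, ["R1"], membrane, markers, [ds], CFG)
        assert result.n_distinct == 0
        assert any(w["kind"] == "no_ligand" for w in result.warnings)
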
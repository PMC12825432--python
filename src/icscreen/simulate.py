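"""Seeded generator of complete pipeline inputs with planted structure.

The generator emulates the statistical shape of the screen's real-world
inputs — a gene universe with membrane and cell-type annotations,
knockout differential-expression tables with planted down-calls, an
interaction network with planted membrane/APC/tolerogenic ligands — not
realistic expression magnitudes.  Every planted count in a
:class:`FixtureSpec` is recovered exactly by construction: planted genes
draw p strictly below alpha with the planted sign, genes the screen
looks at but that are not planted ("guarded" genes: candidates, panel
members, triage survivors) draw p uniformly on [alpha, 1) so they can
never be called, and true background genes draw from the exchangeable
null (p uniform on [0, 1], log2FC zero-centred normal), which is what
gives the expected alpha-level false-call rate on background.

The shipped reference-screen spec (``data/reference_screen.yaml``) plants every
headline count of the screen this package models, so the whole published
arithmetic becomes a regression surface.  Its reference panel and
knockout-target names use real checkpoint gene symbols purely as a
synthetic stand-in panel; candidate and ligand symbols are synthetic
GENE##### tokens.
"""

from __future__ import annotations

import functools
import json
import zlib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DataError, DifferentialTable, GeneSet
from .ligands import InteractionTable

__all__ = [
    "KOPlan",
    "ReceptorPlan",
    "SharedLigandPlan",
    "TolerogenicPlan",
    "ModulationPlan",
    "FixtureSpec",
    "reference_screen_spec",
    "reference_recorded_counts",
    "simulate_universe",
    "simulate_de_dataset",
    "simulate_tolerogenic_dataset",
    "simulate_modulation_dataset",
    "simulate_interactions",
    "simulate_expression_matrix",
    "reference_expression_means",
    "write_fixture",
]


@dataclass(frozen=True)
class KOPlan:
    """Down-call plan for one knockout/blockade dataset.

    ``candidate_down`` non-finalist round-2 survivors, starting at
    ``candidate_offset`` in the rotation of survivors (wrapping), are
    planted DOWN; ``include_finalists`` additionally plants every
    finalist.  ``panel_down`` reference-panel genes (excluding the
    perturbed target itself) are planted DOWN, which fixes the dataset's
    hierarchy score.  ``scoring`` marks membership in the hierarchy
    scoring panel.
    """

    dataset_id: str
    target: str
    panel_down: int = 0
    candidate_down: int = 0
    candidate_offset: int = 0
    include_finalists: bool = False
    scoring: bool = True


@dataclass(frozen=True)
class ReceptorPlan:
    """Ligand-triage plan for one finalist receptor.

    ``role`` addresses the finalist by branch and ordinal ("TREG_0",
    "FOXP3_3", ...) since finalist symbols are only fixed at layout time.
    ``n_membrane`` partners carry membrane annotation (all of them also
    carry APC markers, so the chained triage is monotone);
    ``n_apc_only`` partners carry APC markers without membrane
    annotation (they raise the standalone APC count above the chained
    one); ``n_final`` membrane partners are additionally up-called in the
    plan's tolerogenic dataset(s).
    """

    role: str
    n_partners: int
    n_membrane: int
    n_apc_only: int
    n_final: int
    apc_types: tuple = ("B_cell",)
    tolerogenic: tuple = ("B1_BCELL",)
    self_partner: bool = False


@dataclass(frozen=True)
class SharedLigandPlan:
    """n final ligands shared verbatim between two receptors' lists."""

    role_a: str
    role_b: str
    n: int


@dataclass(frozen=True)
class TolerogenicPlan:
    dataset_id: str
    comparison: str = ""


@dataclass(frozen=True)
class ModulationPlan:
    """A perturbation dataset in which part of the final ligand panel is altered."""

    dataset_id: str
    target_label: str
    n_up: int
    n_down: int


@dataclass(frozen=True)
class FixtureSpec:
    """Complete, validated description of a synthetic screening instance."""

    universe_size: int
    membrane_size: int
    foxp3_up_size: int
    treg_specific_size: int
    membrane_foxp3_overlap: int
    membrane_treg_overlap: int
    known_ic_foxp3: int
    known_ic_treg: int
    survivors_treg: int
    survivors_foxp3: int
    finalists_treg: int
    finalists_foxp3: int
    reference_panel: tuple
    ko_plans: tuple
    receptor_plans: tuple = ()
    shared_ligands: tuple = ()
    tolerogenic_plans: tuple = ()
    modulation_plans: tuple = ()
    apc_marker_sizes: tuple = ()  # ((type, size), ...)
    background_size: int = 2000
    alpha: float = 0.05
    noise_log2fc_sd: float = 1.0
    species: str = "human"

    # ---- derived sizes -------------------------------------------------
    @property
    def foxp3_branch_size(self) -> int:
        return self.membrane_foxp3_overlap - self.known_ic_foxp3

    @property
    def treg_branch_size(self) -> int:
        return self.membrane_treg_overlap - self.known_ic_treg

    @property
    def n_candidates(self) -> int:
        return self.foxp3_branch_size + self.treg_branch_size

    @property
    def n_survivors(self) -> int:
        return self.survivors_treg + self.survivors_foxp3

    @property
    def n_finalists(self) -> int:
        return self.finalists_treg + self.finalists_foxp3

    @property
    def n_nonfinal_survivors(self) -> int:
        return self.n_survivors - self.n_finalists

    def __post_init__(self):
        def require(cond, msg):
            if not cond:
                raise DataError(f"infeasible fixture spec: {msg}")

        require(self.membrane_size <= self.universe_size, "membrane larger than universe")
        require(
            self.membrane_foxp3_overlap <= min(self.membrane_size, self.foxp3_up_size),
            "membrane/foxp3 overlap exceeds a parent set size",
        )
        require(
            self.membrane_treg_overlap <= min(self.membrane_size, self.treg_specific_size),
            "membrane/treg overlap exceeds a parent set size",
        )
        require(
            self.membrane_foxp3_overlap + self.membrane_treg_overlap <= self.membrane_size,
            "branch overlaps exceed the membrane set",
        )
        require(self.known_ic_foxp3 <= self.membrane_foxp3_overlap, "known-IC removals exceed foxp3 overlap")
        require(self.known_ic_treg <= self.membrane_treg_overlap, "known-IC removals exceed treg overlap")
        require(self.survivors_foxp3 <= self.foxp3_branch_size, "foxp3 survivors exceed branch size")
        require(self.survivors_treg <= self.treg_branch_size, "treg survivors exceed branch size")
        require(self.finalists_foxp3 <= self.survivors_foxp3, "foxp3 finalists exceed survivors")
        require(self.finalists_treg <= self.survivors_treg, "treg finalists exceed survivors")
        require(len(set(self.reference_panel)) == len(self.reference_panel), "duplicate panel symbols")
        require(0 < self.alpha < 1, "alpha outside (0,1)")

        ids = [p.dataset_id for p in self.ko_plans]
        require(len(set(ids)) == len(ids), "duplicate KO dataset_id")
        n_nonfinal = self.n_nonfinal_survivors
        covered = set()
        finalists_planted = False
        for plan in self.ko_plans:
            require(
                plan.candidate_down <= max(n_nonfinal, 0),
                f"{plan.dataset_id}: candidate_down exceeds non-finalist survivors",
            )
            panel_cap = len(self.reference_panel) - (1 if plan.target in self.reference_panel else 0)
            require(
                plan.panel_down <= panel_cap,
                f"{plan.dataset_id}: panel_down exceeds panel size after self-exclusion",
            )
            if n_nonfinal > 0:
                covered.update(
                    (plan.candidate_offset + j) % n_nonfinal for j in range(plan.candidate_down)
                )
            finalists_planted = finalists_planted or plan.include_finalists
        if self.ko_plans:
            require(
                len(covered) == n_nonfinal,
                "a non-finalist survivor has no planted down-call in any dataset",
            )
            require(
                finalists_planted or self.n_finalists == 0,
                "finalists exist but no dataset plants them",
            )

        roles = [p.role for p in self.receptor_plans]
        require(len(set(roles)) == len(roles), "duplicate receptor role")
        shared_per_role: dict = {}
        for s in self.shared_ligands:
            require(s.role_a in roles and s.role_b in roles, f"shared plan names unknown role {s.role_a}/{s.role_b}")
            require(s.role_a != s.role_b, "shared plan pairs a role with itself")
            shared_per_role[s.role_a] = shared_per_role.get(s.role_a, 0) + s.n
            shared_per_role[s.role_b] = shared_per_role.get(s.role_b, 0) + s.n
        tol_ids = {t.dataset_id for t in self.tolerogenic_plans}
        for plan in self.receptor_plans:
            branch, _, idx = plan.role.partition("_")
            require(branch in ("TREG", "FOXP3") and idx.isdigit(), f"bad role {plan.role!r}")
            cap = self.finalists_treg if branch == "TREG" else self.finalists_foxp3
            require(int(idx) < cap, f"role {plan.role!r} has no finalist")
            require(plan.n_final <= plan.n_membrane, f"{plan.role}: n_final exceeds n_membrane")
            require(
                plan.n_membrane + plan.n_apc_only <= plan.n_partners,
                f"{plan.role}: membrane + apc_only exceed partner count",
            )
            own = shared_per_role.get(plan.role, 0) + (1 if plan.self_partner else 0)
            require(own <= plan.n_final, f"{plan.role}: shared/self ligands exceed n_final")
            for t in plan.tolerogenic:
                require(t in tol_ids, f"{plan.role}: unknown tolerogenic dataset {t!r}")
            for t in plan.apc_types:
                require(
                    t in dict(self.apc_marker_sizes),
                    f"{plan.role}: APC type {t!r} has no marker set",
                )
        # capacity check happens in the layout (it knows every block size)
        _layout(self)


def _sym(i: int) -> str:
    return f"GENE{i:05d}"


@functools.lru_cache(maxsize=8)
def _layout(spec: FixtureSpec) -> dict:
    """Deterministic assignment of every planted role to concrete symbols.

    Pure function of the spec; the seed only enters when noise is drawn.
    """
    mfo, mto = spec.membrane_foxp3_overlap, spec.membrane_treg_overlap

    foxp3_overlap = [_sym(i) for i in range(mfo)]
    treg_overlap = [_sym(i) for i in range(mfo, mfo + mto)]
    known_f = foxp3_overlap[: spec.known_ic_foxp3]
    known_t = treg_overlap[: spec.known_ic_treg]
    foxp3_branch = foxp3_overlap[spec.known_ic_foxp3 :]
    treg_branch = treg_overlap[spec.known_ic_treg :]

    treg_surv = treg_branch[: spec.survivors_treg]
    foxp3_surv = foxp3_branch[: spec.survivors_foxp3]
    treg_fin = treg_surv[: spec.finalists_treg]
    foxp3_fin = foxp3_surv[: spec.finalists_foxp3]
    nonfinal_surv = treg_surv[spec.finalists_treg :] + foxp3_surv[spec.finalists_foxp3 :]
    role_symbol = {f"TREG_{i}": g for i, g in enumerate(treg_fin)}
    role_symbol.update({f"FOXP3_{i}": g for i, g in enumerate(foxp3_fin)})

    mem_cursor = mfo + mto

    def take_membrane(n):
        nonlocal mem_cursor
        if mem_cursor + n > spec.membrane_size:
            raise DataError("infeasible fixture spec: membrane set too small for ligand blocks")
        block = [_sym(i) for i in range(mem_cursor, mem_cursor + n)]
        mem_cursor += n
        return block

    # --- ligand finals ---------------------------------------------------
    final_sets: dict = {p.role: [] for p in spec.receptor_plans}
    for s in spec.shared_ligands:
        block = take_membrane(s.n)
        final_sets[s.role_a].extend(block)
        final_sets[s.role_b].extend(block)
    plans_by_role = {p.role: p for p in spec.receptor_plans}
    for role, plan in plans_by_role.items():
        if plan.self_partner:
            final_sets[role].append(role_symbol[role])
        n_unique = plan.n_final - len(final_sets[role])
        final_sets[role].extend(take_membrane(n_unique))

    extras = {
        role: take_membrane(plan.n_membrane - plan.n_final)
        for role, plan in plans_by_role.items()
    }

    cursor = spec.membrane_size

    def take_universe(n, what):
        nonlocal cursor
        if cursor + n > spec.universe_size:
            raise DataError(f"infeasible fixture spec: universe too small for {what}")
        block = [_sym(i) for i in range(cursor, cursor + n)]
        cursor += n
        return block

    foxp3_tail = take_universe(spec.foxp3_up_size - mfo, "foxp3 tail")
    treg_tail = take_universe(spec.treg_specific_size - mto, "treg tail")
    apc_only = {
        role: take_universe(plan.n_apc_only, "apc-only partners")
        for role, plan in plans_by_role.items()
    }
    fillers = {
        role: take_universe(
            plan.n_partners - plan.n_membrane - plan.n_apc_only, "partner fillers"
        )
        for role, plan in plans_by_role.items()
    }
    background = take_universe(spec.background_size, "background block")
    marker_fill_region = [_sym(i) for i in range(cursor, spec.universe_size)]

    # --- APC marker sets --------------------------------------------------
    marker_sets: dict = {t: set() for t, _ in spec.apc_marker_sizes}
    for role, plan in plans_by_role.items():
        for t in plan.apc_types:
            marker_sets[t].update(final_sets[role])
            marker_sets[t].update(extras[role])
            marker_sets[t].update(apc_only[role])
    for t, size in spec.apc_marker_sizes:
        need = size - len(marker_sets[t])
        if need < 0:
            raise DataError(
                f"infeasible fixture spec: APC marker set {t!r} smaller than its planted members"
            )
        if need > len(marker_fill_region):
            raise DataError(
                f"infeasible fixture spec: universe too small to fill APC marker set {t!r}"
            )
        marker_sets[t].update(marker_fill_region[:need])

    membrane = [_sym(i) for i in range(spec.membrane_size)]
    partners = {
        role: sorted(final_sets[role] + extras[role] + apc_only[role] + fillers[role])
        for role in plans_by_role
    }
    final_distinct = sorted({g for fs in final_sets.values() for g in fs})

    return {
        "membrane": membrane,
        "foxp3_up": foxp3_overlap + foxp3_tail,
        "treg_specific": treg_overlap + treg_tail,
        "known_ics": known_f + known_t,
        "foxp3_branch": foxp3_branch,
        "treg_branch": treg_branch,
        "treg_survivors": treg_surv,
        "foxp3_survivors": foxp3_surv,
        "finalists": treg_fin + foxp3_fin,
        "role_symbol": role_symbol,
        "nonfinal_survivors": nonfinal_surv,
        "final_sets": final_sets,
        "final_distinct": final_distinct,
        "extras": extras,
        "apc_only": apc_only,
        "partners": partners,
        "background": background,
        "marker_sets": {t: sorted(s) for t, s in marker_sets.items()},
    }


def simulate_universe(spec: FixtureSpec) -> dict:
    """The input gene sets: membrane universe, signatures, exclusion list, panel."""
    lay = _layout(spec)
    sp = spec.species
    mk = lambda name, members: GeneSet.from_iterable(name, sp, members, provenance="synthetic fixture")
    out = {
        "membrane": mk("membrane", lay["membrane"]),
        "foxp3_up": mk("foxp3_up", lay["foxp3_up"]),
        "treg_specific": mk("treg_specific", lay["treg_specific"]),
        "known_ics": mk("known_ics", lay["known_ics"]),
        "reference_panel": mk("reference_panel", spec.reference_panel),
    }
    return out


def _rng(seed: int, dataset_id: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(dataset_id.encode())])


def _fill_noise(rng, genes, alpha, sd, guarded):
    """p/log2fc draws: guarded genes can never reach p < alpha."""
    n = len(genes)
    if guarded:
        p = rng.uniform(alpha, 1.0, size=n)
    else:
        p = rng.uniform(0.0, 1.0, size=n)
    lfc = rng.normal(0.0, sd, size=n)
    return p, lfc


def _planted_rows(rng, genes, alpha, sign):
    n = len(genes)
    p = rng.uniform(alpha * 0.01, alpha * 0.99, size=n)
    lfc = sign * rng.uniform(0.5, 2.5, size=n)
    return p, lfc


def _assemble_table(spec, dataset_id, target, comparison, planted_down, planted_up, guarded, seed):
    """Build one DifferentialTable: planted rows, guarded rows, free background."""
    rng = _rng(seed, dataset_id)
    lay = _layout(spec)
    rows = []
    pd_down, lfc_down = _planted_rows(rng, planted_down, spec.alpha, -1.0)
    rows += list(zip(planted_down, lfc_down, pd_down))
    pu, lfc_up = _planted_rows(rng, planted_up, spec.alpha, +1.0)
    rows += list(zip(planted_up, lfc_up, pu))
    pg, lg = _fill_noise(rng, guarded, spec.alpha, spec.noise_log2fc_sd, guarded=True)
    rows += list(zip(guarded, lg, pg))
    pb, lb = _fill_noise(rng, lay["background"], spec.alpha, spec.noise_log2fc_sd, guarded=False)
    rows += list(zip(lay["background"], lb, pb))
    frame = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"])
    return DifferentialTable.from_frame(
        frame,
        dataset_id=dataset_id,
        perturbed_target=target,
        species=spec.species,
        comparison=comparison,
    )


def simulate_de_dataset(spec: FixtureSpec, dataset_id: str, seed: int) -> DifferentialTable:
    """One knockout dataset per its :class:`KOPlan`.

    Rows cover every candidate, every reference-panel gene, and the
    background block.  Planted genes satisfy p < alpha strictly with
    negative log2FC; unplanted candidates and panel genes are guarded.
    """
    plans = {p.dataset_id: p for p in spec.ko_plans}
    if dataset_id not in plans:
        raise DataError(f"unknown KO dataset_id {dataset_id!r}")
    plan = plans[dataset_id]
    lay = _layout(spec)

    planted = []
    nonfinal = lay["nonfinal_survivors"]
    if nonfinal and plan.candidate_down:
        planted += [
            nonfinal[(plan.candidate_offset + j) % len(nonfinal)]
            for j in range(plan.candidate_down)
        ]
    if plan.include_finalists:
        planted += lay["finalists"]
    panel_planted = [g for g in spec.reference_panel if g != plan.target][: plan.panel_down]
    planted_down = sorted(set(planted)) + panel_planted

    candidates = lay["treg_branch"] + lay["foxp3_branch"]
    guarded = sorted(
        (set(candidates) | set(spec.reference_panel)) - set(planted_down)
    )
    return _assemble_table(
        spec,
        dataset_id,
        plan.target,
        f"{plan.target} deficiency vs control",
        planted_down,
        [],
        guarded,
        seed,
    )


def simulate_tolerogenic_dataset(spec: FixtureSpec, dataset_id: str, seed: int) -> DifferentialTable:
    """One tolerogenic-APC-subset dataset with planted ligand up-calls."""
    if dataset_id not in {t.dataset_id for t in spec.tolerogenic_plans}:
        raise DataError(f"unknown tolerogenic dataset_id {dataset_id!r}")
    lay = _layout(spec)
    planted_up = set()
    survivors = set()
    for plan in spec.receptor_plans:
        survivors.update(lay["final_sets"][plan.role])
        survivors.update(lay["extras"][plan.role])
        if dataset_id in plan.tolerogenic:
            planted_up.update(lay["final_sets"][plan.role])
    guarded = sorted(survivors - planted_up)
    comparison = next(
        (t.comparison for t in spec.tolerogenic_plans if t.dataset_id == dataset_id), ""
    )
    return _assemble_table(
        spec, dataset_id, f"{dataset_id}_SUBSET", comparison, [], sorted(planted_up), guarded, seed
    )


def simulate_modulation_dataset(spec: FixtureSpec, dataset_id: str, seed: int) -> DifferentialTable:
    """A perturbation dataset altering part of the final ligand panel."""
    plans = {p.dataset_id: p for p in spec.modulation_plans}
    if dataset_id not in plans:
        raise DataError(f"unknown modulation dataset_id {dataset_id!r}")
    plan = plans[dataset_id]
    finals = _layout(spec)["final_distinct"]
    if plan.n_up + plan.n_down > len(finals):
        raise DataError(f"{dataset_id}: planted alterations exceed the ligand panel")
    planted_up = finals[: plan.n_up]
    planted_down = finals[plan.n_up : plan.n_up + plan.n_down]
    guarded = finals[plan.n_up + plan.n_down :]
    return _assemble_table(
        spec,
        dataset_id,
        plan.target_label,
        f"{plan.target_label} vs control",
        planted_down,
        planted_up,
        guarded,
        seed,
    )


def simulate_interactions(spec: FixtureSpec, seed: int):
    """Interaction table, APC marker sets, and tolerogenic tables for the triage.

    Returns ``(interactions, apc_markers, tolerogenic_tables)``; receptor
    keys are the finalist symbols the layout assigned to each role.
    """
    lay = _layout(spec)
    receptors = {
        lay["role_symbol"][plan.role]: frozenset(lay["partners"][plan.role])
        for plan in spec.receptor_plans
    }
    interactions = InteractionTable(
        receptors=receptors, species=spec.species, source="synthetic fixture"
    )
    apc_markers = {
        t: GeneSet.from_iterable(f"{t}_markers", spec.species, members, provenance="synthetic fixture")
        for t, members in lay["marker_sets"].items()
    }
    tolerogenic = [
        simulate_tolerogenic_dataset(spec, t.dataset_id, seed) for t in spec.tolerogenic_plans
    ]
    return interactions, apc_markers, tolerogenic


def simulate_expression_matrix(
    means: pd.DataFrame,
    cells_per_type: int,
    seed: int,
    noise_sd: float = 0.5,
):
    """Cell x gene matrix around planted per-type means (values clipped at 0).

    ``means`` is cell_type x gene.  Returns ``(matrix, labels)`` with cell
    ids ``{type}_{i}``.
    """
    rng = np.random.default_rng([int(seed), zlib.crc32(b"expression")])
    frames = []
    labels = {}
    for cell_type in means.index:
        draws = rng.normal(
            means.loc[cell_type].to_numpy(), noise_sd, size=(cells_per_type, means.shape[1])
        )
        idx = [f"{cell_type}_{i}" for i in range(cells_per_type)]
        frames.append(pd.DataFrame(np.clip(draws, 0, None), index=idx, columns=means.columns))
        labels.update({i: cell_type for i in idx})
    matrix = pd.concat(frames)
    return matrix, pd.Series(labels, name="cell_type")


T_CELL_TYPES = ("CD4_T", "CD8_T", "MITOTIC_T", "TISSUE_T", "TREG")


def reference_expression_means(spec: FixtureSpec) -> pd.DataFrame:
    """Planted per-type means for the finalists plus five established checkpoints.

    Structure emulated: established checkpoints express highest in mitotic
    T cells and above the finalists in Tregs; one finalist peaks outside
    mitotic T cells so the argmax summary has signal to find.
    """
    lay = _layout(spec)
    genes = list(spec.reference_panel[:5]) + lay["finalists"]
    means = pd.DataFrame(2.0, index=list(T_CELL_TYPES), columns=genes)
    for g in spec.reference_panel[:5]:
        means.loc["MITOTIC_T", g] = 9.0
        means.loc["TREG", g] = 6.0
        means.loc["CD8_T", g] = 4.0
        means.loc["CD4_T", g] = 3.0
    for g in lay["finalists"]:
        means.loc["MITOTIC_T", g] = 6.0
        means.loc["TREG", g] = 3.0
        means.loc["CD8_T", g] = 3.0
        means.loc["CD4_T", g] = 2.0
    if lay["finalists"]:
        odd = lay["finalists"][-1]
        means.loc["MITOTIC_T", odd] = 2.0
        means.loc["TREG", odd] = 4.5  # the one finalist not peaking in mitotic T
    return means


# --------------------------------------------------------------------------
# shipped reference-screen spec


def _spec_from_dict(doc: dict) -> FixtureSpec:
    return FixtureSpec(
        universe_size=doc["universe_size"],
        membrane_size=doc["membrane_size"],
        foxp3_up_size=doc["foxp3_up_size"],
        treg_specific_size=doc["treg_specific_size"],
        membrane_foxp3_overlap=doc["membrane_foxp3_overlap"],
        membrane_treg_overlap=doc["membrane_treg_overlap"],
        known_ic_foxp3=doc["known_ic_foxp3"],
        known_ic_treg=doc["known_ic_treg"],
        survivors_treg=doc["survivors_treg"],
        survivors_foxp3=doc["survivors_foxp3"],
        finalists_treg=doc["finalists_treg"],
        finalists_foxp3=doc["finalists_foxp3"],
        reference_panel=tuple(doc["reference_panel"]),
        ko_plans=tuple(KOPlan(**p) for p in doc["ko_plans"]),
        receptor_plans=tuple(
            ReceptorPlan(
                **{**p, "apc_types": tuple(p.get("apc_types", ["B_cell"])),
                   "tolerogenic": tuple(p.get("tolerogenic", ["B1_BCELL"]))}
            )
            for p in doc.get("receptor_plans", [])
        ),
        shared_ligands=tuple(SharedLigandPlan(**p) for p in doc.get("shared_ligands", [])),
        tolerogenic_plans=tuple(TolerogenicPlan(**p) for p in doc.get("tolerogenic_plans", [])),
        modulation_plans=tuple(ModulationPlan(**p) for p in doc.get("modulation_plans", [])),
        apc_marker_sizes=tuple((t, n) for t, n in doc.get("apc_marker_sizes", {}).items()),
        background_size=doc.get("background_size", 2000),
        alpha=doc.get("alpha", 0.05),
        noise_log2fc_sd=doc.get("noise_log2fc_sd", 1.0),
        species=doc.get("species", "human"),
    )


@functools.lru_cache(maxsize=1)
def _reference_screen_doc() -> dict:
    text = resources.files("icscreen.data").joinpath("reference_screen.yaml").read_text()
    return yaml.safe_load(text)


def reference_screen_spec() -> FixtureSpec:
    """The shipped fixture spec reproducing every headline count of the screen."""
    return _spec_from_dict(_reference_screen_doc()["fixture"])


def reference_recorded_counts() -> dict:
    """Externally recorded counts the fixture emulates, for discrepancy logging."""
    return dict(_reference_screen_doc()["recorded"])


# --------------------------------------------------------------------------
# file output


def write_fixture(spec: FixtureSpec, outdir, seed: int) -> dict:
    """Write every pipeline input as plain-text files; returns the manifest.

    Output is a pure function of (spec, seed): same inputs give
    byte-identical files.
    """
    from . import io as icio  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = simulate_universe(spec)
    icio.write_gmt(list(sets.values()), outdir / "gene_sets.gmt")

    interactions, apc_markers, tolerogenic = simulate_interactions(spec, seed)
    icio.write_gmt(list(apc_markers.values()), outdir / "apc_markers.gmt")
    icio.write_interactions(interactions, outdir / "interactions.tsv")

    manifest = {
        "seed": int(seed),
        "species": spec.species,
        "gene_sets": "gene_sets.gmt",
        "apc_markers": "apc_markers.gmt",
        "interactions": "interactions.tsv",
        "ko_datasets": [],
        "scoring_datasets": [p.dataset_id for p in spec.ko_plans if p.scoring],
        "tolerogenic_datasets": [],
        "modulation_datasets": [],
    }
    (outdir / "ko").mkdir(exist_ok=True)
    for plan in spec.ko_plans:
        table = simulate_de_dataset(spec, plan.dataset_id, seed)
        icio.write_de_table(table, outdir / "ko" / f"{plan.dataset_id}.tsv")
        manifest["ko_datasets"].append(f"ko/{plan.dataset_id}.tsv")
    (outdir / "tolerogenic").mkdir(exist_ok=True)
    for table in tolerogenic:
        icio.write_de_table(table, outdir / "tolerogenic" / f"{table.dataset_id}.tsv")
        manifest["tolerogenic_datasets"].append(f"tolerogenic/{table.dataset_id}.tsv")
    (outdir / "modulation").mkdir(exist_ok=True)
    for plan in spec.modulation_plans:
        table = simulate_modulation_dataset(spec, plan.dataset_id, seed)
        icio.write_de_table(table, outdir / "modulation" / f"{plan.dataset_id}.tsv")
        manifest["modulation_datasets"].append(f"modulation/{plan.dataset_id}.tsv")

    means = reference_expression_means(spec)
    matrix, labels = simulate_expression_matrix(means, cells_per_type=40, seed=seed)
    icio.write_expression_matrix(matrix, labels, outdir / "expression_matrix.tsv", outdir / "cell_labels.tsv")
    manifest["expression_matrix"] = "expression_matrix.tsv"
    manifest["cell_labels"] = "cell_labels.tsv"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
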
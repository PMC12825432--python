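import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from icscreen import (
    DifferentialTable,
    PipelineInputs,
    ScreenConfig,
    reference_recorded_counts,
    reference_screen_spec,
    run_pipeline,
    simulate_de_dataset,
    simulate_interactions,
    simulate_modulation_dataset,
    simulate_universe,
)

settings.register_profile(
    "unit",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("unit")

SEED = 1


def make_de(rows, dataset_id="DS", target="CTLA4", species="human", comparison=""):
    """Quick DifferentialTable from {gene: (log2fc, pvalue)}."""
    frame = pd.DataFrame(
        [(g, lfc, p) for g, (lfc, p) in rows.items()],
        columns=["gene", "log2fc", "pvalue"],
    )
    return DifferentialTable.from_frame(
        frame,
        dataset_id=dataset_id,
        perturbed_target=target,
        species=species,
        comparison=comparison,
    )


@pytest.fixture(scope="session")
def spec():
    return reference_screen_spec()


@pytest.fixture(scope="session")
def config():
    return ScreenConfig(seed=SEED)


@pytest.fixture(scope="session")
def universe(spec):
    return simulate_universe(spec)


@pytest.fixture(scope="session")
def fixture_inputs(spec, universe):
    ko = [simulate_de_dataset(spec, p.dataset_id, SEED) for p in spec.ko_plans]
    interactions, apc_markers, tolerogenic = simulate_interactions(spec, SEED)
    modulation = [
        simulate_modulation_dataset(spec, p.dataset_id, SEED) for p in spec.modulation_plans
    ]
    return PipelineInputs(
        membrane=universe["membrane"],
        foxp3_up=universe["foxp3_up"],
        treg_specific=universe["treg_specific"],
        known_ics=universe["known_ics"],
        reference_panel=universe["reference_panel"],
        ko_datasets=ko,
        interactions=interactions,
        apc_markers=apc_markers,
        tolerogenic_datasets=tolerogenic,
        modulation_datasets=modulation,
        scoring_dataset_ids=tuple(p.dataset_id for p in spec.ko_plans if p.scoring),
    )


@pytest.fixture(scope="session")
def fixture_report(fixture_inputs, config):
    return run_pipeline(
        fixture_inputs, config, recorded=reference_recorded_counts()
    )
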
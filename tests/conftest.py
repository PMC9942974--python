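import pandas as pd
import pytest

from xciescape import (
    PipelineConfig,
    SimulationConfig,
    apply_qc,
    call_sample_skew,
    fit_escape_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic cohort, fixed seed; shared across tests."""
    config = SimulationConfig(seed=1)
    counts, sheet, truth, annotation = simulate_dataset(config)
    return {
        "config": config,
        "counts": counts,
        "sheet": sheet,
        "truth": truth,
        "annotation": annotation,
    }


@pytest.fixture(scope="session")
def default_scored(default_sim):
    """QC'd observations, skew calls and fitted escape model for the
    default cohort."""
    observations = apply_qc(default_sim["counts"], default_sim["sheet"])
    skew_calls = call_sample_skew(observations, default_sim["sheet"])
    model, records = fit_escape_model(observations, skew_calls)
    return {
        "observations": observations,
        "skew_calls": skew_calls,
        "model": model,
        "records": records,
    }


def make_counts(rows):
    """rows: iterable of (gene_id, sample_id, hapA, hapB)."""
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "hapA_count", "hapB_count"]
    )


def make_sheet(rows):
    """rows: iterable of (sample_id, individual_id, tissue[, pair, zygosity])."""
    full = [tuple(r) + (None,) * (5 - len(r)) for r in rows]
    return pd.DataFrame(
        full,
        columns=["sample_id", "individual_id", "tissue", "twin_pair_id", "zygosity"],
    )


@pytest.fixture
def tiny_config():
    """Config with gates lowered so tiny hand-built datasets pass them."""
    return PipelineConfig(min_skewed_samples=2)
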
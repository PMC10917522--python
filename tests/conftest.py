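import pandas as pd
import pytest

import brewtrack as bt


@pytest.fixture(scope="session")
def small_config() -> bt.SimulationConfig:
    """Desk-scale study: 40 proteins, 2 batches x 4 time points x 2 replicates."""
    return bt.SimulationConfig(
        n_proteins=40,
        timepoints_hours=((0.0, 6.0, 24.0, 48.0), (0.0, 6.0, 24.0, 48.0)),
        n_planted_clusters=2,
        cluster_profiles=((0.5, 1.0, 2.0, 4.0), (4.0, 2.0, 1.0, 0.5)),
        background_fraction=0.5,
        complex_specs=((4, 0.7), (4, 0.7)),
        detection_limit=1e2,  # essentially everything detected
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    records, truth = bt.generate_proteome(small_config)
    evidence, metadata = bt.generate_evidence(small_config, records, truth)
    return {
        "config": small_config,
        "records": records,
        "proteome": bt.proteome_dict(records),
        "truth": truth,
        "evidence": evidence,
        "metadata": metadata,
    }


def toy_matrix(values: dict, batch_hours_rep: list, value_kind: str = "log2-centred"):
    """Hand-built AbundanceMatrix: values maps protein -> list per sample."""
    sample_ids = [f"b{b}_t{h:g}_r{r}" for b, h, r in batch_hours_rep]
    samples = pd.DataFrame(
        {"batch": [b for b, _, _ in batch_hours_rep],
         "hours": [h for _, h, _ in batch_hours_rep],
         "replicate": [r for _, _, r in batch_hours_rep]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=sample_ids).T
    df.index.name = "protein_id"
    return bt.AbundanceMatrix(values=df, samples=samples, value_kind=value_kind)
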
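"""Shared fixtures: small synthetic experiments and toy matrices."""

import numpy as np
import pandas as pd
import pytest

from crcpathways import syndata


@pytest.fixture(scope="session")
def small_design():
    return syndata.SimulationDesign(
        n_probes=400,
        n_samples_per_group={"NC": 10, "AD": 10, "CA": 10},
        n_pathways=20,
        pathway_size_range=(8, 20),
        planted_pathways=(
            syndata.PlantedPathway("PW001", "NC_vs_AD+CA", 1.0),
            syndata.PlantedPathway("PW002", "epithelium", 1.5),
        ),
        n_monotone_up=5,
        n_monotone_down=5,
        y_probe_count=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dictionary(small_design):
    annot = syndata.probe_annotation(small_design)
    universe = annot.loc[annot["is_chrY"] == 0, "gene_symbol"].tolist()
    return syndata.generate_pathway_dictionary(
        small_design.n_pathways,
        small_design.pathway_size_range,
        universe,
        overlap_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_design, small_dictionary):
    return syndata.simulate_experiment(small_design, small_dictionary)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(11)
    values = rng.lognormal(mean=5.0, sigma=1.0, size=(50, 8))
    return pd.DataFrame(
        values,
        index=[f"P{i:03d}" for i in range(50)],
        columns=[f"S{j}" for j in range(8)],
    )
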
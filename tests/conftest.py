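import numpy as np
import pandas as pd
import pytest

from orthotx import simulate


@pytest.fixture(scope="session")
def small_reference():
    return simulate.generate_reference_gene_set(
        60, isoform_fraction=0.2, length_range=(500, 1500), seed=101
    )


@pytest.fixture(scope="session")
def species_pair(small_reference):
    return simulate.generate_species_pair(
        small_reference, divergence=0.02, n_chimeras=8, overlap_mix=0.5,
        seed=102,
    )


@pytest.fixture(scope="session")
def null_experiment():
    exp, truth = simulate.generate_count_experiment(
        1000, dispersion=0.1, seed=103
    )
    return exp, truth


@pytest.fixture(scope="session")
def effect_experiment():
    exp, truth = simulate.generate_count_experiment(
        800, dispersion=0.1, deg_fraction=0.1, ddeg_fraction=0.1,
        effect_size_log2=2.0, baseline_mean_log2=(7.0, 11.0), seed=104
    )
    return exp, truth
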
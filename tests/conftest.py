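import numpy as np
import pandas as pd
import pytest

import radmap
from radmap import linkage as lk


@pytest.fixture(scope="session")
def small_truth():
    """Two chromosomes, 8 polymorphic loci each, 40 DH individuals."""
    cfg = radmap.SimConfig(n_chromosomes=2, loci_per_chromosome=8,
                           inter_locus_cM=10.0, n_individuals=40,
                           n_repeat_loci=0, seed=101)
    truth = radmap.simulate_genome(cfg)
    return radmap.simulate_dh_population(truth, cfg.n_individuals, seed=102), cfg


@pytest.fixture(scope="session")
def study_truth():
    """The full-size design: 7 chromosomes x 20 loci, 93 DH lines."""
    cfg = radmap.SimConfig(seed=7, n_repeat_loci=0)
    truth = radmap.simulate_genome(cfg)
    return radmap.simulate_dh_population(truth, cfg.n_individuals, seed=8), cfg


@pytest.fixture(scope="session")
def study_matrix(study_truth):
    truth, _ = study_truth
    return radmap.simdata.true_genotype_matrix(truth)


@pytest.fixture(scope="session")
def study_map(study_matrix):
    gmap, unlinked = lk.build_map(study_matrix)
    return gmap, unlinked


def tiny_matrix(rows: dict[str, str]) -> pd.DataFrame:
    """Genotype matrix from compact strings, e.g. {'M1': 'AAB-'}."""
    data = {m: list(s) for m, s in rows.items()}
    mat = pd.DataFrame.from_dict(data, orient="index")
    mat.columns = [f"I{i + 1}" for i in range(mat.shape[1])]
    mat.index.name = "locus_id"
    return mat
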
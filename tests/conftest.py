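"""Shared synthetic fixtures for the test suite.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import poolfit as pf


@pytest.fixture(scope="session")
def genome():
    return pf.simulate_genome(
        200, megaplasmid_fraction=0.05, mean_operon_size=2.5, n_subroles=6, seed=101)


@pytest.fixture(scope="session")
def dataset(genome):
    """A small but complete simulated compendium with moderate signal."""
    lib = pf.simulate_insertion_library(genome, 450, intergenic_fraction=0.05, seed=102)
    pools = pf.assemble_pools(lib, detect_failure_rate=0.02, seed=103)
    truth = pf.simulate_truth(
        genome, n_conditions=16, n_controls=8, sparsity=0.06,
        effect_scale=2.5, operon_share=0.8, seed=104)
    table = pf.simulate_intensities(
        pools, truth, probe_sd=0.25, plate_sd=0.25, replicon_shift=0.25, seed=105)
    return {"genome": genome, "library": lib, "pools": pools,
            "truth": truth, "table": table}


@pytest.fixture(scope="session")
def fitness_matrix(dataset):
    return pf.compute_strain_fitness(
        dataset["table"], dataset["pools"].strains, dataset["genome"])


@pytest.fixture(scope="session")
def scores(fitness_matrix):
    return pf.score_genes(fitness_matrix)


def make_strain_matrix(values: dict, provenance: dict,
                       experiments: list[str] | None = None):
    """Hand-build a StrainFitnessMatrix from plain dicts.

    ``values``: {(strain, pool): {experiment: value}};
    ``provenance``: {(strain, pool): (replicon, plate, gene_id, gene_fraction)}.
    """
    idx = pd.MultiIndex.from_tuples(values.keys(), names=["strain_id", "pool"])
    vals = pd.DataFrame([values[k] for k in values], index=idx)
    prov = pd.DataFrame(
        [{"pool": k[1], "replicon": provenance[k][0], "plate": provenance[k][1],
          "gene_id": provenance[k][2], "gene_fraction": provenance[k][3]}
         for k in values], index=idx)
    exps = experiments or list(vals.columns)
    meta = pd.DataFrame({
        "experiment_id": exps, "pool": "both", "class": "condition",
        "condition_name": exps, "group": [f"x_{e}" for e in exps]})
    return pf.StrainFitnessMatrix(values=vals, provenance=prov, experiments=meta)
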
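import numpy as np
import pandas as pd
import pytest

from ecoparallel.expression import ExpressionExperiment, filter_cpm, tmm_factors
from ecoparallel.simulate import ExpressionScenario, gen_expression


@pytest.fixture(scope="session")
def small_experiment():
    """Paper-structured synthetic expression data at small scale."""
    exp, truth, _ = gen_expression(ExpressionScenario(n_genes=400, seed=3))
    return exp, truth


@pytest.fixture(scope="session")
def filtered_experiment(small_experiment):
    exp, _ = small_experiment
    f = filter_cpm(exp)
    return ExpressionExperiment(f.counts, f.samples, tmm_factors(f))


def toy_allele_table(rows):
    """Build an allele-count table from (chrom, pos, gene, pop, count, n) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "gene_id", "pop", "minor_count", "n"]
    )
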
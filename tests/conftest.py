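import numpy as np
import pandas as pd
import pytest

from varicourse.hvg import variability_table
from varicourse.quantify import ExpressionMatrix, compute_tpm, filter_genes
from varicourse.simulate import SimConfig, generate_dataset
from varicourse.timecourse import assemble


def make_matrix(values, unit="tpm", timepoint="ZT2", lengths=None, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    if lengths is not None:
        lengths = pd.Series(np.asarray(lengths, dtype=float), index=df.index)
    return ExpressionMatrix(df, unit, timepoint=timepoint, gene_lengths=lengths)


@pytest.fixture(scope="session")
def single_timepoint():
    """One simulated time-point (14 individuals) with planted always-on HVGs."""
    config = SimConfig(
        n_timepoints=1,
        n_individuals=14,
        n_genes=2000,
        seed=11,
        cluster_scheme={"always": [True]},
    )
    matrices, truth = generate_dataset(config)
    return matrices[0], truth


@pytest.fixture(scope="session")
def small_course():
    """A full (reduced) diurnal run: 6 time-points, per-time-point tables."""
    config = SimConfig(n_timepoints=6, n_individuals=14, n_genes=800, seed=3)
    matrices, truth = generate_dataset(config)
    tpms = {m.timepoint: compute_tpm(m) for m in matrices}
    tables = {}
    for tp, mat in tpms.items():
        report = filter_genes(tpms, tp)
        tables[tp], _ = variability_table(mat, genes=report.retained)
    course = assemble(tables, n_lvg=100)
    return course, tables, truth
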
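import numpy as np
import pandas as pd
import pytest

from gecna import (
    CnaCallMatrix,
    ExpressionMatrix,
    PlantedGene,
    SimulationConfig,
    align_cohort,
    generate_cohort,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium synthetic cohort with 3 facilitators and 3 suppressors planted
    on total burden, plus one survival-coupled gene."""
    config = SimulationConfig(
        n_patients=300,
        n_genes=400,
        mu_burden=120.0,
        missing_gene_fraction=0.1,
        facilitators=[PlantedGene(3.0, "total", f"FAC{i}") for i in range(3)],
        suppressors=[PlantedGene(-3.0, "total", f"SUP{i}") for i in range(3)],
        gene_betas={"FAC0": 0.5},
        seed=11,
    )
    cohort, truth = generate_cohort(config)
    return config, cohort, truth


@pytest.fixture
def tiny_matrix_files(tmp_path):
    """3-gene x 4-patient expression TSV (one NA cell) and a matching CNA TSV."""
    expr = tmp_path / "expr.txt"
    expr.write_text(
        "Hugo_Symbol\tP1\tP2\tP3\tP4\n"
        "GENE1\t0.5\t-1.25\t2.0\t0.0\n"
        "GENE2\tNA\t0.75\t-0.5\t1.5\n"
        "GENE3\t1.0\t0.25\t-2.0\t-0.125\n"
    )
    cna = tmp_path / "cna.txt"
    cna.write_text(
        "Hugo_Symbol\tP1\tP2\tP3\tP4\n"
        "GENE1\t2\t-1\t0\t1\n"
        "GENE2\t0\t0\t-2\t0\n"
        "GENE3\t1\t0\t0\t-1\n"
    )
    return expr, cna


def make_cohort(expr_values, cna_values, patients=None, genes=None, clinical=None):
    """Assemble an aligned cohort from plain arrays (helper for unit tests)."""
    expr_values = np.asarray(expr_values, dtype=float)
    genes = genes or [f"G{i}" for i in range(expr_values.shape[0])]
    patients = patients or [f"P{i:03d}" for i in range(expr_values.shape[1])]
    expr = ExpressionMatrix(pd.DataFrame(expr_values, index=genes, columns=patients))
    cna = CnaCallMatrix(
        pd.DataFrame(np.asarray(cna_values, dtype=np.int8), index=genes, columns=patients)
    )
    return align_cohort(expr, cna, clinical)
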
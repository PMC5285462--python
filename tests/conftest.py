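import numpy as np
import pytest

import cnvgsa as c


def scaled_config(**overrides) -> c.SimConfig:
    """Down-scaled study conditions for tests: gene density, CNV size
    distribution and probe rate match the full-size defaults; subject and
    gene counts are reduced."""
    base = dict(
        n_genes=1200,
        n_chroms=6,
        genome_length_per_chrom=30_000_000,
        n_cases=500,
        n_controls=500,
        seed=0,
    )
    base.update(overrides)
    return c.SimConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return scaled_config()


@pytest.fixture(scope="session")
def genes(small_config):
    return c.gen_gene_annotation(small_config)


@pytest.fixture(scope="session")
def gene_index(genes):
    return c.GeneIndex(genes)


@pytest.fixture(scope="session")
def homology(genes):
    return c.gen_homology_table(genes, frac_unmapped=0.05,
                                frac_multimapped=0.05, seed=11)


@pytest.fixture(scope="session")
def planted_cohort(genes, small_config):
    """Cohort with a planted log-OR of log(2) on a random 5% gene set."""
    rng = np.random.default_rng(21)
    planted = {genes[i].gene_id
               for i in rng.choice(len(genes), size=60, replace=False)}
    cfg = small_config.replace(planted_log_or=float(np.log(2)))
    subjects, cnvs = c.gen_cnv_cohort(genes, planted, cfg, seed=22)
    return subjects, cnvs, planted


@pytest.fixture(scope="session")
def annotated_planted(planted_cohort, gene_index):
    subjects, cnvs, planted = planted_cohort
    annotated = c.annotate_cnvs(c.filter_cnvs(cnvs), gene_index)
    return subjects, annotated, planted
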
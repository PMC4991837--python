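import numpy as np
import pytest

from wrkyscan import pipeline, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """24-gene cohort on 3 chromosomes with one planted 4-gene cluster."""
    cfg = synthetic.scaled_config(24)
    cfg.n_chromosomes = 3
    cfg.cluster_plans = [synthetic.ClusterPlan(0, 4, 200_000)]
    return synthetic.gen_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    c = small_cohort
    return pipeline.run_pipeline(
        c.genome, c.genes, c.proteins, expr=c.expression,
        alignment=c.domain_alignment, alignment_labels=c.domain_labels,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
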
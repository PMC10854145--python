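import warnings

import pytest

from iwhmb import irg, synthetic


@pytest.fixture(scope="session")
def toy():
    return synthetic.toy_fixture()


@pytest.fixture(scope="session")
def cohort():
    """Standard synthetic cohort: n=300 samples, 2000 genes, 24 sets."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.generate(synthetic.SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_expr_z(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return irg.zscore_rows(cohort.expression)


@pytest.fixture(scope="session")
def cohort_fits(cohort, cohort_expr_z):
    """SVR fits for every gene of the standard cohort (shared: expensive)."""
    return irg.fit_svr_per_gene(cohort.iwhmb, cohort_expr_z)


@pytest.fixture(scope="session")
def subtype_cohort():
    """Smaller cohort (n=200) for clustering and eigengene recovery."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.generate(
            synthetic.SyntheticCohortConfig(n_samples=200, seed=3)
        )


@pytest.fixture
def small_cohort_dir(tmp_path):
    """A tiny cohort written to disk for CLI round-trips."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = synthetic.generate(SMALL_CONFIG)
    cohort.write(tmp_path / "cohort")
    return tmp_path / "cohort"


SMALL_CONFIG = synthetic.SyntheticCohortConfig(
    n_samples=40,
    n_genes=150,
    n_sets=6,
    set_size_min=8,
    set_size_max=12,
    attachment=2,
    n_tf_edges=20,
    n_subtypes=2,
    sets_per_subtype=2,
    enrichment_multiplier=6.0,
    background_rate=0.05,
    n_planted_irgs=10,
    n_module_genes=8,
    n_immune_genes=6,
    n_planted_bridges=4,
    seed=5,
)
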
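import warnings

import numpy as np
import pytest

import plasmaprot as pp
from plasmaprot.io import medication_wide, npx_wide


@pytest.fixture(scope="session")
def demo():
    """One mid-size cohort run through QC and the covariate screen, shared
    across test modules."""
    cfg = pp.SimulationConfig(
        n_discovery=300,
        n_replication=150,
        n_proteins=40,
        n_variants=200,
        n_low_abundance=2,
        seed=11,
    )
    cohort = pp.generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normed, _ = pp.normalize_batches(cohort.npx)
        filtered, qc_report = pp.filter_lod(normed)
        wide = npx_wide(filtered)
        med = medication_wide(cohort.medication, wide.index)
        screen = pp.screen_all(wide, cohort.cohort, med)
    return {
        "config": cfg,
        "cohort": cohort,
        "npx_wide": wide,
        "medication_wide": med,
        "qc_report": qc_report,
        "screen": screen,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
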
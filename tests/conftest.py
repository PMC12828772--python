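import warnings

import numpy as np
import pandas as pd
import pytest

import tmesubtypes as tms

warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")

COMPONENTS = list(tms.COMPONENTS)


@pytest.fixture(scope="session")
def reference():
    return tms.generate_reference(n_genes_per_type=30, n_background_genes=90, seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort(reference):
    cfg = tms.SimulationConfig(
        n_patients=40, noise_sd=0.0, sd_focus=0.0, sd_sample=0.0, seed=3
    )
    return tms.simulate_cohort(cfg, reference)


@pytest.fixture(scope="session")
def default_cohort(reference):
    cfg = tms.SimulationConfig(n_patients=300, seed=7)
    return tms.simulate_cohort(cfg, reference)


@pytest.fixture(scope="session")
def default_composition(reference, default_cohort):
    expr, _, _, _ = default_cohort
    return tms.deconvolve_cohort(expr, reference)


def make_composition(values: np.ndarray, sample_ids=None) -> tms.CompositionMatrix:
    """Wrap an (n x 8) array of simplex rows as a CompositionMatrix."""
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(values.shape[0])]
    return tms.CompositionMatrix(pd.DataFrame(values, index=sample_ids, columns=COMPONENTS))


def make_clinical(times, events, gleason=None, pt=None, ids=None) -> tms.ClinicalTable:
    n = len(times)
    ids = ids if ids is not None else [f"P{i}" for i in range(n)]
    return tms.ClinicalTable(
        pd.DataFrame(
            {
                "followup_months": times,
                "bcr_event": events,
                "gleason_category": gleason if gleason is not None else ["low"] * n,
                "pt_category": pt if pt is not None else ["T2"] * n,
            },
            index=ids,
        )
    )
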
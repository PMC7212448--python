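import numpy as np
import pandas as pd
import pytest

from glycoquant.pipeline import run_pipeline
from glycoquant.synthetic import SimConfig, simulate_experiment
from glycoquant.tables_io import ChannelDesign


@pytest.fixture(scope="session")
def design():
    return ChannelDesign.default()


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic experiment, shared across tests."""
    return simulate_experiment(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline on the default synthetic experiment."""
    return run_pipeline(default_sim.glyco_psms, default_sim.protein_psms)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free experiment: every ratio must be exact."""
    return simulate_experiment(SimConfig(sigma_log2=0.0), seed=3)


@pytest.fixture(scope="session")
def noiseless_run(noiseless_sim):
    return run_pipeline(noiseless_sim.glyco_psms, noiseless_sim.protein_psms)


def make_psms(rows, design, kind="glyco"):
    """Build an in-memory PSM table from (keys..., intensities) tuples.

    For glyco rows: (protein, glycosite, glycan, [i126, i127N, i128C, i129N]).
    For protein rows: (protein, [intensities]).
    """
    records = []
    for i, row in enumerate(rows):
        if kind == "glyco":
            protein, site, glycan, intens = row
            rec = {
                "spectrum_id": f"S{i:05d}",
                "peptide": "TESTN#STK",
                "protein": protein,
                "glycosite": site,
                "glycan": glycan,
            }
        else:
            protein, intens = row
            rec = {
                "spectrum_id": f"S{i:05d}",
                "peptide": "TESTPEPK",
                "protein": protein,
            }
        rec.update(dict(zip(design.channels, map(float, intens))))
        records.append(rec)
    return pd.DataFrame(records)
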
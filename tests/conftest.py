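import warnings

import numpy as np
import pandas as pd
import pytest

from coldphos.io_formats import PhosphopeptideRecord, ProteomeDb, QuantTable
from coldphos.synthetic_data import SimConfig, simulate_dataset

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", module="scipy")


def make_quant(intensity_rows, sites=None, probs=None, times=(0, 5, 15, 30, 60),
               n_reps=3):
    """Build a QuantTable from a dict peptide_id -> intensity list (row-major
    over time asc, rep asc); optional per-peptide sites/loc probabilities."""
    cols = [f"{t}min_rep{r}" for t in times for r in range(1, n_reps + 1)]
    records, data = [], []
    for pid, vals in intensity_rows.items():
        s = (sites or {}).get(pid, [(7, "S")])
        p = (probs or {}).get(pid, [0.95] * len(s))
        seq = "AAAAAA" + "".join(res for _, res in s) + "AAAAAA"
        records.append(PhosphopeptideRecord(
            peptide_id=pid, sequence=seq, protein_id=f"P_{pid}",
            sites=s, loc_probability=p))
        data.append(vals)
    df = pd.DataFrame(data, columns=cols,
                      index=pd.Index(intensity_rows.keys(), name="peptide_id"))
    return QuantTable(records=records, times=list(times),
                      replicates=list(range(1, n_reps + 1)), intensities=df)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic study shared across tests."""
    return simulate_dataset(SimConfig(seed=20260924))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast synthetic study (25 peptides per archetype)."""
    return simulate_dataset(SimConfig(seed=7, n_per_archetype=25,
                                      n_background_proteins=60))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
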
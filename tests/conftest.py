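import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lipidaxis import FeatureTable, LipidomeSimConfig, generate_lipidome
from lipidaxis.preprocess import normalize_total_area

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")

#: Compact subclass inventory covering every node of the default reaction
#: network, used by tests that need many replicates.
PATHWAY_COUNTS = {
    "LPC": 8, "PC": 20, "PA": 15, "DG": 10, "TG": 8,
    "LPA": 5, "PI": 8, "LPI": 5, "PG": 6, "LPG": 4,
}


def make_table(values, features=None, n_dl=None, tissue="PFC", normalized=False):
    """Build a FeatureTable from a plain array (features x samples)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n_dl is None:
        n_dl = n // 2
    samples = pd.Index(
        [f"DL{i:02d}" for i in range(n_dl)] + [f"HC{i:02d}" for i in range(n - n_dl)],
        name="sample",
    )
    if features is None:
        features = [f"f{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame(
        {"group": ["DL"] * n_dl + ["HC"] * (n - n_dl), "tissue": tissue},
        index=samples,
    )
    frame = pd.DataFrame(values, index=pd.Index(features, name="species"), columns=samples)
    return FeatureTable(frame, meta, normalized=normalized)


@pytest.fixture(scope="session")
def pfc_lipidome():
    """One small PFC lipidome with a planted DG effect, QC-clean."""
    cfg = LipidomeSimConfig(
        tissues=("PFC",),
        n_species_per_subclass=PATHWAY_COUNTS,
        subclass_effects=(("PFC", "DG", 1.38),),
        seed=20260101,
    )
    return generate_lipidome(cfg).tissues["PFC"]


@pytest.fixture(scope="session")
def pfc_normalized(pfc_lipidome):
    return normalize_total_area(pfc_lipidome.table)
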
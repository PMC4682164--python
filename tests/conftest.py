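import numpy as np
import pytest

from phenodyn import SimConfig, SessionSeries, gen_parcel_sessions


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale generator configuration shared across tests."""
    return SimConfig(
        n_parcels=40, n_networks=4, n_sessions=10,
        timepoints_per_session=200, n_genes=120, n_gene_modules=4,
        n_metabolites=24, n_metab_clusters=3, n_omics_sessions=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sessions(small_cfg):
    sessions, truth = gen_parcel_sessions(small_cfg)
    return sessions, truth


def make_session(data, mask=None, session_id="s0", state="unknown"):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[1], dtype=bool)
    return SessionSeries(parcel_ids=np.arange(data.shape[0]), data=data,
                         censor_mask=np.asarray(mask, dtype=bool),
                         session_id=session_id, state=state)
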
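import numpy as np
import pandas as pd
import pytest

from glacierseg.movement import UD
from glacierseg.synthetic import SimConfig, simulate_seascape, simulate_tracks


def gaussian_ud(mean, sigma, cell=100.0, pad_sd=6.0) -> UD:
    """Discretized isotropic Gaussian UD on the global lattice (test helper)."""
    pad = pad_sd * sigma
    ix0 = int(np.floor((mean[0] - pad) / cell))
    ix1 = int(np.floor((mean[0] + pad) / cell))
    iy0 = int(np.floor((mean[1] - pad) / cell))
    iy1 = int(np.floor((mean[1] + pad) / cell))
    xc = (ix0 + np.arange(ix1 - ix0 + 1) + 0.5) * cell
    yc = (iy0 + np.arange(iy1 - iy0 + 1) + 0.5) * cell
    g = np.exp(
        -((xc[None, :] - mean[0]) ** 2 + (yc[:, None] - mean[1]) ** 2)
        / (2 * sigma**2)
    )
    return UD(ix0=ix0, iy0=iy0, masses=g / g.sum(), cell=cell)


def fixes_frame(times_min, lon, lat, individual="B1", colony="C01",
                t0="2017-07-15T00:00:00Z") -> pd.DataFrame:
    t0 = pd.Timestamp(t0)
    return pd.DataFrame(
        {
            "individual_id": individual,
            "colony_id": colony,
            "timestamp": t0 + pd.to_timedelta(np.asarray(times_min, float), unit="m"),
            "lon": np.asarray(lon, float),
            "lat": np.asarray(lat, float),
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated study shared across tests."""
    cfg = SimConfig(seed=11, individuals_per_colony=4, n_colonies=3, n_fronts=10)
    sea = simulate_seascape(cfg)
    fixes, truth = simulate_tracks(cfg, sea)
    return cfg, sea, fixes, truth
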
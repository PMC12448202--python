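import numpy as np
import pandas as pd
import pytest

import segdrive as sd


def make_table(pos_bp, mat, pat, chrom="1", tissue="pollen", cross_id="t",
               pos_cM=None, cm_per_mb=5.0):
    """Small count-table builder; genetic positions default to a linear map."""
    pos_bp = np.asarray(pos_bp, dtype=int)
    if pos_cM is None:
        pos_cM = pos_bp / 1e6 * cm_per_mb
    df = pd.DataFrame({
        "chrom": str(chrom), "pos_bp": pos_bp, "pos_cM": pos_cM,
        "mat_count": np.asarray(mat, dtype=int),
        "pat_count": np.asarray(pat, dtype=int),
    })
    return sd.SiteCountTable(df, tissue=tissue, cross_id=cross_id)


@pytest.fixture(scope="session")
def f1_fixture():
    return sd.load_f1_effect_matrix()


@pytest.fixture(scope="session")
def sim_cross_k10():
    """One simulated cross with a distorter of k = 0.10 at 5 Mb."""
    cfg = sd.SimulationConfig(
        n_sites=3000, chrom_length_bp=20_000_000, map_length_morgans=1.0,
        distorters={"1": (5_000_000, 0.10)}, error_rate=0.005,
        depth_mean=100, depth_dispersion="fixed", seed=42)
    leaf, pollen, truth = sd.simulate_cross(cfg)
    model = sd.LikelihoodModel(genetic_map=cfg.map(), error_rate=0.005,
                               grid_thin=8, site_bin_cM=0.1)
    return cfg, leaf, pollen, truth, model
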
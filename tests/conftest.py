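import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sfmultiome.config import validate_config
from sfmultiome.core import CountMatrix
from sfmultiome.simulate import SimulationDesign, simulate_multiome


def small_design(seed: int = 3) -> SimulationDesign:
    """A reduced design for fast unit tests (not the default study design)."""
    return SimulationDesign(
        n_clusters=6,
        cells_per_cluster_per_condition=30,
        n_genes=300,
        n_tfs=5,
        n_peaks=600,
        genome={f"chr{i}": 12_000_000 for i in range(1, 5)},
        markers_per_cluster=8,
        targets_per_tf=10,
        n_trajectory_genes=15,
        n_primed=10,
        n_decoy_motifs=5,
        prior_extra_genes=10,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate_multiome(small_design())


@pytest.fixture(scope="session")
def small_cfg():
    # thresholds scaled to the reduced library size of the small design
    return validate_config({"min_genes": 50, "top_k": 40, "min_targets": 5})


@pytest.fixture
def toy_counts():
    """3 genes x 4 cells toy count matrix."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 4],
            [1, 1, 1, 1],
        ]
    )
    return CountMatrix(
        np.array(["gA", "gB", "gC"], dtype=object),
        np.array(["c1", "c2", "c3", "c4"], dtype=object),
        sp.csr_matrix(counts),
    )


def make_peaks(rows):
    """Helper: interval frame from (chrom, start, end, score) tuples."""
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    frame["name"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(frame["chrom"], frame["start"], frame["end"])
    ]
    return frame
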
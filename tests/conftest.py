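import numpy as np
import pytest

from tandemrrm.peaklists import AssignedPeak, PeakList, TitrationSeries
from tandemrrm.trajectory import TrajectoryEnsemble


@pytest.fixture
def tiny_series():
    """Two-point titration with one residue shifting and one static."""
    ref = PeakList(
        "free",
        (
            AssignedPeak(10, "G", w_H=8.40, w_N=108.00),
            AssignedPeak(11, "A", w_H=7.90, w_N=121.50),
        ),
    )
    shifted = PeakList(
        "bound",
        (
            AssignedPeak(10, "G", w_H=8.50, w_N=108.20),
            AssignedPeak(11, "A", w_H=7.90, w_N=121.50),
        ),
    )
    return TitrationSeries(protein_conc=0.05, ligand_concs=(0.0, 5.0), peaklists=(ref, shifted))


def make_ca_ensemble(coords_per_replica, start_residue=1):
    """Wrap (frames, n_res, 3) arrays as a Calpha-only ensemble."""
    n_res = coords_per_replica[0].shape[1]
    topo = tuple((start_residue + i, "CA") for i in range(n_res))
    return TrajectoryEnsemble(replicas=[np.asarray(c, float) for c in coords_per_replica],
                              topology=topo)


@pytest.fixture
def static_ensemble():
    rng = np.random.default_rng(0)
    ref = rng.uniform(0, 20, (12, 3))
    frames = np.tile(ref, (5, 1, 1))
    return make_ca_ensemble([frames.copy(), frames.copy()])
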
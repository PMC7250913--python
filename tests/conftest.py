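import numpy as np
import pytest

from neurosurv.design import ExperimentDesign, HazardModel, ImagingModel, ReporterDynamics
from neurosurv import simulate as sim


@pytest.fixture(scope="session")
def clean_imaging():
    """Noise-free camera: exact rendering for equivalence checks."""
    return ImagingModel(poisson_noise=False, read_noise_sd=0.0,
                        photobleach_rate=0.0)


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(
        plates=1, wells_per_plate=2, fields_per_well=2, neurons_per_field=8,
        group_of_well={0: "control", 1: "mutant"},
        frame_interval=24.0, end_of_followup=120.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_design, clean_imaging):
    hm = HazardModel(shape=1.3, scale=110.0, group_log_hr={"mutant": 0.5})
    return sim.simulate_fates(small_design, hm, seed=101, imaging=clean_imaging)


def match_tracks_to_truth(tracks, field_truth):
    """Pair each track with its nearest ground-truth neuron (by seed)."""
    pairs = []
    used = set()
    for tr in tracks:
        x, y = tr.seed
        d = np.hypot(field_truth.fates["x"] - x, field_truth.fates["y"] - y)
        j = d.idxmin()
        nid = int(field_truth.fates.loc[j, "neuron_id"])
        if nid in used:
            continue
        used.add(nid)
        pairs.append((tr, nid))
    return pairs
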
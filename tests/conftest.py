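import numpy as np
import pytest

from cardiofat3d.coilcombine import combine_coils, reference_to_first_echo
from cardiofat3d.phantom import AcquisitionParams, PhantomConfig, make_truth, simulate_wf_echoes

TAU_MS = np.array([0.0, 0.23, 0.46])
FAT_OFFSET_HZ = -1361.0


def forward_signal(w, f, psi_hz, tau_ms=TAU_MS, fat_offset_hz=FAT_OFFSET_HZ,
                   phase_w=0.0, phase_f=0.0):
    """Reference forward model for a single voxel (independent of the solver)."""
    t = np.asarray(tau_ms) * 1e-3
    return (w * np.exp(1j * phase_w)
            + f * np.exp(1j * phase_f) * np.exp(2j * np.pi * fat_offset_hz * t)) \
        * np.exp(2j * np.pi * psi_hz * t)


@pytest.fixture(scope="session")
def default_truth():
    return make_truth(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def noisefree_combined(default_truth):
    params = AcquisitionParams(n_coils=default_truth.coil_sens.shape[0],
                               noise_sd=0.0, seed=7)
    multi = simulate_wf_echoes(default_truth, params)
    return reference_to_first_echo(combine_coils(multi, mode="complex_sum"))
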
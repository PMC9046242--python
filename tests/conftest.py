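import numpy as np
import pytest

from acropore.config import (AcquisitionConfig, CaSensorModel, MFParams,
                             PSFParams, SimCellParams)


@pytest.fixture
def sensor():
    return CaSensorModel()


@pytest.fixture
def acq_quiet():
    """Noise-free acquisition at the default 2 Hz / 8 min geometry."""
    return AcquisitionConfig(noise_sd=0.0)


@pytest.fixture
def acq_default():
    return AcquisitionConfig()


@pytest.fixture
def fast_cell_params():
    """A canonical fast responder undergoing full exocytosis."""
    return SimCellParams(
        responder_class="fast", acr_onset_s=60.0, amp_dF=450.0,
        slope_dF_per_s=120.0, rise_duration_s=20.0,
        mf=MFParams(mf_onset_s=85.0, mf_duration_s=12.0))


@pytest.fixture
def psf_cell_params():
    """A fast responder preceded by a prespike-foot-like shelf."""
    return SimCellParams(
        responder_class="fast", acr_onset_s=60.0, amp_dF=500.0,
        slope_dF_per_s=120.0, rise_duration_s=20.0,
        psf=PSFParams(psf_onset_s=45.0, psf_duration_s=15.0,
                      psf_amp_fraction=0.2))


def scan_onset_bruteforce(values, threshold, m_frames, start):
    """Independent frame-by-frame scan of the sustained-threshold onset
    rule: first index >= start beginning >= m_frames consecutive frames
    with value > threshold. Deliberately naive."""
    n = len(values)
    for i in range(start, n - m_frames + 1):
        run = True
        for j in range(m_frames):
            if not values[i + j] > threshold:
                run = False
                break
        if run:
            return i
    return None


def euler_pore_ode(t_end, dt, n_pores, pore_flux, sensor, ca0, clear=0.0):
    """Brute-force forward-Euler integration of the calcium law."""
    ca = ca0
    out = [ca0]
    steps = int(round(t_end / dt))
    for _ in range(steps):
        influx = (n_pores * pore_flux * (sensor.ca_ext_uM - ca)
                  / sensor.ca_ext_uM) if sensor.ca_ext_uM > 0 else 0.0
        ca = ca + dt * (influx - clear * (ca - sensor.ca_rest_uM))
        out.append(ca)
    return np.asarray(out)
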
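import numpy as np
import pytest

from ventmech.io import WaveformRecord
from ventmech.synthetic import SyntheticConfig, generate_record

#: single-compartment regime used throughout: physiological porcine
#: elastance/resistance/PEEP (cmH2O/L, cmH2O*s/L, mbar)
SINGLE_TRUTH = (26.1130, 7.1716, 3.3972)

#: hybrid ground truth used by the recovery and ranking experiments
HYBRID_TRUTH = (26.1130, 7.1716, 0.4, 0.05, 3.3972)
HYBRID_NCPS = {"alpha": 0.8, "beta": 5.0}

#: measurement-noise regime for parameter-recovery experiments: 1% of the
#: plateau pressure on the transducer channel, instrument-scale noise on the
#: digitally-derived flow and volume channels
RECOVERY_NOISE = dict(noise_sd_pressure=0.15, noise_sd_flow=5e-4, noise_sd_volume=5e-5)

NOISELESS = dict(noise_sd_pressure=0.0, noise_sd_flow=0.0, noise_sd_volume=0.0)


def make_record(pressure, flow, volume, h=0.01):
    return WaveformRecord(
        pressure=np.asarray(pressure, float),
        flow=np.asarray(flow, float),
        volume=np.asarray(volume, float),
        h=h,
    )


@pytest.fixture(scope="session")
def clean_pc_record():
    """Noise-free 30 s pressure-controlled record, single-compartment truth."""
    cfg = SyntheticConfig(duration=30.0, truth_coefficients=SINGLE_TRUTH, **NOISELESS)
    record, truth = generate_record(cfg)
    return record, truth


@pytest.fixture(scope="session")
def noisy_pc_record():
    """Default-noise 30 s pressure-controlled record."""
    cfg = SyntheticConfig(duration=30.0, truth_coefficients=SINGLE_TRUTH, seed=7)
    record, truth = generate_record(cfg)
    return record, truth


@pytest.fixture(scope="session")
def hybrid_vc_record():
    """Default-noise 30 s volume-controlled record from the hybrid truth."""
    cfg = SyntheticConfig(
        mode="VC",
        duration=30.0,
        truth_model="hybrid",
        truth_coefficients=HYBRID_TRUTH,
        truth_ncps=HYBRID_NCPS,
        seed=1,
    )
    record, truth = generate_record(cfg)
    return record, truth
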
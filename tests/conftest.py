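import numpy as np
import pytest

from cppopt import MonitoringRecord, SimulationConfig, simulate_monitoring


def record_from_means(abp_mean, icp_mean, pulse_abp=40.0, pulse_icp=8.0,
                      sample_period_s=1.0, patient_id="test"):
    """Build a valid MonitoringRecord from mean series alone."""
    abp_mean = np.asarray(abp_mean, float)
    icp_mean = np.asarray(icp_mean, float)
    t = np.arange(abp_mean.size, dtype=float) * sample_period_s
    return MonitoringRecord(
        patient_id=patient_id,
        t=t,
        abp_mean=abp_mean,
        abp_sys=abp_mean + pulse_abp / 2,
        abp_dia=abp_mean - pulse_abp / 2,
        icp_mean=icp_mean,
        icp_sys=icp_mean + pulse_icp / 2,
        icp_dia=icp_mean - pulse_icp / 2,
        sample_period_s=sample_period_s,
    )


@pytest.fixture(scope="session")
def stationary_sim():
    """6 h of stationary monitoring (CPP near the optimum, artifacts on)."""
    cfg = SimulationConfig(duration_s=21600, seed=7)
    record, truth = simulate_monitoring(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def sweep_sim():
    """6 h with CPP sweeping the full ground-truth curve each 2-h window."""
    from cppopt import sweep_config

    cfg = sweep_config(21600, seed=3, bwave_on_fraction=1.0, artifact_rate_per_h=0.0)
    record, truth = simulate_monitoring(cfg)
    return cfg, record, truth
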
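import numpy as np
import pytest

import hbdyn as h


@pytest.fixture(scope="session")
def gradient():
    return h.BicoidGradient()


@pytest.fixture(scope="session")
def nc12_config():
    return h.EmbryoConfig(cycle=12, seed=42)


@pytest.fixture(scope="session")
def nc12_dataset(nc12_config, gradient):
    """One synthetic nc12 embryo: nuclei, traces and ground truth."""
    nuclei = h.assign_birth_times(h.place_nuclei(nc12_config),
                                  nc12_config.wave_speed)
    traces, truth = h.generate_parametric_traces(nuclei, gradient, nc12_config)
    return nuclei, traces, truth


@pytest.fixture(scope="session")
def noiseless_dataset(gradient):
    cfg = h.EmbryoConfig(cycle=12, n_nuclei=60, seed=7)
    params = h.TraceParams(noise_mult_sigma=0.0, noise_add_sigma=0.0)
    nuclei = h.place_nuclei(cfg)
    traces, truth = h.generate_parametric_traces(nuclei, gradient, cfg, params)
    return nuclei, traces, truth


@pytest.fixture(scope="session")
def independent6():
    """Six independent (non-cooperative) sites, boundary occupancy 1/2."""
    kin = h.PromoterKinetics.uniform(6, 1.0)
    return h.calibrate_boundary(kin, observable="occupancy")


@pytest.fixture(scope="session")
def fitted6():
    """Cooperative 6-site model fitted under the pattern constraints."""
    return h.fit_kinetics(6, seed=0, de_maxiter=60, de_popsize=10)
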
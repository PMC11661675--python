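import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polynematic as pn

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def unit_params() -> pn.ModelParams:
    return pn.ModelParams(B=1.0, A=1.0, L=1.0, Gt=1.0, rho0=1.0)


@pytest.fixture(scope="session")
def dna_1000bp_params() -> pn.ModelParams:
    """Reference parameter set for 1000-bp chains at base density (ratios × ρ0)."""
    rho0 = 2.0e-6
    return pn.ModelParams(
        B=0.000800 * rho0, A=0.0513 * rho0, L=5.93 * rho0, Gt=64.0 * rho0, rho0=rho0
    )


def _ideal_gas_configs(n_configs: int, n0: int, box: float, seed: int):
    """Uncorrelated point segments with uniform random orientations."""
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n_configs):
        pos = rng.random((n0, 3)) * box
        cos = 2.0 * rng.random(n0) - 1.0
        sin = np.sqrt(1.0 - cos**2)
        phi = 2.0 * np.pi * rng.random(n0)
        t = np.stack([sin * np.cos(phi), sin * np.sin(phi), cos], axis=1)
        configs.append(
            pn.ChainConfiguration(box=box, positions=pos, directions=t, chain_id=np.arange(n0))
        )
    return configs


@pytest.fixture(scope="session")
def ideal_gas_spectrum() -> pn.FluctuationSpectrum:
    """Shell spectrum of a free-segment gas (flat: rho = 1, xy = 3/20, zz = 1/5)."""
    configs = _ideal_gas_configs(n_configs=60, n0=2048, box=32.0, seed=42)
    return pn.estimate_spectrum(configs, n_shells=8, block_size=10)


@pytest.fixture(scope="session")
def wlc_recovery():
    """Full pipeline on an ideal worm-like-chain ensemble emulating 16-bp dsDNA.

    Study conditions: Ns = 16 segments, bending stiffness εT = 109 (the DNA
    persistence length in base pairs), segment density ρ0 = 2×10⁻⁶ l0⁻³ in a
    reduced periodic box (L0 = 400, Nc = 8 chains), 2000 independent
    configurations.  Returns (spectrum, fit).
    """
    spec = pn.WLCSpec(Ns=16, Nc=8, epsT=109.0, L0=400.0, seed=1, n_configs=2000)
    configs = pn.sample_wlc_ensemble(spec)
    spectrum = pn.estimate_spectrum(configs, n_shells=12, block_size=100)
    fit = pn.fit_model(spectrum, omit_lowest_shell=True)
    return spectrum, fit
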
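"""Synthetic ensembles: worm-like chains, Gaussian field modes, oxDNA fixtures.

Three generators cover every input the analysis pipeline needs:

* :func:`sample_wlc_ensemble` — ideal (non-interacting) discrete worm-like
  chains with per-joint bending energy ``εT(1 − cosθ)`` in a periodic cubic
  box.  The polar angle between consecutive segments has density
  ∝ exp(εT·cosθ)·sinθ, so ⟨cosθ⟩ = coth(εT) − 1/εT (the Langevin function)
  and the orientational correlation decays as ⟨cosθ⟩^d along the chain; for
  εT ≫ 1 the persistence length approaches εT segments.
* :func:`sample_gaussian_modes` — direct draws of the six per-mode amplitudes
  from the continuum model's Gaussian equipartition distribution.  This is the
  statistical oracle: the estimator and fitter applied to its output must
  recover the generating parameters.
* :func:`make_oxdna_fixture` — tiny syntactically valid oxDNA topology +
  configuration pairs (synthetic stand-ins for real trajectories) to exercise
  the reader.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import ModelParams, mode_matrix, theoretical_amplitudes
from .spectrum import OBSERVABLES, ChainConfiguration, FluctuationSpectrum, block_errors

__all__ = [
    "WLCSpec",
    "GaussianFieldSpec",
    "sample_wlc_ensemble",
    "sample_gaussian_modes",
    "synth_spectrum_from_params",
    "make_oxdna_fixture",
    "mean_cos_bend",
]


@dataclasses.dataclass(frozen=True)
class WLCSpec:
    """Recipe for a monodisperse worm-like-chain ensemble.

    ``Ns`` segments (unit length) per chain, ``Nc`` chains, dimensionless
    bending stiffness ``epsT`` (the target persistence length in segments),
    cubic box side ``L0``, ``n_configs`` independent snapshots.
    """

    Ns: int
    Nc: int
    epsT: float
    L0: float
    seed: int = 0
    n_configs: int = 1

    def __post_init__(self) -> None:
        if self.Ns < 1 or self.Nc < 1 or self.n_configs < 1:
            raise ValueError("Ns, Nc and n_configs must all be >= 1")
        if self.epsT < 0 or self.L0 <= 0:
            raise ValueError("epsT must be >= 0 and L0 > 0")

    @property
    def rho0(self) -> float:
        """Segment number density Nc·Ns/L0³."""
        return self.Nc * self.Ns / self.L0**3


@dataclasses.dataclass(frozen=True)
class GaussianFieldSpec:
    """Recipe for direct Gaussian sampling of the model's Fourier modes."""

    params: ModelParams
    q: tuple[float, ...]
    n_draws: int
    seed: int = 0
    block_size: int = 1

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if any(qi <= 0 for qi in self.q):
            raise ValueError("all q must be positive")


def mean_cos_bend(epsT: float) -> float:
    """⟨cosθ⟩ of the bend distribution: the Langevin function coth(εT) − 1/εT."""
    if epsT == 0:
        return 0.0
    return 1.0 / np.tanh(epsT) - 1.0 / epsT


def _sample_cos_theta(rng: np.random.Generator, epsT: float, size) -> np.ndarray:
    """Inverse-CDF sample of cosθ with density ∝ exp(εT·cosθ) on [−1, 1]."""
    u = rng.random(size)
    if epsT == 0:
        return 2.0 * u - 1.0
    # stable for large epsT: cos = 1 + log(u + (1-u) e^{-2 epsT}) / epsT
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * epsT)) / epsT


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    cos = 2.0 * rng.random(n) - 1.0
    sin = np.sqrt(np.clip(1.0 - cos**2, 0.0, None))
    phi = 2.0 * np.pi * rng.random(n)
    return np.stack([sin * np.cos(phi), sin * np.sin(phi), cos], axis=1)


def _rotate_about(prev: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """New unit vectors at polar angle arccos(cos_t), azimuth phi, about prev."""
    helper = np.tile(np.array([0.0, 0.0, 1.0]), (len(prev), 1))
    near_pole = np.abs(prev[:, 2]) > 0.9
    helper[near_pole] = [1.0, 0.0, 0.0]
    u1 = np.cross(prev, helper)
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    u2 = np.cross(prev, u1)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    new = (
        cos_t[:, None] * prev
        + sin_t[:, None] * (np.cos(phi)[:, None] * u1 + np.sin(phi)[:, None] * u2)
    )
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def _one_wlc_config(rng: np.random.Generator, spec: WLCSpec) -> ChainConfiguration:
    Ns, Nc, L0 = spec.Ns, spec.Nc, spec.L0
    dirs = np.empty((Nc, Ns, 3))
    dirs[:, 0] = _uniform_sphere(rng, Nc)
    for k in range(1, Ns):
        cos_t = _sample_cos_theta(rng, spec.epsT, Nc)
        phi = 2.0 * np.pi * rng.random(Nc)
        dirs[:, k] = _rotate_about(dirs[:, k - 1], cos_t, phi)
    start = rng.random((Nc, 3)) * L0
    # vertices v_k = start + sum of previous bonds; segment at bond midpoint
    cum = np.cumsum(dirs, axis=1)
    vertices = start[:, None, :] + np.concatenate(
        [np.zeros((Nc, 1, 3)), cum[:, :-1]], axis=1
    )
    midpoints = (vertices + 0.5 * dirs) % L0
    return ChainConfiguration(
        box=L0,
        positions=midpoints.reshape(Nc * Ns, 3),
        directions=dirs.reshape(Nc * Ns, 3),
        chain_id=np.repeat(np.arange(Nc), Ns),
    )


def sample_wlc_ensemble(spec: WLCSpec) -> list[ChainConfiguration]:
    """Generate independent ideal worm-like-chain snapshots.

    Chains are mutually independent (ideal solution) and snapshots are
    statistically independent (no Monte Carlo time correlation), so block
    averaging over the sequence is exercised but trivially unbiased.
    """
    rng = np.random.default_rng(spec.seed)
    return [_one_wlc_config(rng, spec) for _ in range(spec.n_configs)]


def sample_gaussian_modes(
    spec: GaussianFieldSpec,
    return_draws: bool = False,
):
    """Sample per-mode amplitude vectors from the model's Gaussian distribution.

    For each q the 6-component complex mode vector is drawn with covariance
    ⟨x x†⟩ = ρ0·M(q)⁻¹ per segment (real and imaginary parts independent with
    half the covariance each), exactly the equipartition statistics of the
    continuum model.  Sample amplitudes and block-averaged errors are
    assembled precisely as the configuration-space estimator would report
    them.  Fixed seed → bit-identical output.
    """
    params = spec.params
    rng = np.random.default_rng(spec.seed)
    qs = np.sort(np.asarray(spec.q, dtype=float))
    est = {name: np.empty(len(qs)) for name in OBSERVABLES}
    err = {name: np.empty(len(qs)) for name in OBSERVABLES}
    draws_out = []
    # component order of mode_matrix: (drho, Qzz, Dxxyy, Qxy, Qxz, Qyz)
    idx = {"rho": 0, "zz": 1, "xy": 3, "xz": 4, "yz": 5}
    for i, qi in enumerate(qs):
        M = mode_matrix(qi, params)
        cov = params.rho0 * np.linalg.inv(M)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - params validated upstream
            raise ValueError("mode covariance not positive definite") from exc
        re = rng.standard_normal((spec.n_draws, 6)) @ (chol.T / np.sqrt(2.0))
        im = rng.standard_normal((spec.n_draws, 6)) @ (chol.T / np.sqrt(2.0))
        x = re + 1j * im
        series = {
            name: np.abs(x[:, j]) ** 2 for name, j in idx.items() if name != "rho"
        }
        series["rho"] = np.abs(x[:, 0]) ** 2
        series["cross"] = (x[:, 0] * np.conj(x[:, 1])).real
        for name in OBSERVABLES:
            est[name][i] = series[name].mean()
            err[name][i] = block_errors(series[name], block_size=spec.block_size)
        if return_draws:
            draws_out.append(x)

    spectrum = FluctuationSpectrum(
        q=qs,
        n_qvec=np.ones(len(qs), dtype=int),
        est=est,
        err=err,
        meta={
            "N0": 1.0,
            "rho0": params.rho0,
            "L0": np.nan,
            "n_configs": float(spec.n_draws),
            "block_size": float(spec.block_size),
        },
    )
    return (spectrum, draws_out) if return_draws else spectrum


def synth_spectrum_from_params(
    params: ModelParams,
    q: Sequence[float],
    noise_rel: float | None = None,
    seed: int = 0,
) -> FluctuationSpectrum:
    """Noiseless (or relatively-perturbed) spectrum evaluated from the closed forms.

    With ``noise_rel=None`` the output round-trips through the fitter to
    machine precision (errors set to zero → unweighted fit).  Otherwise each
    estimate is perturbed by seeded Gaussian noise of relative scale
    ``noise_rel`` and the standard errors are set accordingly.
    """
    qs = np.sort(np.asarray(q, dtype=float))
    if np.any(qs <= 0):
        raise ValueError("q values must be positive")
    amp = theoretical_amplitudes(qs, params)
    est = {
        "xy": np.asarray(amp.xy), "xz": np.asarray(amp.xz), "yz": np.asarray(amp.xz).copy(),
        "zz": np.asarray(amp.zz), "rho": np.asarray(amp.rho), "cross": np.asarray(amp.cross),
    }
    if noise_rel is None:
        err = {name: np.zeros(len(qs)) for name in OBSERVABLES}
    else:
        if noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        rng = np.random.default_rng(seed)
        err = {}
        for name in OBSERVABLES:
            scale = np.abs(est[name]) * noise_rel
            # cross can vanish; give it the scale of the zz observable there
            scale = np.where(scale > 0, scale, np.abs(est["zz"]) * noise_rel)
            est[name] = est[name] + rng.normal(0.0, 1.0, len(qs)) * scale
            err[name] = scale
        for name in ("xy", "xz", "yz", "zz", "rho"):
            est[name] = np.clip(est[name], 1e-300, None)
    return FluctuationSpectrum(
        q=qs,
        n_qvec=np.ones(len(qs), dtype=int),
        est=est,
        err=err,
        meta={
            "N0": np.nan,
            "rho0": params.rho0,
            "L0": np.nan,
            "n_configs": 0.0,
            "block_size": 0.0,
        },
    )


def make_oxdna_fixture(
    n_bp: int,
    seed: int,
    path: str | Path,
    box: float = 50.0,
    normals_pm_z: bool = False,
) -> tuple[Path, Path]:
    """Write a minimal synthetic oxDNA topology/configuration duplex fixture.

    Two antiparallel complementary strands (polyG/polyC) of ``n_bp``
    nucleotides each; base-pair centres follow a gently bending path, strand
    positions sit symmetrically off-centre so the pair midpoint reconstructs
    the centre exactly, and the two strands' base normals are exactly
    antiparallel (±a3), making the reader's direction estimate equal a3.

    Returns (topology_path, configuration_path).
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    rng = np.random.default_rng(seed)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    # base-pair centres along a mildly wiggly path
    axis = _uniform_sphere(rng, 1)[0]
    centres = np.empty((n_bp, 3))
    centres[0] = box / 2.0 + rng.normal(0, 1, 3)
    a3 = np.empty((n_bp, 3))
    a3[0] = np.array([0.0, 0.0, 1.0]) if normals_pm_z else axis
    for i in range(1, n_bp):
        if normals_pm_z:
            a3[i] = [0.0, 0.0, 1.0]
        else:
            wob = a3[i - 1] + 0.1 * rng.normal(0, 1, 3)
            a3[i] = wob / np.linalg.norm(wob)
        centres[i] = centres[i - 1] + a3[i]
    offset = np.cross(a3, np.tile([1.0, 0.0, 0.0], (n_bp, 1)))
    bad = np.linalg.norm(offset, axis=1) < 1e-6
    offset[bad] = np.cross(a3[bad], np.tile([0.0, 1.0, 0.0], (bad.sum(), 1)))
    offset *= 0.4 / np.linalg.norm(offset, axis=1, keepdims=True)

    sign = rng.choice([-1.0, 1.0], size=n_bp) if normals_pm_z else np.ones(n_bp)
    a3_s1 = a3 * sign[:, None]

    top_path = path / "fixture.top"
    conf_path = path / "fixture.conf"

    lines = [f"{2 * n_bp} 2"]
    for i in range(n_bp):  # strand 1: polyG, 3'->5'
        lines.append(f"1 G {i - 1} {i + 1 if i < n_bp - 1 else -1}")
    for j in range(n_bp):  # strand 2: polyC
        prev = n_bp + j - 1 if j > 0 else -1
        nxt = n_bp + j + 1 if j < n_bp - 1 else -1
        lines.append(f"2 C {prev} {nxt}")
    top_path.write_text("\n".join(lines) + "\n")

    def _row(pos, a1, a3v) -> str:
        vals = [*pos, *a1, *a3v, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        return " ".join(f"{v:.9f}" for v in vals)

    rows = ["t = 0", f"b = {box:g} {box:g} {box:g}", "E = 0 0 0"]
    a1 = np.tile([1.0, 0.0, 0.0], (n_bp, 1))
    for i in range(n_bp):  # strand 1
        rows.append(_row(centres[i] + offset[i], a1[i], a3_s1[i]))
    for j in range(n_bp):  # strand 2, reverse order, antiparallel normals
        i = n_bp - 1 - j
        rows.append(_row(centres[i] - offset[i], -a1[i], -a3_s1[i]))
    conf_path.write_text("\n".join(rows) + "\n")
    return top_path, conf_path
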
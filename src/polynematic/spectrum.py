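"""Fluctuation-spectrum estimation from segmented-chain configurations.

For each lattice-commensurate wavevector ``q = (2π/L0)·n`` the estimator
accumulates the discrete Fourier sums ``δa(q) = Σ_s a_s e^{-iq·r_s}`` over all
segments, with per-segment weights

    a_s = 1                                   (density δρ)
    a_s = [3(t_s·ê_z)² − 1]/2                 (ρ0δQzz)
    a_s = 3(t_s·ê_x)(t_s·ê_z)/2               (ρ0δQxz), similarly yz
    a_s = 3(t_s·ê_x)(t_s·ê_y)/2               (ρ0δQxy)

where (ê_x, ê_y, ê_z) is a per-wavevector orthonormal frame with ê_z = q̂ and
ê_x obtained by Gram–Schmidt projection of a box axis.  The per-mode
correlation of observables a, b is

    (1/N0) [C_a C_b + S_a S_b],   C = Σ a_s cos(q·r_s), S = Σ a_s sin(q·r_s),

i.e. (1/N0)·Re[δa(q) δb(q)*].  Wavevectors are pooled over spherical shells of
width Δq = 2π/L0 (q = 0 excluded), averaged per configuration first and then
over the ensemble; standard errors come from block averaging over the
configuration sequence.

All weights are even under t → −t, so the estimator is apolar: the sign
convention of segment directions cannot matter.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OBSERVABLES",
    "ChainConfiguration",
    "QFrame",
    "FluctuationSpectrum",
    "qframe_axes",
    "segment_weights",
    "mode_correlation",
    "lattice_wavevectors",
    "estimate_spectrum",
    "block_errors",
    "orientation_decorrelation",
]

#: Observables reported per shell, in canonical column order.
OBSERVABLES = ("xy", "xz", "yz", "zz", "rho", "cross")

_BOX_AXES = (np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])


@dataclasses.dataclass
class ChainConfiguration:
    """One snapshot of an ensemble of segmented chains in a periodic cubic box.

    Attributes
    ----------
    box : float
        Cubic box side L0 (l0 units).
    positions : (N0, 3) array
        Segment positions r_s.
    directions : (N0, 3) array
        Unit segment direction vectors t_s (sign convention irrelevant).
    chain_id : (N0,) int array
        Chain membership; each chain's segments must be stored contiguously
        and in order along the chain.
    """

    box: float
    positions: np.ndarray
    directions: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.chain_id = np.asarray(self.chain_id)
        if self.box <= 0:
            raise ValueError(f"box side must be positive, got {self.box}")
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.directions.shape != (n, 3):
            raise ValueError("positions and directions must both be (N0, 3)")
        if self.chain_id.shape != (n,):
            raise ValueError("chain_id must be length N0")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            worst = float(np.abs(norms - 1.0).max())
            raise ValueError(f"directions must be unit vectors (worst |t|-1 = {worst:.2e})")
        # contiguous chains: ids must not reappear after a different id
        ids = self.chain_id
        if n > 1:
            changes = ids[1:] != ids[:-1]
            seen_ids = ids[np.concatenate(([True], changes))]
            if len(np.unique(seen_ids)) != len(seen_ids):
                raise ValueError("chain segments must be contiguous per chain")

    @property
    def n_segments(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    @property
    def density(self) -> float:
        return self.n_segments / self.box**3


@dataclasses.dataclass(frozen=True)
class QFrame:
    """Right-handed orthonormal triad with ê_z along the wavevector."""

    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray


def qframe_axes(qvec: Sequence[float], reference_axis: Sequence[float] = (1.0, 0.0, 0.0)) -> QFrame:
    """Build the per-wavevector frame: ê_z = q̂, ê_x by Gram–Schmidt, ê_y = ê_z × ê_x.

    If the reference axis is (numerically) parallel to q̂ the next box axes
    (0,1,0) then (0,0,1) are tried, deterministically.
    """
    q = np.asarray(qvec, dtype=float)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise ValueError("qvec must be nonzero")
    ez = q / qn
    candidates = [np.asarray(reference_axis, dtype=float), *_BOX_AXES]
    for ref in candidates:
        perp = ref - (ref @ ez) * ez
        norm = np.linalg.norm(perp)
        if norm > 1e-8:
            ex = perp / norm
            ey = np.cross(ez, ex)
            return QFrame(ex=ex, ey=ey, ez=ez)
    raise RuntimeError("no valid reference axis found")  # pragma: no cover


def segment_weights(t: np.ndarray, frame: QFrame) -> dict[str, np.ndarray]:
    """Per-segment Fourier weights for the five observables in a given frame.

    ``t`` may be a single vector or an (N, 3) array.  Returns arrays keyed by
    observable name; all weights are even in t.
    """
    t = np.asarray(t, dtype=float)
    single = t.ndim == 1
    t = np.atleast_2d(t)
    tx, ty, tz = t @ frame.ex, t @ frame.ey, t @ frame.ez
    w = {
        "rho": np.ones_like(tz),
        "zz": 1.5 * tz**2 - 0.5,
        "xz": 1.5 * tx * tz,
        "yz": 1.5 * ty * tz,
        "xy": 1.5 * tx * ty,
    }
    return {k: (float(v[0]) if single else v) for k, v in w.items()}


def _check_commensurate(qvec: np.ndarray, box: float) -> None:
    n = np.asarray(qvec, float) * box / (2.0 * np.pi)
    if not np.allclose(n, np.round(n), atol=1e-9):
        raise ValueError(
            f"wavevector {qvec} is not commensurate with box side {box} "
            "(components must be integer multiples of 2*pi/L0)"
        )


def mode_correlation(
    config: ChainConfiguration,
    qvec: Sequence[float],
    weights_a: np.ndarray,
    weights_b: np.ndarray,
) -> float:
    """One-configuration contribution (1/N0)[C_a C_b + S_a S_b] at one wavevector.

    Non-negative for a = b.  Rejects wavevectors incommensurate with the
    periodic box, for which the Fourier sum would break periodicity.
    """
    qvec = np.asarray(qvec, dtype=float)
    _check_commensurate(qvec, config.box)
    phase = config.positions @ qvec
    c, s = np.cos(phase), np.sin(phase)
    wa = np.asarray(weights_a, dtype=float)
    wb = np.asarray(weights_b, dtype=float)
    return float((wa @ c) * (wb @ c) + (wa @ s) * (wb @ s)) / config.n_segments


def lattice_wavevectors(box: float, qmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer-lattice wavevectors with 0 < |q| <= qmax, one per ±q pair.

    Returns (integer triples (M, 3), q vectors (M, 3)).  Since the estimator's
    correlations are identical at q and −q, only one representative of each
    inversion pair is enumerated.
    """
    dq = 2.0 * np.pi / box
    nmax = int(np.floor(qmax / dq + 1e-9))
    if nmax < 1:
        raise ValueError(f"qmax={qmax} below the smallest lattice wavenumber {dq}")
    rng = np.arange(-nmax, nmax + 1)
    nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
    n = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
    n2 = (n**2).sum(axis=1)
    keep = (n2 > 0) & (n2 <= (nmax + 1e-9) ** 2)
    # one representative per {n, -n}: first nonzero component positive
    pos = (n[:, 2] > 0) | ((n[:, 2] == 0) & (n[:, 1] > 0)) | (
        (n[:, 2] == 0) & (n[:, 1] == 0) & (n[:, 0] > 0)
    )
    keep &= pos
    n = n[keep]
    return n, n * dq


@dataclasses.dataclass
class FluctuationSpectrum:
    """Shell-averaged fluctuation observables ± standard errors versus q.

    ``q`` holds the mean wavenumber of the lattice vectors pooled in each
    shell (strictly increasing, q = 0 excluded), ``n_qvec`` the number of
    pooled ±q pairs.  ``est``/``err`` map observable name → per-shell arrays;
    an error entry of NaN means "not estimable" (fewer than two blocks).
    ``meta`` carries N0, rho0, L0, n_configs and block_size.
    """

    q: np.ndarray
    n_qvec: np.ndarray
    est: dict[str, np.ndarray]
    err: dict[str, np.ndarray]
    meta: dict[str, float]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("shell q values must be positive and strictly increasing")
        for name in OBSERVABLES:
            if name not in self.est:
                raise ValueError(f"missing observable {name!r}")
        for name in ("xy", "xz", "yz", "zz", "rho"):
            if np.any(self.est[name] < 0):
                raise ValueError(f"estimate of {name!r} must be non-negative")
        for name, e in self.err.items():
            if np.any(e[np.isfinite(e)] < 0):
                raise ValueError(f"stderr of {name!r} must be non-negative")

    @property
    def n_shells(self) -> int:
        return len(self.q)

    @property
    def rho0(self) -> float:
        return float(self.meta["rho0"])

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"q": self.q, "n_qvec": self.n_qvec}
        for name in OBSERVABLES:
            cols[name] = self.est[name]
            cols[f"{name}_err"] = self.err[name]
        return pd.DataFrame(cols)


def block_errors(series: np.ndarray, block_size: int = 100) -> np.ndarray:
    """Standard error of the mean of a (possibly correlated) series by block averaging.

    The series (first axis = time/configuration index) is cut into
    ``floor(n/block_size)`` full blocks; the result is the sample standard
    deviation of the block means divided by sqrt(n_blocks).  NaN where fewer
    than two blocks are available.
    """
    series = np.asarray(series, dtype=float)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = series.shape[0]
    nb = n // block_size
    if nb < 2:
        return np.full(series.shape[1:], np.nan) if series.ndim > 1 else np.nan
    trimmed = series[: nb * block_size]
    blocks = trimmed.reshape(nb, block_size, *series.shape[1:]).mean(axis=1)
    return blocks.std(axis=0, ddof=1) / np.sqrt(nb)


def _axis_phases(coord: np.ndarray, dq: float, nmax: int) -> np.ndarray:
    """exp(-i·dq·n·x) for n = -nmax..nmax (row index n + nmax)."""
    return np.exp(-1j * dq * np.outer(np.arange(-nmax, nmax + 1), coord))


def _config_shell_values(
    config: ChainConfiguration,
    n_int: np.ndarray,
    frames: tuple[np.ndarray, np.ndarray, np.ndarray],
    shell_idx: np.ndarray,
    n_shells: int,
) -> np.ndarray:
    """Per-shell averages of the six observables for one configuration.

    The Fourier sums of all five weight fields are obtained from the
    second-moment tensor G_ij(q) = Σ_s t_i t_j e^{-iq·r_s}: since the
    weights are quadratic in t (and Σ_i t_i² = 1 gives the density sum as
    tr G), the per-wavevector sums reduce to frame contractions of G.
    """
    ex, ey, ez = frames
    dq = 2.0 * np.pi / config.box
    nmax = int(np.abs(n_int).max())

    # e^{-iq.r} via separable per-axis phase tables (gathers + in-place products)
    E = _axis_phases(config.positions[:, 0], dq, nmax)[n_int[:, 0] + nmax]
    E *= _axis_phases(config.positions[:, 1], dq, nmax)[n_int[:, 1] + nmax]
    E *= _axis_phases(config.positions[:, 2], dq, nmax)[n_int[:, 2] + nmax]

    t = config.directions
    P = (t[:, :, None] * t[:, None, :]).reshape(config.n_segments, 9)  # t_i t_j
    G = (E.real @ P) + 1j * (E.imag @ P)  # (M, 9) -> G_ij(q)
    G = G.reshape(-1, 3, 3)

    F_rho = np.einsum("mii->m", G)  # tr G = Σ_s e^{-iq·r_s} since |t_s| = 1
    contract = lambda u, v: np.einsum("mi,mij,mj->m", u, G, v)
    F = {
        "xy": 1.5 * contract(ex, ey),
        "xz": 1.5 * contract(ex, ez),
        "yz": 1.5 * contract(ey, ez),
        "zz": 1.5 * contract(ez, ez) - 0.5 * F_rho,
    }

    inv_n0 = 1.0 / config.n_segments
    vals = np.empty((n_int.shape[0], len(OBSERVABLES)))
    for j, name in enumerate(OBSERVABLES):
        if name == "rho":
            v = np.abs(F_rho) ** 2
        elif name == "cross":
            v = (F_rho * np.conj(F["zz"])).real
        else:
            v = np.abs(F[name]) ** 2
        vals[:, j] = v * inv_n0

    counts = np.bincount(shell_idx, minlength=n_shells)
    out = np.empty((n_shells, len(OBSERVABLES)))
    for j in range(len(OBSERVABLES)):
        out[:, j] = np.bincount(shell_idx, weights=vals[:, j], minlength=n_shells) / counts
    return out


def estimate_spectrum(
    configs: Iterable[ChainConfiguration],
    qmax: float | None = None,
    n_shells: int = 15,
    block_size: int = 100,
    reference_axis: Sequence[float] = (1.0, 0.0, 0.0),
) -> FluctuationSpectrum:
    """Estimate the five shell-averaged fluctuation observables from an ensemble.

    Parameters
    ----------
    configs : iterable of ChainConfiguration
        Snapshots; all must share the same box side and segment count.
    qmax : float, optional
        Largest wavenumber; defaults to ``n_shells`` shells of width
        Δq = 2π/L0 (the low-q regime where the continuum model applies).
    n_shells : int
        Number of shells when ``qmax`` is not given.
    block_size : int
        Block length for the block-averaged standard errors.  If fewer than
        two blocks are available the errors are reported as NaN.
    reference_axis : length-3 sequence
        Box axis used to seed the per-wavevector frames.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("need at least one configuration")
    box = configs[0].box
    n0 = configs[0].n_segments
    for c in configs:
        if not np.isclose(c.box, box) or c.n_segments != n0:
            raise ValueError("all configurations must share the same box and N0")

    dq = 2.0 * np.pi / box
    if qmax is None:
        qmax = n_shells * dq
    n_int, qvecs = lattice_wavevectors(box, qmax)
    qmag = np.linalg.norm(qvecs, axis=1)
    # shell k (0-based) covers (k*dq, (k+1)*dq]
    shell_idx = np.ceil(qmag / dq - 1e-9).astype(int) - 1
    n_shell_total = int(shell_idx.max()) + 1

    ez = qvecs / qmag[:, None]
    ref = np.asarray(reference_axis, dtype=float)
    frames_list = [qframe_axes(qv, ref) for qv in qvecs] if len(qvecs) < 64 else None
    if frames_list is None:
        # vectorised Gram-Schmidt with deterministic fallback axes
        ex = np.empty_like(ez)
        remaining = np.ones(len(ez), dtype=bool)
        for cand in [ref, *_BOX_AXES]:
            if not remaining.any():
                break
            perp = cand[None, :] - (ez @ cand)[:, None] * ez
            norm = np.linalg.norm(perp, axis=1)
            ok = remaining & (norm > 1e-8)
            ex[ok] = perp[ok] / norm[ok, None]
            remaining &= ~ok
        ey = np.cross(ez, ex)
    else:
        ex = np.array([f.ex for f in frames_list])
        ey = np.array([f.ey for f in frames_list])

    per_config = np.empty((len(configs), n_shell_total, len(OBSERVABLES)))
    for i, cfg in enumerate(configs):
        per_config[i] = _config_shell_values(cfg, n_int, (ex, ey, ez), shell_idx, n_shell_total)

    est_arr = per_config.mean(axis=0)
    err_arr = block_errors(per_config, block_size=block_size)
    if np.isscalar(err_arr) or err_arr.shape != est_arr.shape:
        err_arr = np.full_like(est_arr, np.nan)

    counts = np.bincount(shell_idx, minlength=n_shell_total)
    qshell = np.bincount(shell_idx, weights=qmag, minlength=n_shell_total) / counts

    est = {name: est_arr[:, j] for j, name in enumerate(OBSERVABLES)}
    err = {name: err_arr[:, j] for j, name in enumerate(OBSERVABLES)}
    return FluctuationSpectrum(
        q=qshell,
        n_qvec=counts,
        est=est,
        err=err,
        meta={
            "N0": float(n0),
            "rho0": n0 / box**3,
            "L0": float(box),
            "n_configs": float(len(configs)),
            "block_size": float(block_size),
        },
    )


def orientation_decorrelation(
    configs: Iterable[ChainConfiguration],
    initial: ChainConfiguration,
) -> np.ndarray:
    """Mean projection of chain end-to-end directions onto the initial ones.

    End-to-end vectors are taken as the sum of segment direction vectors per
    chain (robust under periodic wrapping).  Chains whose end-to-end vector
    vanishes in either snapshot are skipped.  Values lie in [−1, 1]; an
    equilibrated, decorrelated ensemble fluctuates around 0 with spread
    ~ Nc^(−1/2).
    """

    def _unit_e2e(cfg: ChainConfiguration) -> dict:
        out = {}
        for cid in np.unique(cfg.chain_id):
            v = cfg.directions[cfg.chain_id == cid].sum(axis=0)
            n = np.linalg.norm(v)
            out[cid] = v / n if n > 1e-12 else None
        return out

    e0 = _unit_e2e(initial)
    series = []
    for cfg in configs:
        e = _unit_e2e(cfg)
        dots = [
            float(e[cid] @ e0[cid])
            for cid in e0
            if cid in e and e[cid] is not None and e0[cid] is not None
        ]
        if not dots:
            raise ValueError("no chains with finite end-to-end vectors in common")
        series.append(float(np.mean(dots)))
    return np.asarray(series)
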
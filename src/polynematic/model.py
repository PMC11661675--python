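"""Quadratic continuum free-energy model of an isotropic linear-polymer solution.

The model couples variations of the relative segment density ``δρ̃ = δρ/ρ0``
to the nematic order tensor ``δQij`` (symmetric, traceless; zero in the
isotropic equilibrium).  Per unit volume, in units of ``kBT`` and the segment
length ``l0``::

    f = (1/2) B δρ̃² + (1/2) A δQij² + (1/2) L (∂k δQij)²
        + (1/2) G̃ [∂j δQij + (1/2) ∂i δρ̃]²

with ``G̃ = G ((2/3) ρ0 l0)²``.  The last term penalises the sources of the
tensorial chain-continuity law and is the density–nematic coupling: it is a
perfect square, so positivity of B, A and non-negativity of L, G̃ make every
Fourier mode's quadratic form positive definite.

For a single Fourier mode with wavevector along the mode's local z axis the
degrees of freedom are ``(δρ̃, Qzz, Qxx−Qyy, Qxy, Qxz, Qyz)`` and the free
energy is ``(1/2) xᵀ M(q) x``; equipartition then gives the five measurable
fluctuation amplitudes as entries of ``ρ0 M(q)⁻¹``.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy.constants import k as BOLTZMANN_J_PER_K

__all__ = [
    "ModelParams",
    "UnitSystem",
    "AmplitudeSet",
    "MODE_COMPONENTS",
    "free_energy_density",
    "mode_matrix",
    "theoretical_amplitudes",
    "to_si",
    "from_si",
]

#: Ordering of the per-mode degrees of freedom used by :func:`mode_matrix`.
MODE_COMPONENTS = ("drho", "Qzz", "Dxxyy", "Qxy", "Qxz", "Qyz")


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Parameters of the continuum model, in kBT / l0 units.

    Attributes
    ----------
    B : float
        Concentration susceptibility (solution) / bulk modulus (melt),
        kBT·l0⁻³.
    A : float
        Nematic order modulus ("stiffness" of nematic order), kBT·l0⁻³.
    L : float
        Single isotropic-phase nematic elastic constant, kBT·l0⁻¹.
    Gt : float
        Density–nematic coupling strength G̃ = G·((2/3)ρ0l0)², kBT·l0⁻¹.
    rho0 : float
        Equilibrium segment number density, l0⁻³.
    """

    B: float
    A: float
    L: float
    Gt: float
    rho0: float

    def __post_init__(self) -> None:
        if not (self.B > 0 and self.A > 0):
            raise ValueError(f"B and A must be positive (got B={self.B}, A={self.A})")
        if self.L < 0 or self.Gt < 0:
            raise ValueError(f"L and Gt must be >= 0 (got L={self.L}, Gt={self.Gt})")
        if not self.rho0 > 0:
            raise ValueError(f"rho0 must be positive (got {self.rho0})")
        for name in ("B", "A", "L", "Gt", "rho0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def G(self) -> float:
        """Raw (unscaled) coupling constant G = G̃ / ((2/3)ρ0)², with l0 = 1."""
        return self.Gt / ((2.0 / 3.0) * self.rho0) ** 2

    @property
    def G_prime(self) -> float:
        """Coupling constant of the induced-order equation, G' = G̃/ρ0²."""
        return self.Gt / self.rho0**2

    def ratios(self) -> dict[str, float]:
        """The density-normalised parameter set {A/ρ0, L/ρ0, G̃/ρ0, B/ρ0}."""
        return {
            "A/rho0": self.A / self.rho0,
            "L/rho0": self.L / self.rho0,
            "Gt/rho0": self.Gt / self.rho0,
            "B/rho0": self.B / self.rho0,
        }

    def to_dict(self) -> dict[str, float]:
        return {"B": self.B, "A": self.A, "L": self.L, "Gt": self.Gt, "rho0": self.rho0}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(B=d["B"], A=d["A"], L=d["L"], Gt=d["Gt"], rho0=d["rho0"])

    def to_json(self, units: "UnitSystem | None" = None) -> str:
        payload: dict = self.to_dict()
        units = units or UnitSystem()
        payload["units"] = {"l0_nm": units.l0 * 1e9, "T_K": units.T}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


@dataclasses.dataclass(frozen=True)
class UnitSystem:
    """Conversion between the dimensionless (kBT, l0) units and SI.

    Defaults correspond to B-form dsDNA at 25 °C: one segment = one base
    pair, l0 = 0.34 nm, and a reference segment density of 2.5×10²⁸ m⁻³.
    """

    l0: float = 0.34e-9  # segment length, m
    T: float = 298.16  # temperature, K
    rho_si_unit: float = 2.5e28  # reference SI density, m^-3

    def __post_init__(self) -> None:
        if self.l0 <= 0 or self.T <= 0 or self.rho_si_unit <= 0:
            raise ValueError("l0, T and rho_si_unit must all be positive")

    @property
    def energy_unit(self) -> float:
        """kB·T in joules — the unit of the ratios A/ρ0 and B/ρ0."""
        return BOLTZMANN_J_PER_K * self.T

    @property
    def elastic_unit(self) -> float:
        """kB·T·l0² in J·m² — the unit of the ratios L/ρ0 and G̃/ρ0."""
        return self.energy_unit * self.l0**2


@dataclasses.dataclass(frozen=True)
class AmplitudeSet:
    """The five dimensionless fluctuation amplitudes at one (or many) q.

    ``xy`` = ⟨|ρ0δQxy|²⟩/N0, ``xz`` = ⟨|ρ0δQ{xz,yz}|²⟩/N0,
    ``zz`` = ⟨|ρ0δQzz|²⟩/N0, ``rho`` = ⟨|δρ|²⟩/N0 and
    ``cross`` = Re⟨δρ* ρ0δQzz⟩/N0.
    """

    xy: np.ndarray | float
    xz: np.ndarray | float
    zz: np.ndarray | float
    rho: np.ndarray | float
    cross: np.ndarray | float

    def as_dict(self) -> dict[str, np.ndarray | float]:
        return dataclasses.asdict(self)


def _check_symmetric_traceless(Q: np.ndarray, *, what: str, atol: float = 1e-8) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.shape[-2:] != (3, 3):
        raise ValueError(f"{what} must have trailing shape (3, 3), got {Q.shape}")
    if not np.allclose(Q, np.swapaxes(Q, -1, -2), atol=atol):
        raise ValueError(f"{what} must be symmetric")
    if not np.allclose(np.trace(Q, axis1=-2, axis2=-1), 0.0, atol=atol):
        raise ValueError(f"{what} must be traceless")


def free_energy_density(
    params: ModelParams,
    drho: float = 0.0,
    Q: np.ndarray | None = None,
    grad_drho: Sequence[float] | None = None,
    grad_Q: np.ndarray | None = None,
) -> float:
    """Evaluate the local free-energy density f (kBT·l0⁻³) for given fields.

    Parameters
    ----------
    drho : float
        Relative density variation δρ̃ = δρ/ρ0 at the point.
    Q : (3, 3) array, optional
        Nematic order tensor variation δQij; must be symmetric traceless.
    grad_drho : length-3 sequence, optional
        Gradient ∂i δρ̃.
    grad_Q : (3, 3, 3) array, optional
        Gradient ∂k δQij, indexed ``grad_Q[k, i, j]``; each slice along the
        first axis must be symmetric traceless.

    Returns
    -------
    float
        The sum of the four quadratic terms; non-negative, zero only at the
        uniform isotropic state.
    """
    f = 0.5 * params.B * float(drho) ** 2

    if Q is not None:
        _check_symmetric_traceless(Q, what="Q")
        f += 0.5 * params.A * float(np.sum(np.asarray(Q, float) ** 2))

    gQ = None
    if grad_Q is not None:
        gQ = np.asarray(grad_Q, dtype=float)
        if gQ.shape != (3, 3, 3):
            raise ValueError(f"grad_Q must have shape (3, 3, 3), got {gQ.shape}")
        _check_symmetric_traceless(gQ, what="each grad_Q[k]")
        f += 0.5 * params.L * float(np.sum(gQ**2))

    # Coupling term: (1/2) G̃ |∂j δQij + (1/2) ∂i δρ̃|²  (a perfect square).
    v = np.zeros(3)
    if gQ is not None:
        v += np.einsum("jij->i", gQ)
    if grad_drho is not None:
        gd = np.asarray(grad_drho, dtype=float)
        if gd.shape != (3,):
            raise ValueError("grad_drho must be a length-3 vector")
        v += 0.5 * gd
    f += 0.5 * params.Gt * float(v @ v)

    if not np.isfinite(f):
        raise ValueError("free energy evaluated to a non-finite value")
    return f


def mode_matrix(q: float, params: ModelParams) -> np.ndarray:
    """Quadratic-form matrix M(q) of one Fourier mode, f(q) = (1/2) xᵀ M x.

    The component ordering is :data:`MODE_COMPONENTS`:
    ``x = (δρ̃, Qzz, Qxx−Qyy, Qxy, Qxz, Qyz)`` with the wavevector along the
    mode's z axis.  Uses the tensor-sum identity
    ``δQij² = (3/2)Qzz² + (Qxx−Qyy)²/2 + 2(Qxy² + Qxz² + Qyz²)``.

    Positive definite for every valid :class:`ModelParams` and q ≥ 0.
    """
    if q < 0:
        raise ValueError(f"q must be non-negative, got {q}")
    q2 = q * q
    aL = params.A + params.L * q2
    M = np.zeros((6, 6))
    M[0, 0] = params.B + params.Gt * q2 / 4.0
    M[0, 1] = M[1, 0] = params.Gt * q2 / 2.0
    M[1, 1] = 1.5 * aL + params.Gt * q2
    M[2, 2] = 0.5 * aL
    M[3, 3] = 2.0 * aL
    M[4, 4] = M[5, 5] = 2.0 * (params.A + (params.L + params.Gt / 2.0) * q2)
    return M


def theoretical_amplitudes(q: np.ndarray | float, params: ModelParams) -> AmplitudeSet:
    """Closed-form fluctuation amplitudes of the model at wavenumber(s) q.

    Defined as ρ0 × the corresponding entries of ``mode_matrix(q)⁻¹`` (the
    equipartition result); evaluated here through the analytic inverse of the
    block-diagonal matrix, which is vectorised over q.

    Limits: ``xy = ρ0/(2(A+Lq²))``, ``rho(0) = ρ0/B``, ``zz(0) = 2ρ0/(3A)``,
    ``cross(0) = 0`` and ``zz(0)/xy(0) = 4/3``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    q2 = q * q
    aL = params.A + params.L * q2
    # (δρ̃, Qzz) 2x2 block.
    b11 = params.B + params.Gt * q2 / 4.0
    b22 = 1.5 * aL + params.Gt * q2
    b12 = params.Gt * q2 / 2.0
    det = b11 * b22 - b12 * b12
    rho0 = params.rho0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = AmplitudeSet(
            xy=rho0 / (2.0 * aL),
            xz=rho0 / (2.0 * (params.A + (params.L + params.Gt / 2.0) * q2)),
            zz=rho0 * b11 / det,
            rho=rho0 * b22 / det,
            cross=-rho0 * b12 / det,
        )
    if q.ndim == 0:
        return AmplitudeSet(**{k: float(v) for k, v in out.as_dict().items()})
    return out


def to_si(
    params: ModelParams,
    units: UnitSystem | None = None,
    density_multiple: float = 1.0,
) -> dict[str, float]:
    """Convert a dimensionless parameter set to SI values.

    The ratios ``X/ρ0`` convert with kBT (A, B) or kBT·l0² (L, G̃); absolute
    values additionally multiply by ``rho_si_unit × density_multiple``.
    Returns a flat report; keys ending in ``_per_rho0`` are the intensive
    ratios (J or J·m²), bare keys the absolute values (J·m⁻³ for A and B,
    N = J·m⁻¹ for L and G̃).
    """
    units = units or UnitSystem()
    rho_si = units.rho_si_unit * density_multiple
    r = params.ratios()
    return {
        "A_per_rho0_J": r["A/rho0"] * units.energy_unit,
        "B_per_rho0_J": r["B/rho0"] * units.energy_unit,
        "L_per_rho0_Jm2": r["L/rho0"] * units.elastic_unit,
        "Gt_per_rho0_Jm2": r["Gt/rho0"] * units.elastic_unit,
        "A_J_per_m3": r["A/rho0"] * units.energy_unit * rho_si,
        "B_J_per_m3": r["B/rho0"] * units.energy_unit * rho_si,
        "L_N": r["L/rho0"] * units.elastic_unit * rho_si,
        "Gt_N": r["Gt/rho0"] * units.elastic_unit * rho_si,
        "rho0_per_m3": rho_si,
        "density_multiple": density_multiple,
    }


def from_si(
    report: dict[str, float],
    rho0: float,
    units: UnitSystem | None = None,
) -> ModelParams:
    """Invert :func:`to_si` given the dimensionless density ρ0 (l0⁻³ units)."""
    units = units or UnitSystem()
    return ModelParams(
        B=report["B_per_rho0_J"] / units.energy_unit * rho0,
        A=report["A_per_rho0_J"] / units.energy_unit * rho0,
        L=report["L_per_rho0_Jm2"] / units.elastic_unit * rho0,
        Gt=report["Gt_per_rho0_Jm2"] / units.elastic_unit * rho0,
        rho0=rho0,
    )
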
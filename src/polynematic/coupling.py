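"""Chain-length dependence of the density–nematic coupling.

The coupling strength of the continuum model has a microscopic interpretation:
gradients of ``ρ Qij`` must be paid for by chain ends (entropic cost, density
``ρ0± = 2ρ0/Ns``) or by chain bending (cost set by the dimensionless bending
stiffness εT, which equals the persistence length in segment units).  Treating
both source types as independent ideal gases and averaging over their
realisations yields the crossover law

    G = (3/2) (1/ρ0) (1/Ns + 1/εT)⁻¹,
    G̃/ρ0 = (2/3) (1/Ns + 1/εT)⁻¹,

interpolating between the stiff regime G ≈ (3/2)Ns/ρ0 (chain-end dominated)
and the flexible regime G ≈ (3/2)εT/ρ0 (curvature dominated).  Fitting the law
to measured G̃/ρ0(Ns) data with εT as the only free parameter estimates the
persistence length.

This module also provides the reciprocal scaling law ``a·(1/Ns + 1/b)`` used
for the nematic modulus ratio A/ρ0, the ideal-chain compressibility check
B/ρ0 ≈ 1/Ns, and a packaged table of reference parameter values for dsDNA
(per-density ratios at chain lengths 16–5000 bp) so the printed-data analyses
run without any simulation stage.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fitting import FitResult
from .model import ModelParams

__all__ = [
    "SourceDensities",
    "CouplingLawFit",
    "ScalingFit",
    "load_reference_table",
    "reference_ratio_series",
    "source_penalty_energies",
    "coupling_strength_G",
    "gt_over_rho0",
    "fit_persistence_length",
    "fit_reciprocal_law",
    "compressibility_scaling_check",
    "coupling_report",
]


@dataclasses.dataclass(frozen=True)
class SourceDensities:
    """Magnitudes of the two source densities of the continuity law.

    ``g``: chain-end direction density (l0⁻³); ``k_density``: deflection
    density ρ0·l0·k (l0⁻³); ``rho_ends``: chain-end number density
    ρ0± = 2ρ0/Ns.
    """

    g: float
    k_density: float
    rho_ends: float


@dataclasses.dataclass(frozen=True)
class CouplingLawFit:
    """Persistence length εT (segments) fitted through the crossover law."""

    epsT: float
    points: tuple[tuple[float, float], ...]
    residual_norm: float

    def __post_init__(self) -> None:
        if not self.epsT > 0:
            raise ValueError("fitted epsT must be positive")


@dataclasses.dataclass(frozen=True)
class ScalingFit:
    """Reciprocal law value = a·(1/Ns + 1/b)."""

    a: float
    b: float
    residual_norm: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be positive")


def load_reference_table() -> pd.DataFrame:
    """Packaged reference table of fitted dsDNA model-parameter ratios.

    Columns: ``quantity`` (one of A/rho0, L/rho0, Gt/rho0, B/rho0),
    ``density_multiple`` (1, 20, 100 × the base density 2×10⁻⁶ l0⁻³),
    ``Ns`` (chain length in base pairs) and ``value`` (dimensionless ratio).
    """
    with resources.files("polynematic.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def reference_ratio_series(
    quantity: str, density_multiple: float = 1
) -> list[tuple[float, float]]:
    """(Ns, value) pairs for one quantity at one density from the packaged table."""
    tab = load_reference_table()
    sel = tab[(tab["quantity"] == quantity) & (tab["density_multiple"] == density_multiple)]
    if sel.empty:
        raise ValueError(f"no rows for quantity={quantity!r}, density_multiple={density_multiple}")
    sel = sel.sort_values("Ns")
    return list(zip(sel["Ns"].astype(float), sel["value"].astype(float)))


def source_penalty_energies(
    src: SourceDensities, Ns: float, rho0: float, epsT: float
) -> tuple[float, float]:
    """Free-energy densities of chain-end and kink sources (kBT·l0⁻³).

    Δf_ends = (1/2)(3/ρ0±) g² = (1/2)(3Ns/2ρ0) g²  and
    Δf_kinks = (1/2)(3εT/2ρ0) (ρ0 l0 k)².  Both scale as 1/ρ0 at fixed
    source magnitude.
    """
    if Ns < 1:
        raise ValueError(f"Ns must be >= 1, got {Ns}")
    if rho0 <= 0 or epsT < 0:
        raise ValueError("rho0 must be positive and epsT non-negative")
    if src.g < 0 or src.k_density < 0:
        raise ValueError("source density magnitudes must be non-negative")
    expected_ends = 2.0 * rho0 / Ns
    if not np.isclose(src.rho_ends, expected_ends, rtol=1e-12, atol=0.0):
        raise ValueError(
            f"rho_ends={src.rho_ends} inconsistent with 2*rho0/Ns={expected_ends}"
        )
    df_ends = 0.5 * (3.0 / src.rho_ends) * src.g**2
    df_kinks = 0.5 * (3.0 * epsT / (2.0 * rho0)) * src.k_density**2
    return df_ends, df_kinks


def coupling_strength_G(Ns: float, epsT: float, rho0: float) -> float:
    """Crossover law for the raw coupling constant G (kBT·l0⁵).

    G = (3/2)(1/ρ0)(1/Ns + 1/εT)⁻¹; symmetric in (Ns, εT) and bounded above
    by (3/2)·min(Ns, εT)/ρ0.
    """
    if Ns < 1 or epsT <= 0 or rho0 <= 0:
        raise ValueError("require Ns >= 1, epsT > 0, rho0 > 0")
    return 1.5 / rho0 / (1.0 / Ns + 1.0 / epsT)


def gt_over_rho0(Ns: np.ndarray | float, epsT: float) -> np.ndarray | float:
    """Dimensionless coupling ratio G̃/ρ0 = (2/3)(1/Ns + 1/εT)⁻¹."""
    Ns = np.asarray(Ns, dtype=float)
    out = (2.0 / 3.0) / (1.0 / Ns + 1.0 / epsT)
    return float(out) if out.ndim == 0 else out


def coupling_params(Ns: float, epsT: float, rho0: float) -> tuple[float, float]:
    """(G, G̃) predicted by the crossover law for given chain length/stiffness."""
    G = coupling_strength_G(Ns, epsT, rho0)
    return G, G * ((2.0 / 3.0) * rho0) ** 2


def fit_persistence_length(points: Sequence[tuple[float, float]]) -> CouplingLawFit:
    """Fit the crossover law to (Ns, G̃/ρ0) data with εT the only parameter.

    Unweighted squared residuals on the natural scale.  For a single point the
    closed-form inversion ``1/εT = (2/3)/(G̃/ρ0) − 1/Ns`` is used; it must be
    feasible (G̃/ρ0 < (2/3)Ns).
    """
    pts = [(float(n), float(y)) for n, y in points]
    if len(pts) < 1:
        raise ValueError("need at least one (Ns, Gt/rho0) point")
    for n, y in pts:
        if n < 1 or y <= 0:
            raise ValueError(f"invalid point (Ns={n}, value={y})")

    if len(pts) == 1:
        n, y = pts[0]
        inv = (2.0 / 3.0) / y - 1.0 / n
        if inv <= 0:
            raise ValueError(
                f"single point (Ns={n}, Gt/rho0={y}) admits no positive epsT: "
                f"value must be below (2/3)*Ns = {2 * n / 3:.4g}"
            )
        return CouplingLawFit(epsT=1.0 / inv, points=tuple(pts), residual_norm=0.0)

    ns = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])

    def resid(logeps: np.ndarray) -> np.ndarray:
        return gt_over_rho0(ns, float(np.exp(logeps[0]))) - ys

    # start from the average of feasible single-point inversions
    invs = (2.0 / 3.0) / ys - 1.0 / ns
    feasible = invs[invs > 0]
    start = float(np.log(1.0 / np.mean(feasible))) if feasible.size else np.log(100.0)
    sol = least_squares(resid, x0=[start], method="lm")
    epsT = float(np.exp(sol.x[0]))
    return CouplingLawFit(
        epsT=epsT, points=tuple(pts), residual_norm=float(np.linalg.norm(sol.fun))
    )


def fit_reciprocal_law(
    points: Sequence[tuple[float, float]], method: str = "linear"
) -> ScalingFit:
    """Fit value = a·(1/Ns + 1/b) by unweighted least squares.

    ``method='linear'`` solves the equivalent linear regression of value on
    1/Ns (slope a, intercept a/b); ``method='nonlinear'`` runs the direct
    nonlinear least squares.  The two routes agree to high precision on any
    dataset, which the test suite asserts.
    """
    pts = [(float(n), float(y)) for n, y in points]
    if len(pts) < 2:
        raise ValueError("need at least two points")
    ns = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(ns).size < 2:
        raise ValueError("all Ns equal: singular design")

    x = 1.0 / ns
    if method == "linear":
        slope, intercept = np.polyfit(x, ys, 1)
        a, b = float(slope), float(slope / intercept)
        resid = ys - a * (x + 1.0 / b)
    elif method == "nonlinear":
        lin = fit_reciprocal_law(pts, method="linear")

        def f(theta: np.ndarray) -> np.ndarray:
            return theta[0] * (x + 1.0 / theta[1]) - ys

        sol = least_squares(f, x0=[lin.a, lin.b], method="lm", xtol=1e-15, ftol=1e-15)
        a, b = float(sol.x[0]), float(sol.x[1])
        resid = sol.fun
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScalingFit(a=a, b=b, residual_norm=float(np.linalg.norm(resid)))


def compressibility_scaling_check(
    points: Sequence[tuple[float, float]]
) -> dict[str, object]:
    """log–log slope of B/ρ0 vs Ns and deviation from the ideal 1/Ns law.

    For non-interacting chains each chain contributes kBT/V of pressure, so
    B/ρ0 = 1/Ns exactly (slope −1, per-point products (B/ρ0)·Ns = 1).
    """
    pts = [(float(n), float(y)) for n, y in points]
    if len(pts) < 2:
        raise ValueError("need at least two points")
    ns = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.any(ys <= 0) or np.any(ns <= 0):
        raise ValueError("all points must be positive")
    slope, intercept = np.polyfit(np.log(ns), np.log(ys), 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "ratio_to_ideal": ys * ns,  # == 1 under the ideal-chain law
    }


def coupling_report(
    fits: Iterable[tuple[float, float, ModelParams | FitResult]]
) -> pd.DataFrame:
    """Tabulate density-normalised ratios across chain lengths and densities.

    ``fits`` is an iterable of (Ns, density_multiple, params-or-FitResult).
    Returns one row per entry with the X/ρ0 ratios, the coupling dominance
    ratio G̃/L, and per-(Ns) collapse diagnostics: the relative spread of each
    ratio across densities (zero means perfect proportionality to ρ0).
    """
    rows = []
    for Ns, mult, obj in fits:
        params = obj.params if isinstance(obj, FitResult) else obj
        r = params.ratios()
        rows.append(
            {
                "Ns": Ns,
                "density_multiple": mult,
                **r,
                "Gt/L": params.Gt / params.L if params.L > 0 else np.inf,
            }
        )
    if not rows:
        raise ValueError("no fits supplied")
    df = pd.DataFrame(rows)
    for col in ("A/rho0", "L/rho0", "Gt/rho0", "B/rho0"):
        spread = df.groupby("Ns")[col].transform(
            lambda s: (s.max() - s.min()) / s.mean() if len(s) > 1 else 0.0
        )
        df[f"{col}_density_spread"] = spread
    return df
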
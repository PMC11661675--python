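# Methods

## The continuum model

The package analyses an isotropic solution (or melt) of linear polymers
through the minimal quadratic free-energy density coupling segment density
and nematic order,

    f = ½ B δρ̃² + ½ A δQ_ij² + ½ L (∂_k δQ_ij)² + ½ G̃ [∂_j δQ_ij + ½ ∂_i δρ̃]²

with δρ̃ = δρ/ρ₀ the relative segment-density variation and δQ_ij the
(symmetric, traceless) nematic order tensor variation, both zero in
equilibrium.  Units are k_BT for energy and the segment length l₀ for
length throughout the core; SI enters only at the reporting boundary
(`model.to_si`, default l₀ = 0.34 nm, T = 298.16 K — one B-form dsDNA base
pair per segment).  Parameters:

| symbol | meaning | unit | typical dsDNA value (per ρ₀, base density) |
|---|---|---|---|
| B | concentration susceptibility / bulk modulus | k_BT·l₀⁻³ | B/ρ₀ ≈ 1/Ns (ideal chains) |
| A | nematic order modulus | k_BT·l₀⁻³ | 0.05–0.27 |
| L | isotropic-phase nematic elastic constant | k_BT·l₀⁻¹ | 1–8 |
| G̃ | density–nematic coupling strength | k_BT·l₀⁻¹ | 2.7–72 |

The coupling term penalises the sources of the tensorial chain-continuity
law; because it is a perfect square, B, A > 0 and L, G̃ ≥ 0 suffice for
positive definiteness of every Fourier mode.  In the isotropic phase there
is a single elastic constant L (no splay/twist/bend distinction).

Per Fourier mode (wavevector along the mode's z axis) the degrees of freedom
are x = (δρ̃, Qzz, Qxx−Qyy, Qxy, Qxz, Qyz) and f(q) = ½ xᵀM(q)x with M block
structure: a coupled (δρ̃, Qzz) 2×2 block, and diagonal entries for the
other components.  Equipartition gives the measurable per-segment amplitudes
as entries of ρ₀M(q)⁻¹; the matrix-inverse route is the authoritative
definition in `model.theoretical_amplitudes` (evaluated through the analytic
block inverse, and pinned to the numerical 6×6 inverse at 1e-10 relative
tolerance by the test suite).  Useful signatures: ⟨|Qxy|²⟩ is the only
amplitude independent of G̃, so the xy–xz splitting isolates the coupling;
the density amplitude is q-independent iff G̃ = 0; the δρ–Qzz
cross-correlation is negative for G̃ > 0 and vanishes at q = 0.

## Spectrum estimator

For each lattice wavevector q = (2π/L₀)n (integer n, one representative per
±n pair — the correlations are inversion-even) the estimator forms
δa(q) = Σ_s a_s e^(−iq·r_s) over all segments with the apolar weights
a_s ∈ {1, [3(t·ê_z)²−1]/2, 3(t·ê_x)(t·ê_z)/2, …} in a per-wavevector frame
ê_z = q̂, ê_x Gram–Schmidt-projected from the first box axis (deterministic
fallback to the next axis when degenerate; isotropy of the results is
asserted in tests).  Only lattice-commensurate wavevectors are accepted, so
periodic wrapping is exact.  Implementation note: all five weighted sums are
contractions of the second-moment tensor G_ij(q) = Σ_s t_i t_j e^(−iq·r_s)
(tr G recovers the density sum since |t| = 1), which reduces the per-snapshot
cost to two real matrix products and a few length-M contractions.

Wavevectors are pooled in shells of width Δq = 2π/L₀ — shell k covers
((k−1)Δq, kΔq], q = 0 excluded; the reported shell wavenumber is the mean
|q| of its members.  Averaging is per configuration first, then over the
ensemble; standard errors come from block averaging (default block 100) over
the configuration sequence, reported as NaN when fewer than two blocks
exist.  The default cutoff is 15 shells (configurable) — the low-q window
where the continuum description applies.

## Simultaneous fit

`fitting.fit_model` minimises the inverse-variance-weighted squared
residuals of {xy, (xz+yz)/2, zz, rho} against the closed-form amplitudes.
Choices made where the procedure was genuinely open:

* xz and yz are theoretically equal and are pooled (halves the noise);
  the fit is invariant under relabelling them.
* Weights are 1/stderr² from block averaging; degenerate or missing errors
  trigger an unweighted fallback (logged, recorded in the result).
* Parameters are log-parameterised (positivity by construction) and
  optimised by Levenberg–Marquardt from a closed-form initial guess
  (intercept/slope of ρ₀/(2·xy) in q², low-shell density amplitude, low-shell
  xy–xz splitting), with two additional seeded perturbed starts to guard
  against the shallow L/G̃ trade-off at low q.
* The lowest q > 0 shell is dropped by default (it pools very few
  wavevectors and carries the largest statistical error); a flag restores it.
* Parameter errors are asymptotic: cov(log p) = (JᵀJ)⁻¹·2·cost/(m−4),
  scaled to the natural parameters.  No posterior sampling.
* The cross-correlation is never fitted; it is predicted from the fitted
  parameters and compared in `goodness_report`.

## Coupling crossover law and scaling fits

Chain ends (number density 2ρ₀/Ns) and chain bending (dimensionless
stiffness εT, which equals the persistence length in segment units) are the
two sources that can absorb splay; treating them as independent ideal gases
and merging their quadratic costs into the single penalty of the model gives

    G̃/ρ₀ = (2/3) (1/Ns + 1/εT)⁻¹,

symmetric in (Ns, εT) and bounded by (2/3)·min(Ns, εT).
`coupling.fit_persistence_length` fits εT by unweighted least squares on the
natural scale (a single point inverts in closed form and must satisfy
G̃/ρ₀ < (2/3)Ns).  The packaged reference table of fitted dsDNA ratios
(A, L, G̃, B over ρ₀ at chain lengths 16–5000 bp and three densities) lets
the printed-data analyses run standalone; fits on its long-chain subsets
bracket the dsDNA persistence length at εT ≈ 102–111 bp.  The nematic
modulus follows the reciprocal law A/ρ₀ = a(1/Ns + 1/b) (fitted equivalently
by linear regression on 1/Ns — the package asserts both routes agree to
1e-8), and B/ρ₀ tracks the ideal-chain compressibility 1/Ns.

## Induced order

With the non-linearised continuity source, an imposed 1-D profile δρ(z)
induces δQzz(z) obeying

    (L + G′ρ²)∂²δQzz + 2G′ρ(∂δρ)∂δQzz + G′(δQzz + ½)ρ∂²δρ − A·δQzz = 0,

a linear variable-coefficient ODE with source −½G′ρ∂²δρ, where
G′ = G̃/ρ₀².  (The alternative reading G′ = G·(2/3)l₀² of the coupling
constant is dimensionally flat here; G̃/ρ₀² is adopted because it is the
unique choice whose linearisation reproduces the sinusoidal transfer factor
−½G̃q²/(A+(L+G̃)q²).)  The solver uses second-order central differences with
a banded direct solve; boundary conditions are clamped-zero (default, for
localised profiles with decaying tails) or periodic — the physical problem
does not single out a condition, so both are exposed.  Verified properties:
the discrete residual is at rounding level, the error decreases as O(h²)
under grid refinement, and the small-amplitude solution matches the transfer
factor to better than 1e-4.

The saturated limit δQzz ≈ −½(1+L/G̃)⁻¹δρ̃ applies to profiles whose
features are *sharp* compared to the coupling length sqrt((G̃+L)/A): their
Fourier content lies where the transfer factor has saturated.  For wide
profiles the response is instead the small curvature term (G̃/2A)∂²δρ̃.  The
relative error of the saturated approximation grows roughly linearly in
feature-width over coupling-length (≈4% at a width of 0.03 coupling
lengths, measured against the full solver).  Sign convention: depleted
regions order prolate (δQzz > 0), enhanced regions oblate (δQzz < 0);
physical bounds −½ ≤ Qzz ≤ 1.

## Synthetic ensembles

`synth.sample_wlc_ensemble` draws ideal discrete worm-like chains: uniform
chain starts, first segment uniform on the sphere, successive bend angles
with density ∝ exp(εT·cosθ)sinθ (closed-form inverse CDF; the per-joint
bending energy is εT(1−cosθ)), uniform azimuth, segment positions at bond
midpoints (symmetric and apolar — the reference point within a segment only
matters beyond the fitted q range), wrapped periodically.  Consequences used
as oracles: ⟨cosθ⟩ = coth εT − 1/εT, orientational correlation ⟨cosθ⟩^d at
separation d, persistence length → εT segments for εT ≫ 1 (at small εT the
identification is only approximate).  Chains are non-interacting and
snapshots independent — no excluded volume, electrostatics, hybridisation,
or Monte Carlo time correlation.  Passing tests on these ensembles therefore
validate the estimator/fitter chain and the entropic (ideal-chain) part of
the physics — e.g. B/ρ₀ → 1/Ns — but not interaction-driven features of real
DNA solutions (the density dependence of the ratios, the behaviour at
100–200× base density, or oxDNA-specific structure at high q).

`synth.sample_gaussian_modes` is the statistical oracle: per-mode complex
amplitude vectors drawn with covariance ρ₀M(q)⁻¹ (real/imaginary parts
independent, half each), i.e. exactly the model's equipartition statistics;
estimator and fitter applied to its output must recover the generating
parameters within errors, which is asserted end-to-end.

Study conditions for the headline pipeline run (chosen once to emulate the
16-bp reference system at desk scale): Ns = 16, εT = 109, segment density
2×10⁻⁶ l₀⁻³, periodic box L₀ = 400 (8 chains, 128 segments), 2000
independent snapshots, 12 shells, block size 100, lowest shell excluded from
the fit.  The reduced box keeps the smallest wavevector well inside the
low-q window while the ensemble size keeps the B/ρ₀ standard error near 1%.

## Degenerate inputs and numerical edges

* Wavevectors incommensurate with the box, inconsistent boxes or segment
  counts, non-unit directions, and non-contiguous chain storage are
  rejected, not repaired.
* q ∥ reference axis: deterministic fallback to the next box axis.
* Fewer than two blocks: errors reported missing (NaN), fit falls back to
  unweighted.
* Single-point persistence fits with G̃/ρ₀ ≥ (2/3)Ns are infeasible and
  rejected with a message.
* Zero-length end-to-end vectors are skipped in orientation decorrelation.

## Known limitations

* The quadratic source penalty is an approximation; real chains show
  systematic deviations (e.g. the non-monotonic L(Ns), which the package
  reports but does not model).
* Asymptotic parameter errors understate uncertainty when residuals are
  strongly correlated across shells.
* Static, equal-time spectra only; no dynamic correlations.
* The oxDNA reader supports equal-length complementary duplex pairs
  (reverse-order pairing); nicked or circular topologies are rejected.
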
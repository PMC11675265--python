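# Methods

## Model

`alignkt` treats the continuous-time Vicsek-like model of `N` point
particles in a periodic square box of edge `L`.  Particles move at fixed
speed `v0` along their heading `θ_i` and interact purely through headings:

    dθ_i/dt = Γ Σ_{j∈Ω_i} sin(n(θ_j − θ_i)) + η_i,

with `Ω_i = {j ≠ i : |x_i − x_j| ≤ R}` (metric neighbourhood, minimum-image
distance), Gaussian white rotational noise of strength `D_r`, and an integer
*chelation number* `n` that sets the interaction symmetry: `n = 1` polar
alignment, `n = 2` nematic, `n = 3` triatic.  The torque is additive — there
is deliberately no normalization by the neighbour count, which is what makes
a systematic weak-coupling kinetic theory possible at arbitrary density.

Dimensionless groups: density `M = πR²N/L²` (mean number of interaction
partners), coupling `Sc = ΓR/v0`, inverse Peclet number `Pe⁻¹ = R·D_r/v0`,
and the effective coupling `γ = Sc·M`, the small parameter of the theory.
All kinetic-theory quantities are computed in rescaled units `R = v0 = 1`
(time in units of `R/v0`); `ModelParams` centralizes the conversions, and
the simulator may run in raw units (`times_rescaled`, `times_scaled` on
`Trajectory` do the bookkeeping).  `D_r = 0` (`Pe⁻¹ = 0`) is a first-class
setting: the deterministic system still mixes at anti-aligning coupling.
Negative `Γ` is allowed and is the main regime studied, because the
disordered state then remains stable and spatially homogeneous.

## Mode representation and the normalization question

The angular one-particle distribution is represented by a truncated Fourier
spectrum `p̂_m`, `m = 0..m_max`, with negative modes defined by conjugation
(the distribution is real).  The normalization is fixed by the *density*
convention `p̂_0 = 1/2`, which is also what the empirical estimator measures:
`p̂_m = (1/2N) Σ_i exp(−i m θ_i)`.

Two conventions for the mode-coupling matrices circulate, differing by
powers of π, and they are **not** equivalent descriptions of the same
dynamics once a mode normalization is fixed.  The package therefore treats
the choice as an empirical question and settles it against the agent-based
model, which is the ground truth here:

- A wedge-relaxation experiment in a mean-field-dominated regime
  (`M = 2`, `Sc = −0.005`, so `γ = −0.01` while `M Sc² = 5·10⁻⁵` is
  negligible; 8 ensembles of 2000 particles) matches the integrated mode
  equations to 0.3 % when the Vlasov matrix is `V_mw = m γ (δ_{w,n} −
  δ_{w,−n})`, i.e. the linearized mean-field relaxation rate of the
  symmetry-selected mode about disorder is `n γ / 2`.  A matrix `m π γ`
  decays π times too fast.
- A heading-decorrelation experiment in a Landau-dominated regime
  (isotropic background, `γ < 0`, `Pe⁻¹ = 0`) shows a cleanly exponential
  velocity autocorrelation whose rate converges, as the coupling is reduced,
  to `(8/3π²) M Sc² Σ_{j=1..2n} 1/(2j−1)`; this fixes the Landau matrix to
  `L_mw = (4 m M Sc²/3π²) I(n,m,w)`.

These *density*-normalized matrices are the package default and the only
ones the mode integrator accepts.  A second, `"spectral"` convention —
`V_mw = m π γ (…)`, `L_mw = (4 m M Sc²/3) I` — is retained verbatim because
the rational closed forms of the `n = 1, 2` Landau matrices are customarily
quoted in it; it is used in the tests to cross-check the quadrature against
those closed forms and for prefactor-independent quantities (ratios, signs,
zero structure).  Note the two conventions are not related by a single mode
rescaling (the quoted `V` and `L` differ from the density forms by π and π²
respectively); this internal tension is precisely why the package anchors
the physics to the simulation rather than to quoted prefactors.

## Collision kernel and coupling matrices

The Landau matrix element requires the angular kernel integral

    I(n, m, w) = ∫₀^{2π} [sin(nΔ)/|sin(Δ/2)|]
                 (2n cos(nΔ) sin(wΔ) − (m−2w) sin(nΔ) cos(wΔ)) dΔ.

The quotient `sin(nΔ)/|sin(Δ/2)|` equals the Chebyshev polynomial
`U_{2n−1}(cos(Δ/2))`, a smooth bounded function with endpoint values `2n`
and `−2n`, so the integrand needs no singular treatment.  It is integrated
by adaptive Gauss–Kronrod quadrature split at `Δ = π` (the kink of the
original absolute-value form) with absolute tolerance 10⁻¹² per moment; a
quadrature that fails to converge raises rather than degrading silently.
Matrices decompose the integral into two `w`-moments so an `(2m_max+1)²`
matrix costs only `O(m_max)` quadratures (cached).  Useful anchors: for
`w = 0`, `I(n, m, 0) = −4m Σ_{j=1..2n} 1/(2j−1)`; `I(1,1,0) = −16/3`,
`I(2,1,0) = −704/105`, `I(1,1,1) = 16/5`.

The geometric ingredient of the Landau term is the spatially averaged
encounter time of a ballistic pair with relative speed
`v_rel = 2|sin(Δ/2)|`: averaging the traversed chord over partner positions
uniform in the unit disk gives `t⊙ = 8/(3π v_rel)`.  `encounter_time`
returns the closed form; `mc_encounter_time` is an independent Monte Carlo
oracle over the disk used in the tests.  `v_rel = 0` (parallel headings) is
declared undefined; the kernel integrand stays finite there.

## Mode equations, stability, conserved quantities

`mode_rhs` implements
`d p̂_m/dt = −m² Pe⁻¹ p̂_m + Σ_w K_mw p̂_w p̂_{m−w}` with the convolution
restricted to `|w| ≤ m_max` and `|m−w| ≤ m_max` (plain truncation, no
aliasing correction).  Only `m ≥ 0` is evolved; negative modes are
reconstructed by conjugation, so reality is enforced by construction.  Row
`m = 0` of every matrix vanishes identically, making the density mode a
conserved quantity of the integrator itself — `p̂_0` is part of the state
and staying at 1/2 is a genuine (tested) property, not an imposed
constraint.  Integration uses `scipy.integrate.solve_ivp` with DOP853 at
`rtol = 10⁻¹⁰`, `atol = 10⁻¹²`; failures raise.  The default truncation is
`m_max = 10`; doubling it changes the polar mode of the reference relaxation
run by less than 10⁻³ (tested).

Linearizing about the unordered state gives
`λ_m = −m² Pe⁻¹ + (1/2)(K_mm + K_m0)` (this `K_{m,0}` reading, rather than
its transpose, is the one compatible with density conservation) and the
critical noise `Pe⁻¹_c = (1/2)(K_mm + K_m0)/m²`.  The γ- and γ²-coefficients
of the selected mode's rate are exposed as `alpha_n` and `beta_n`; since the
second-order part of `K_{n,0}` is strongly negative and that of `K_{n,n}`
only weakly positive, `beta_n > 0` and the Landau correction shifts the
ordering instability to lower noise for aligning coupling.  Two mean-field
timescale conventions exist (`1/(nπγ)` versus the linearized `2/(nγ)` of the
density normalization); `mean_field_rate` and `mean_field_timescale` expose
both rather than silently reconciling them.

## Self-diffusion

In a disordered background only `K_{1,0}` couples a particle's velocity mode
to the density, so the heading correlation decays exponentially with
`τ_c = −2/K₁₀` and

    D_self = τ_c/2 = −1/K₁₀,  K₁₀ = −(16/3π²) M Sc² Σ_{j=1..2n} 1/(2j−1).

The `n`-dependence enters only through the harmonic-type sum, giving
`D(n=2)/D(n=1) = 35/44` at equal `M Sc²` — the package's headline transport
number.  With noise the compact formula `D = −1/(K₁₀ − Pe⁻¹)` admits a
second parse `−1/K₁₀ − Pe⁻¹`; both are implemented behind
`theory_dself(convention="A"|"B")` (default A) and agree at `Pe⁻¹ = 0`,
where every quantitative claim in the tests is made.  Neither parse
reproduces the exact noise-only limit `D = 1/(2 Pe⁻¹)` (A gives `1/Pe⁻¹`);
the consistent tracer-linearization rate would be `1/(2Pe⁻¹ − K₁₀)`.  This
is documented rather than hidden: noisy-case numbers from `theory_dself`
should be treated as a convention, not a validated prediction.

Empirical estimators: `vacf` computes `C(τ) = ⟨cos(θ(t+τ)−θ(t))⟩` by FFT
over particles and time origins (`C(0) = 1` exactly); `fit_tau_c` does a
weighted log-linear fit over the window `C ∈ [0.1, 0.9]` (weights `C²`, the
inverse variance of the log) and reports `D = τ_c/2` with a fit standard
error.  `dself_msd` fits the slope of the mean squared displacement of the
unwrapped positions and reports `D = slope/4` (two-dimensional Green–Kubo
normalization, consistent with the VACF route and with `τ_c = 2D`); the
un-normalized defining rate `MSD/τ` is carried as `raw_rate`.  It warns when
the fit window is shorter than ten correlation times or when the local
MSD exponent exceeds 1.5 (ballistic regime, no plateau).

## Agent-based numerics

Explicit Euler–Maruyama: torques and displacements are evaluated entirely at
the pre-step state; `θ ← wrap(θ + dt·torque + sqrt(2 D_r dt)·ζ)`, positions
advance with the *old* heading (a config switch `move_with_updated_heading`
selects the O(dt²)-different alternative for sensitivity checks).  Angles
are wrapped to `(−π, π]` with a branch that leaves in-range values
bit-identical, so noise-free headings are exactly frozen when `Γ = 0`.
Per-step displacement length is exactly `v0·dt` (speed conservation is a
tested invariant).  A warning (not an error) fires when
`|Γ|·M·dt > 0.1`, the accuracy heuristic for the torque step.

Neighbour search requires `R ≤ L/2` (minimum image).  Two engines share the
same noise stream (standard normals drawn in fixed step-then-particle order
from one seeded `numpy` Generator): a readable `numpy` reference built on
`scipy.spatial.cKDTree` with periodic `boxsize`, and a numba-compiled
linked-cell list (cell edge ≥ R, 9-cell stencil, O(N) per step; boxes with
fewer than 4 cells per edge fall back to an O(N²) minimum-image scan).  Each
engine is bitwise reproducible given the seed; across engines trajectories
agree to floating round-off (torque summation order differs).  Both
neighbour paths are property-tested against an independent O(N²) brute
force.

## Synthetic data: what it emulates and what it does not

All inputs are generated internally; there is no external data.  The
generators produce the spatially uniform angular states of the homogeneous
theory: `wedge` (headings uniform on `[−α/2, α/2]`, default `α = 5π/6`,
exact spectrum `p̂_m(0) = sin(mα/2)/(mα)`, polarized along x so ensemble
modes are real), `isotropic`, `delta` (perfect order) and `two_beam`
(perfect nematic order).  Positions are always uniform in the box.
Consequently the tests probe exactly the regime where the theory's
assumptions hold — spatial homogeneity, disordered or relaxing angular
states — and say nothing about spatially structured phenomena of real
aligning active matter: band formation and phase separation at aligning
coupling, boundary effects, density–order coupling, or metric-free
interaction rules.

Default study conditions: the mode-relaxation ensemble uses `N = 493`,
`M = 0.1`, `R = 1`, `v0 = 4`, `dt = 0.0025`, `Γ = −0.2` (`n = 1`) with 20
seeded realizations (a scaled-down default; 80 realizations reproduce the
full-ensemble protocol) over 30 raw time units (`|t'|` up to 6), recording
every 60 steps.  The theory side starts from the exact wedge spectrum, not
the measured `t = 0` modes (parameter-free comparison); a flag allows
seeding from measured modes for diagnostics.  Self-diffusion runs use
`N = 300`, `M = 1`, `dt = 0.02` in rescaled units, isotropic starts, run
lengths of 25–60 predicted correlation times; these sizes keep the full
suite within desk-scale minutes while leaving the ensemble errors small
compared with the tested tolerances.

## Measured accuracy limits

The Landau prediction for `D_self` is asymptotic in the coupling.  Measured
ratio `D_sim/D_theory` (VACF route, `n = 1`, `Pe⁻¹ = 0`): ≈ 1.5–1.7 at
`M Sc² = 10⁻²` (across `M = 0.1–4`, `N = 300–1200`, `dt = 0.005–0.02`),
≈ 1.25–1.32 at `2.5·10⁻³`, ≈ 1.30 at `10⁻³`, ≈ 1.18 at `5·10⁻⁴` —
converging to 1 from above as the coupling decreases, with the VACF
remaining single-exponential throughout.  So at `M Sc² = 10⁻²` the theory
underestimates the correlation time by roughly a third; quantitative
agreement at the 10 % level requires `M Sc² ≲ 10⁻³`.  Corrections of this
kind (and their modelling by effective telegraph-process descriptions) are
outside the package's scope; the acceptance suite asserts both the
convergence trend and a fixed-coupling tolerance, and the latter documents
this limit.  The nematic case carries larger corrections at equal `M Sc²`
(ratio ≈ 2.0 at 10⁻²).

## Other limitations

- The theory is spatially homogeneous; gradient terms and band instabilities
  at aligning coupling are not modelled, so long aligning-`γ` runs drift away
  from the homogeneous mode equations for reasons the theory cannot see.
- `m_max` truncation has no aliasing correction; states with spectra wider
  than the truncation (e.g. near-delta initial conditions) need larger
  `m_max`.
- The MSD estimator needs runs much longer than `τ_c` to reach its
  asymptotic slope; on the default run lengths the VACF route is the
  reliable one and is what the scaling experiment reports.
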
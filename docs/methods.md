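# Methods

All internal quantities are in Hartree atomic units (ħ = m_e = e = 1); the
unit registry (`cavikin.units`, built on CODATA constants via
`scipy.constants`) handles the presentation conversions (meV, eV, cm⁻¹,
kJ/mol, fs, K) and its round trips compose to identity at the 1e−12 level.

## Model and assumptions

A single molecule, reduced to one reaction coordinate R with mass M, ground
potential E(R) and permanent dipole μ(R), couples to a single cavity photon
mode of frequency ω_c through the dipole-gauge ground-state light–matter
Hamiltonian. The photon coordinate is mass-weighted (unit mass), and the
coupling enters as a displacement of q_c by √(2/ħω_c³)·χ·μ(R); the squared
form contains the dipole self-energy, which keeps the minimum-energy-path
barrier exactly at the bare E_b for every (χ, ω_c) — this invariance is
enforced by a property test. The molecular dipole is assumed perfectly
aligned with the cavity polarization (no orientational averaging). Nuclear
and photonic degrees of freedom are treated classically in the rate
calculations (their frequencies are comparable, both far below electronic
scales); the electronic problem is solved quantum mechanically once, to
produce E(R) and μ(R). Excited electronic states, multi-mode cavities,
cavity loss and multi-molecule collective coupling are out of scope.

### Coupling parameterizations

Four interchangeable couplings are maintained (`CavityParams`): χ (the
displacement coupling), A₀ = χ/ω_c, the mass-weighted η̃ = χ/(√M ħω_c) and
the dimensionless η = μ₀′ √(ħ/2Mω₀) χ/(ħω_c); the linear-response Rabi
splitting is 2ħω_c·η. Frequency scans at fixed η rescale χ proportionally
to ω_c (equivalently: η̃ is held constant). All conversions round-trip to
machine precision, which is property-tested.

## Molecular potentials

### Grid-solved electron-transfer model

The built-in microscopic model is a one-electron, one-proton system between
two fixed ions (the Shin–Metiu construction): H_el = T_r + V_eN + V_NN with
soft-Coulomb electron–nucleus attractions (erf(|x|/a)/|x| by default;
an inverse-square form −Z/√(x²+a²) is selectable) and bare proton–ion
repulsion. The electronic Hamiltonian is discretized by second-order finite
differences on a uniform grid with Dirichlet boundaries and diagonalized
(`scipy.linalg.eigh_tridiagonal`); the dipole origin is the ion-pair
center, so the fully symmetric configuration has μ = 0 exactly. A warning
is raised when the ground state approaches the first excited state closer
than a configurable gap tolerance (avoided-crossing regions).

Convergence behaviour: the finite-difference kinetic operator
*underestimates* curvature, so the discrete ground energy converges
monotonically **from below** as the grid is refined, with a clean O(dx²)
Richardson ratio of 4 on grid doubling (measured and tested at four
resolutions). This is the opposite sign of a Rayleigh–Ritz variational
basis and is documented here deliberately: tests assert the true monotone
approach, not a variational upper-bound property the scheme does not have.

The default parameter set (ion separation 9.4 a₀, all softening lengths
1.5 a₀, unit charges) was calibrated once so the ground surface is a
double well with ħω₀ ≈ 172 meV, ħω_b ≈ 163 meV, μ₀′ ≈ 0.23 a.u. and
μ‡′ ≈ −2.1 a.u. — representative proton-coupled electron-transfer values.
Every constant is exposed in the config; the calibration is a default, not
a constraint.

### Reference parameters and the quartic surrogate

The reference study conditions are the scalar stationary-point parameters
ħω₀ = 170.6 meV, ħω_b = 162.05 meV, μ₀′ = 0.225 a.u., μ‡′ = −1.887 a.u.
with the proton mass. The analytic rate theory needs nothing else, so
reference-condition scans consume these scalars directly
(`fixtures.table1_stationary_points`). In particular the η ↔ η̃ conversion
always uses the *reference* ω₀ and μ₀′.

The trajectory simulations need a full surface; `fixtures.table1_model`
provides a quartic double well E(R) = A R⁴ − B R² with B = ½Mω_b² and
A = B²/4E_b (barrier at R = 0, ω₀ = √2·ω_b for the quartic itself) and a
cubic dipole μ(R) = μ‡′ R + c R³ with c chosen so the dipole slope at the
wells equals the reference μ₀′ while the slope at the barrier equals μ‡′.
The barrier height is not fixed by any reference value; the default
E_b = 0.014 Ha (≈ 37 kJ/mol, ≈ 14.8 k_BT at 300 K) is a typical
proton-transfer barrier, chosen once. κ is insensitive to E_b because all
trajectories are released from the dividing surface.

### Tabulated input and stationary points

Tabulated surfaces are read from plain-text/CSV (one three-column file or
two two-column files), with units declarable in a `# units:` header;
inputs with non-monotone R, NaNs or fewer than 16 points are rejected.
E and μ are interpolated by cubic splines that reproduce the nodes exactly.
Stationary points are roots of the spline derivative; ω₀ = √(E″(R0)/M) and
ω_b = √(−E″(R‡)/M) come from the spline's analytic second derivative,
cross-checked against a 5-point finite difference (disagreement > 1% warns).
The reactant is the lower-energy of the two minima flanking the barrier
maximum; single-well surfaces raise an error. All extracted quantities are
invariant under rigid translation of R and constant energy shifts (tested);
a helper recenters any model so the barrier sits at R = 0, the dividing
surface convention used throughout.

## Rate theory

The quartic reactive-frequency equation (module docstring of
`cavikin.ghrates`) is solved via companion-matrix eigenvalues (`numpy.roots`)
with a positive-real filter (imaginary tolerance 1e−10 relative); zero or
multiple positive real roots raise, as either signals unphysical inputs.
An independent bracketing + Brent root-finder serves as the test oracle.
The frictionless 2D closed forms (κ_GH, normal modes, the resonance
frequency) are evaluated with the "minus" branches rationalized by their
conjugates, which avoids catastrophic cancellation when 𝒞‡²/ω_c² dominates
(strong coupling at low ω_c); without this the naive difference of nearly
equal numbers underflows to κ = 0.

Friction units: the literature quotes the bath friction as ζ = 400 cm⁻¹
while the equation of motion uses the *rate* ζ/M. The implemented
parameter is the rate γ ≡ ζ/M, defaulting to the angular-frequency
equivalent of 400 cm⁻¹ (≈ 1.823e−3 a.u.); it is overridable everywhere and
this convention is deliberately prominent. The ohmic-bath cutoff ω_p is
used only for a Markovianity diagnostic (warn when γ ≳ ω_p/2) and must be
set explicitly to enable it.

Resonance location: the closed form ω_c* = −(ħ/2)η̃²μ‡′² +
½√(ħ²η̃⁴μ‡′⁴ + 4ω_b²) is exact for the frictionless 2D model (and reduces
to ω_b at zero coupling). With γ > 0 the minimum is found numerically
(log-spaced bracket + bounded golden-section refinement); both numbers are
reported by the CLI. At the reference parameters with η = 0.188 and
γ = 400 cm⁻¹ the numerical minimum sits near 28 meV while the γ = 0 closed
form gives ≈ 30 meV — the minimum is flat, and both sit well below ω_b
(the ultra-strong-coupling red-shift).

The TST rate ω₀/2π·e^(−βE_b) is cavity-independent by construction; the
effective barrier change reported for experiments is recovered as
Δ(ΔG‡) = −k_BT ln(κ/κ₀) through the Eyring form.

## Flux-side simulation

κ(t) is estimated over an ensemble released from the dividing surface:
κ(t) = Σᵢ wᵢ h[Rᵢ(t) − R‡] / Σᵢ wᵢ h[wᵢ] with weights wᵢ = Ṙᵢ(0), the
numerator including negative-velocity members; the t → 0⁺ point uses
h[Ṙ(0)], making κ(0⁺) = 1 exactly. The product side is R > R‡ by default
(configurable sign).

Initial conditions: at fixed R = R‡ the CBO surface is harmonic in q_c, so
the constrained canonical distribution is exactly Gaussian (mean
−√(2/ħω_c³)χμ(R‡), variance k_BT/ω_c²); exact Gaussian sampling is the
default. A constrained-MD mode — a thermostatted trajectory of q_c at fixed
R‡ sampled every 270 fs — mirrors the published protocol and is verified
statistically indistinguishable (two-sample KS test at n = 10⁴). Whether
the original protocol thermostats q_c during constrained sampling is
immaterial for this harmonic marginal. Momenta are Maxwell–Boltzmann.

Integrator: one-step splitting — half-kick (both channels), exact
Ornstein–Uhlenbeck momentum update on R only (multiplier e^(−γdt), matched
noise), full drift, half-kick. The γ → 0 limit is velocity Verlet
(symplectic; windowed-mean energy drift < 1e−6 relative is tested), the OU
substep is exact for any γdt, and dt = 4 a.u. resolves the fastest mode
(dt·ω < 0.3 warning otherwise). Trajectories leaving the model grid are
frozen and counted rather than extrapolated. All randomness derives from
one master seed via `numpy.random.SeedSequence`; identical configs give
bit-identical traces.

Statistics: standard errors by batch means over 20 trajectory batches; the
plateau κ(t_p) averages the trailing 25% of the trace and carries a
flatness diagnostic (|slope|·t_max > 2·stderr flags the result — flagged,
never silently returned).

Problem sizes: the package default is 100,000 trajectories of 200 fs; the
tests and the GH-comparison runs use 10,000 (statistical error ≈ 0.01 on
κ, a few seconds per run), which is ample for the 10%-level comparisons
they make. Measured agreement with the quartic-equation κ_GH at
ħω_c = 170.6 meV on the quartic surrogate: within ~1% at η = 0.047 and
~3% at η = 0.188; at η = 0.376 (deep caging) the simulation falls ~15%
below the harmonic-barrier theory, as expected once the caged trajectory
samples the anharmonic barrier region.

## Polariton spectra

Eigenstates of the 2D polariton Hamiltonian are computed on a sinc-DVR
tensor grid (exponentially convergent kinetic energy); dense
`scipy.linalg.eigh` below 2,000 basis functions (the oracle mode), sparse
shift-invert Lanczos above. The q_c range is chosen automatically from the
minimum-energy-path displacement padded by the photon-oscillator turning
point of the highest requested state. Grid-doubling convergence of the
lowest ten eigenvalues is available as a diagnostic and tested to < 1e−6 Ha
on the harmonic fixture.

The absorption cross-section uses the matter dipole μ(R) (diagonal on the
R grid) as the transition operator, a Lorentzian width ε (default 1 meV —
no reference value exists for this phenomenological parameter; halving ε
doubles peak heights at fixed integrated area, which is tested) and the
prefactor 4πℰ/c with c = 137.036 a.u.; σ is reported in relative units
with no absolute calibration claimed. Peak finding takes local maxima
above 5% of the global maximum with quadratic refinement; the Rabi
splitting is the separation of the two strongest peaks and errors out when
fewer than two resolve (e.g. χ = 0). On the bilinear-oscillator fixture
(harmonic E, linear μ) the splitting matches 2ħω_c·η to 0.02% at η = 0.01
and grows monotonically with η; in the ultra-strong regime the deviation
from linearity is reported, not asserted.

Double-well spectra use the full R range by default; a reactant-window
restriction is available by passing an explicit `R_grid`, covering both
possible readings of well-restricted spectra.

## What the fixtures do and do not show

The quartic/harmonic fixtures are exactly solvable stand-ins: they validate
the estimators, integrators, eigensolvers and closed forms against
independent oracles, and the quartic surrogate reproduces the reference
barrier-region parameters exactly. They do not emulate multi-dimensional
reaction coordinates, real anharmonic dipole surfaces far from the
stationary points, finite-temperature spectral broadening, cavity loss or
collective (N-molecule) coupling — conclusions about real VSC experiments
therefore rest on the model assumptions above, not on the passing tests.

## Known limitations

* The phonon bath enters only as Markovian friction on R (the memoryless
  limit of the ohmic spectral density); the fully non-Markovian bath kernel
  is not implemented.
* Classical nuclei and photon: no quantum rate corrections (tunnelling,
  zero-point effects) in κ or k_TST.
* Single molecule, single lossless mode, perfect dipole alignment.
* The spectrum module computes stick spectra broadened phenomenologically;
  no finite-temperature line shapes or rotational structure.
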
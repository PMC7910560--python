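# cavikin

Cavity-modified ground-state reaction kinetics for vibrational strong
coupling (VSC). `cavikin` implements, for a single molecule coupled to one
optical-cavity photon mode:

* **Grote–Hynes (GH) rate theory** on the cavity Born–Oppenheimer surface —
  polariton normal modes, the reactive frequency λ, the transmission
  coefficient κ_GH = λ/ω_b, the photon-frequency resonance condition, and
  the Markovian phonon-bath generalization;
* **a flux-side Langevin simulator** of the time-dependent transmission
  coefficient κ(t), with the photon coordinate propagated explicitly as a
  non-Markovian "solvent" degree of freedom;
* **quantum vibrational-polariton spectra** — 2D sinc-DVR eigenstates of the
  polariton Hamiltonian and the IR absorption cross-section σ(ℰ), including
  Rabi-splitting extraction;
* **model molecular potentials** — a grid-solved Shin–Metiu-type
  proton-coupled electron-transfer model, tabulated E(R)/μ(R) input, and
  analytic quartic/harmonic fixtures.

## The physics in brief

The dipole-gauge (Pauli–Fierz) Hamiltonian projected on the electronic
ground state couples a reaction coordinate R (mass M, ground surface E(R),
permanent dipole μ(R)) to a photon displacement coordinate q_c:

```
H = P²/2M + p_c²/2 + V_CBO(R, q_c),
V_CBO = E(R) + ½ ω_c² ( q_c + √(2/ħω_c³) χ μ(R) )².
```

Because the dipole self-energy completes the square, the barrier along the
minimum-energy path equals the bare barrier E_b for **every** coupling χ and
frequency ω_c — transition-state theory (k_TST = ω₀/2π · e^(−βE_b)) predicts
no cavity effect at all. The cavity instead acts *dynamically*: near the
barrier the photon mode exerts non-Markovian friction on R whose strength is
set by 𝒞‡ = √(2ω_c/Mħ) χ μ‡′, producing recrossing ("dynamical caging") and
suppressing the transmission coefficient κ in k = κ·k_TST. With an
additional Markovian phonon bath of friction rate γ = ζ/M, the reactive
frequency λ solves

```
λ⁴ + γλ³ + (ω_c² − ω_b² + 𝒞‡²/ω_c²)λ² + γω_c²λ − ω_c²ω_b² = 0,  κ_GH = λ/ω_b.
```

κ(ω_c) at fixed normalized coupling η is unimodal with a minimum near the
barrier frequency ω_b for η < 0.1, red-shifting far below ω_b in the
ultra-strong coupling regime — a *rate* resonance distinct from the
spectroscopic one (ω_c = ω₀) that splits the IR line by the Rabi energy
2ħω_c·η.

## Worked example

```python
import cavikin as ck
from cavikin.fixtures import table1_stationary_points

# reference proton-transfer parameters (ħω0 = 170.6 meV, ħωb = 162.05 meV,
# μ0' = 0.225, μ‡' = −1.887 a.u.); phonon friction 400 cm⁻¹; η = 0.188
sp = table1_stationary_points()
gamma = ck.units.wavenumber_to_angular_frequency(400.0)

wc_star, kappa_min = ck.find_resonance_numeric(
    sp, ck.TABLE1["mass"], 0.188, gamma=gamma, bracket_mev=(1.0, 500.0))
print(f"resonant photon energy : {ck.units.energy(wc_star, 'hartree', 'mev'):.1f} meV")
print(f"kappa at the resonance : {kappa_min:.3f}")

kappa0 = ck.gh_lambda_markovian(sp.omega_b, sp.omega_b, 0.0, gamma) / sp.omega_b
ddg = ck.effective_ddG(kappa_min, kappa0, 300.0)
print(f"kappa without coupling : {kappa0:.3f}")
print(f"effective Δ(ΔG‡)       : {ck.units.energy(ddg, 'hartree', 'kJ/mol'):.2f} kJ/mol")

# direct flux-side simulation vs the analytic theory, on the quartic
# surrogate surface at ħω_c = 170.6 meV
model = ck.table1_model()
msp = ck.stationary_points(model)
cav = ck.CavityParams.from_eta(
    ck.units.energy(170.6, "mev", "hartree"), 0.188,
    mass=model.mass, omega0=msp.omega0, mu0_prime=msp.mu0_prime)
trace = ck.kappa_of_t(model, cav, ck.SimConfig(n_traj=10_000, seed=7))
eff = ck.effective_couplings(msp, cav, mass=model.mass)
kappa_gh = ck.gh_lambda_markovian(msp.omega_b, cav.omega_c,
                                  eff.C_ddag, gamma) / msp.omega_b
print(f"flux-side kappa plateau: {trace.kappa_plateau:.3f} +/- {trace.plateau_stderr:.3f}")
print(f"Grote-Hynes prediction : {kappa_gh:.3f}")
```

prints

```
resonant photon energy : 28.4 meV
kappa at the resonance : 0.175
kappa without coupling : 0.859
effective Δ(ΔG‡)       : 3.97 kJ/mol
flux-side kappa plateau: 0.248 +/- 0.014
Grote-Hynes prediction : 0.260
```

Reading the numbers: tuning the cavity to ≈ 28 meV suppresses the
transmission coefficient five-fold relative to the cavity-free Kramers
value 0.859 — equivalent to an *effective* activation-barrier increase of
about 4 kJ/mol at 300 K even though the true barrier is unchanged — and the
analytic quartic-equation κ agrees with the 10,000-trajectory flux-side
simulation within its statistical error.

## Command line

```
cavikin model                       # build a potential model, report E_b, ω0, ωb, μ'
cavikin gh --eta 0.094              # analytic GH rate + resonance at one setting
cavikin scan --out scan.csv         # κ(ω_c) tables for a list of η values
cavikin kappa --ntraj 10000 --seed 7 --out trace.csv   # flux-side κ(t)
cavikin spectrum --out spectrum.csv # polariton IR spectrum σ(ℰ)
cavikin fixture --out model.json    # serialize the reference quartic model
```

All subcommands accept `--config run.toml` (blocks: `model`, `cavity`,
`bath`, `dynamics`, `spectrum`, `scan`; unknown keys are rejected) and embed
the package version, resolved-config hash and master seed in every output.

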
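# Methods

This note documents the models implemented in `triadet`, the assumptions
behind them, the parameter choices that matter, and what the synthetic-data
generators do and do not emulate.

## Charge-transfer Hamiltonians

Hole transfer along the triad is described over a small set of sites (the
FAD isoalloxazine ring and the aromatic side chains A, B, C).  The package
consumes the matrix elements as data: diagonal entries are site energies
ε_m in eV (frontier-orbital energies, proxies for in-protein ionization
potentials), off-diagonal entries are electronic couplings in eV.  No
electronic-structure calculation is performed; fragment-orbital methods or
tabulated values supply the numbers.

Conventions:

* energies are stored in eV throughout; couplings are reported in meV only
  at interfaces (CLI output, `tunnelling_coupling`);
* the diagonal carries `mean_energy + shift`, where the shift is an additive
  chemistry-dependent correction keyed by residue name.  The default shift
  table is empty — corrections are configuration inputs;
* `energy_gap(donor, acceptor)` returns ε_acc − ε_don; with energies on a
  hole (ionization-potential-like) scale a negative gap is downhill for the
  hole;
* ħ = 6.582119569×10⁻⁴ eV·ps and k_B = 8.617333×10⁻⁵ eV/K are fixed.

`marcus_rate` evaluates the standard non-adiabatic golden-rule expression
k = (2π/ħ)|H|²(4πλk_BT)^(−1/2) exp(−(ΔG+λ)²/4λk_BT) in ns⁻¹.  It is
log-concave in ΔG with its maximum at ΔG = −λ; the tests cross-check the
eV/ps evaluation against an independent SI-unit evaluation.

Gas-phase ionization potentials of the relevant fragments ship as a small
table (FAD 8.05, Tyr 8.15, Trp 7.54, Phe 8.84 eV); the Tyr−Trp difference of
0.61 eV is the intrinsic barrier a tyrosine inserts into a tryptophan chain.

## Super-exchange tunnelling

For bridge-mediated transfer the sites are split into a donor/acceptor pair
and a bridge.  The bridge is folded into an effective 2×2 Hamiltonian

    H_eff[D,A] = β_DA + Σ_ij β_Di G_ij(ε_tun) β_jA,
    G(ε) = (εI − H_bridge)^(−1),

whose off-diagonal is the tunnelling coupling T_DA.  The tunnelling energy
is defined as the average of the eigenvalues of H_eff, which is circular;
the implementation resolves it by fixed-point iteration: start from the mean
of the donor/acceptor diagonal energies, rebuild H_eff, set ε_tun to half
its trace, and repeat until the change is below 10⁻⁹ eV (cap 100
iterations).  The diagonals of H_eff are dressed with the analogous
self-energies β_Di G_ij β_jD so that the eigenvalue-average definition is
self-consistent; a single-evaluation mode (`self_consistent=False`, CLI
`--no-self-consistent`) is exposed because either reading of the definition
is defensible.  Evaluations within 10⁻⁶ eV of a bridge eigenvalue raise a
pole error naming the offending eigenvalue.

Accuracy: for a mirror-symmetric system the exact spectrum shows a
quasi-degenerate pair split by 2|T_DA|; with asymmetric bridging the dressed
donor/acceptor levels detune by δ and the splitting becomes √(δ²+4T²) —
the property tests verify both against exact diagonalization with a
(β/Δ)²-scaled tolerance.

The empirical pathways model multiplies per-step decay factors — covalent
0.6, hydrogen bond 0.36·e^(−1.7(R−2.8)), through-space 0.6·e^(−1.7(R−1.4)),
R in Å.  These constants come from the cited pathways literature and are
overridable via `PathwayParams`.

## Stochastic hole propagation

The propagation module is a deliberately reduced surrogate for non-adiabatic
QM/MM charge transport.  Instead of explicit solvent and protein atoms it
keeps three mechanisms:

1. **Thermal fluctuations.** Each site energy carries an Ornstein–Uhlenbeck
   process (exact discretization, stationary start).  Defaults: sd 0.15 eV,
   correlation time 0.1 ps — typical thermal site-energy spreads for
   aromatic radicals in a protein.  Fluctuations transiently bring sites
   into resonance; transfer happens at those crossings.
2. **Charge response (outer-sphere reorganization).** An auxiliary
   polarization coordinate q̄_i relaxes toward the instantaneous occupation
   with time constant τ_s (default 1 ps) and lowers site i by
   (λ_i/polarization_scale)·q̄_i.  Defaults λ = 0.7 eV per site and
   polarization_scale = 1.4 give an effective trapping depth of 0.5 eV,
   matching the charged-state stabilization scale of these systems.  The
   polarization scale divides all environment-induced terms (noise sd and
   λ), mimicking electronic screening.
3. **Decoherence as stochastic localization.** With probability
   1 − e^(−dt/τ_d) per step (τ_d default 10 fs) the wavefunction collapses
   onto one site drawn from the instantaneous occupations.  This is the
   quantum-jump unravelling of coherence damping: the ensemble-mean
   occupations are unbiased by each collapse event.

The third point is a deliberate design decision.  Mean-field propagation
with *deterministic* coherence damping (a Haken–Strobl model) has a
population flux proportional to the occupation difference — an
infinite-temperature artifact of classical noise — and every trajectory
relaxes to uniform occupations regardless of the energy landscape; no
parameter choice fixes this.  Stochastic localization keeps each trajectory
on essentially one site between hops, so the charge-response term deepens
the occupied site and back-transfer requires a rare uphill fluctuation:
forward hops after relaxation are near-resonant (the 0.4 eV downhill steps
roughly cancel against the 0.5 eV trapping depth, the Marcus activationless
regime) while reverse hops sit ~0.9 eV off resonance.  The deterministic
damping operator is still provided (`apply_decoherence`) as the
density-matrix counterpart with its own closed-form tests.

Numerics: the propagator is the exact exponential of the instantaneous 3×3
Hamiltonian via eigendecomposition (unitary to machine precision; default
dt = 1 fs), so the coherent limit (λ = 0, no noise, no decoherence)
reproduces the closed-form Rabi period exactly.  Occupations are emitted on
a configurable output grid (default 0.1 ps, fine enough for the 500 fs
dwell bookkeeping of the transfer statistics).  Only oxidisable sites may
be propagated; the flavin acts as the spectator counter-ion and is rejected
from the subspace.

In the strongly downhill regime (0.4 eV steps, meV couplings, strong
decoherence) ensembles localize ≥95% of the charge on the terminal site
within 1 ns, and ensemble-averaged occupations are described by the
three-state hopping model to RMS < 0.05 — both verified in the test suite
at reduced problem sizes (3 × 1 ns trajectories at 5 fs steps; 120 × 8 ps
trajectories for the master-equation cross-check).

## Hopping kinetics

The kinetic model is the strict linear chain RP-A ⇌ RP-B ⇌ RP-C with four
rates in ns⁻¹ (no direct A–C channel, enforced structurally).  The master
equation dp/dt = Kp is solved by eigendecomposition of the generator (expm
stepping as fallback); the stationary state has the closed form
p_A : p_B : p_C = k21·k32 : k12·k32 : k12·k23.  Gillespie simulation
provides exact stochastic realizations for the synthetic generator.

`fit_rates` fits all three mean-occupation curves simultaneously by
weighted least squares with ≥8 log-spaced multi-starts over [1, 10⁴] ns⁻¹.
Weights are inverse per-point SD when SDs are provided, floored at the
smallest positive observed SD — zero-variance points (all replicates
agreeing) must not be treated as infinitely precise — and uniform
otherwise.  Rates pinned at a bound are reported in the fit diagnostics
(e.g. k23 when the terminal site is never populated).

A practical identifiability note: with 25 replicates on a 1 ps grid the
refitted k12 has an intrinsic statistical spread of roughly 20% (the
fastest dwell is barely resolved by the grid); recovery statements therefore
refer to fixed replicate ensembles.

## Transfer statistics

A time point is assigned to a site when that site's occupation exceeds the
threshold (default 50%, strict inequality; ties are "delocalized"); the
threshold must exceed 1/n_sites so the assignment is unique.  Back-transfer
counting and residence times use a minimum dwell of 0.5 ps.  Delocalized
gaps no longer than one output step (default 0.1 ps) do not break a
transition or a dwell; the gap's duration is credited to the following
segment.  Both dwell-filtered and unfiltered transition counts are
available (`count_all`), since a counting rule based on thresholded
occupations can reasonably be read either way.

## Photoreduction kinetics

The 450 nm channel (oxidised FAD) is normalized to its t = 0 value and
fitted with y = offset + A·e^(−t/τ), initialized from a log-linear
regression on baseline-subtracted values.  The 580 nm channel (protonated
semiquinone) is baseline-subtracted and normalized to A280, then fitted
with y = a·(e^(−t/τ_decay) − e^(−t/τ_rise)).  The two channels are fitted
independently with empirical forms; no attempt is made to force both into a
single mechanism (the sequential two-step redox model ox → semi → red is
provided only as a generator).  Identifiability of the rise–decay fit is
enforced by parametrizing τ_decay = τ_rise(1 + g) with g > 0, which makes
the result invariant to swapped initializations; when g collapses below
2×10⁻² the constants are degenerate and the limit form a·t·e^(−t/τ) is
fitted instead.  Uncertainties are 1-σ values from the linearized
covariance.  Flat series are flagged as unidentifiable rather than fitted.

## Structural descriptors

PDB files are read through biotite: one frame per MODEL, highest-occupancy
conformer for alternate locations, coordinates in Å, author (1-based)
residue numbering.  Centre-of-mass distances are Euclidean distances of
mass-weighted centroids, averaged over frames when several are given.  The
water RDF bins, for each probe oxygen, its minimum distance to the atoms of
the centre selection (closest-atom convention; a centre-of-mass mode is
exposed as well since either convention is defensible), normalized by
ideal-gas shell counts at the frame's mean probe density — box volume under
periodic boundary conditions (orthorhombic minimum image), the r_max sphere
otherwise.  N(r) is the raw mean cumulative count (hydration number).
Hydrogen bonds use conventional geometric cutoffs, donor–acceptor ≤ 3.5 Å
and D–H···A angle ≥ 135°.

## Synthetic data and what passing tests mean

Every generator records its ground truth in sidecar metadata and is fully
reproducible by seed.

* Occupation ensembles: Gillespie indicator averages (with per-replicate
  trajectories) or master-equation means with truncated/renormalized
  Gaussian noise.  They emulate averaged hopping dynamics — not the
  coherent sub-picosecond structure, non-Markovian environment memory or
  charge-recombination channels of real trajectories.
* Absorbance traces: mono-exponential A450, difference-of-exponentials A580
  excess, constant A280, multiplicative Gaussian noise (default 1%).  Real
  photoreduction data add baseline drift, scattering and correlated noise.
* Parameter presets (`SYSTEM_PRESETS`): site energies −6.3 eV (Tyr A, wild
  type) and −5.8 eV (Trp sites); B–C couplings 4.15 meV (wild type) and
  9.0/7.0 meV for the proximal/distal Trp rotamer, assigned by their B–C
  distance ordering.  A–B couplings are not published numerically; the
  presets use 4 meV (wild type) and 8 meV (rotamers, couplings roughly
  double on Tyr→Trp substitution), and the distal rotamer's A site sits
  0.08 eV closer to B than the proximal one's.  These four numbers are the
  package's documented choices, overridable per call.
* Solvation fixtures: uniform (flat g(r)) or Gaussian-shell (known peak)
  water-oxygen clouds around a single centre atom.

Passing the recovery and property suites therefore demonstrates internal
consistency of the estimators under the stated noise models, not agreement
with any particular experimental dataset.

## Known limitations

* The propagation surrogate has no explicit nuclei: detailed balance enters
  only through the reorganization ratchet, so near-isoenergetic sites
  equilibrate toward equal rather than Boltzmann populations.
* Quantities that require the original MD/QM-MM trajectory ensembles
  (per-frame coupling distributions, MD-averaged distances, absolute ν/τ
  values of specific mutants) are out of scope; the package reproduces the
  counting rules and kinetic analysis, not those datasets.
* The linear three-state chain has no recombination channel back to the
  flavin; model selection among alternative schemes is out of scope.
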
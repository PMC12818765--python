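# Methods

`stochtit` implements the computational core of discrete constant-pH
molecular dynamics in the *stochastic-titration* formulation: the
force-field charge-localization protocol that makes an additive force
field compatible with Poisson–Boltzmann (PB) protonation energetics, the
semigrand-canonical Monte Carlo (MC) sampler over protonation and tautomer
states, the MD/MC alternation contract, and the titration analytics and
convergence diagnostics used to validate such a method.  The MD engine and
the finite-difference PB solver themselves are deliberately outside the
package: dynamics and electrostatics enter through pluggable backends and
matrix inputs, so every algorithmic component is exercisable at desk scale
against exact oracles.

## Protonation model and units

All protonation free energies are carried in **pK units** (energy divided
by kT·ln10), so that one unit corresponds to one pH unit and the
Metropolis factor is `10**(-dE)`.  A system of N titratable sites, each
with one or more protonation/tautomer states, has configurational energy

    E(s) = Σ_i n_i (pH − pKint_i)  +  Σ_i δ_i(s_i)  +  Σ_{i<j} W_ij n_i n_j

where `n_i ∈ {0,1}` is the proton count of site i's chosen state,
`pKint_i` is its intrinsic pKa (the pKa in the environment with all other
sites in reference states), `δ_i` is a tautomer-specific offset (zero for
each protonation count's reference tautomer), and `W` is the symmetric
site–site coupling matrix in pK units with zero diagonal.

The pH field term is the same for acids and bases: any isolated site then
titrates exactly along Henderson–Hasselbalch,
`⟨n⟩ = 1/(1 + 10^(pH − pKint))`.  Acid/base polarity enters only through
the charge map (acid: −1 deprotonated / 0 protonated; base: 0 / +1).
This is a deliberate design decision: an energy whose sign flips with
polarity would make base protonation increase with pH, breaking the
Henderson–Hasselbalch anchor, the monotonicity of total charge against pH
and the definition of the isoelectric point.  The consequence is that the
charge curves of a matched acid/base pair are antisymmetric mirrors about
their shared midpoint, `q_base(pK − d) = −q_acid(pK + d)`, which the test
suite checks.

In the full method `pKint` and `W` come from a PB solver (historically
DelPhi with a two-focusing scheme, protein dielectric 2, solvent 80,
0.1/0.025 nm grids, 0.01 kT/e convergence); those settings are carried
here only as configuration metadata (`CycleConfig.pb_settings`).  The
in-package substitute is a **screened-Coulomb surrogate**,

    W_ij = q_i q_j · C · exp(−κ r_ij) / (ε r_ij),

with `C = e²/(4π ε₀ · 1 nm · kT ln10) ≈ 24.19 pK·nm` at 300 K, `q_i` the
charge of site i's charged state (acid −1, base +1), coordinates in nm,
`ε` a uniform dielectric and `κ` an inverse screening length in nm⁻¹.
It reproduces the qualitative structure that matters to the sampler —
symmetry, monotonic distance decay, sign from the charge product, and
magnitudes of a few pK at sub-nm separations — not real protein
electrostatics.  Couplings can equally be supplied as a matrix file.

## Monte Carlo sampler

One MC **cycle** is a randomized sweep that attempts

* one state change for every site (uniform proposal over the site's other
  states), and
* one joint change for every **strongly coupled pair** — pairs with
  `|W_ij|` above the pair threshold, default 2.0 pK — proposing uniformly
  over the pair's joint state space excluding the current assignment.

Moves are accepted with probability `min(1, 10^(-dE))`.  Both proposal
distributions are symmetric, so detailed balance holds and the chain
samples `10^(-E)/Z`.  Pair moves exist to unstick anticorrelated
double-site configurations that single flips cross only through a high
barrier.  Defaults follow the method as practised: 10⁵ cycles per MC run,
pair threshold 2 pK.  Burn-in (default 10% of cycles) and block-averaged
standard errors (20 blocks) are the package's own choices; block averaging
absorbs the short autocorrelation the sweep induces.

`enumerate_exact` sums the semigrand partition function over the full
mixed-radix state space (capped at 2²⁰ configurations) and is the oracle
the sampler is validated against; for ≤ 12-site systems the suite requires
MC means within three standard errors of enumeration for ≥ 95% of
(site, pH) pairs.  Two numerical notes:

* **Pinned sites.**  When a site's exact occupancy p satisfies
  `p·N ≲ 3` for N measured cycles, a correct sampler most likely records
  zero flips, so the estimate is exactly 0 (or 1) with zero block SE.
  Comparisons therefore add the rule-of-three floor `3/N` — the 95% upper
  confidence bound on p after zero observed events — to the 3·SE band.
* **Midpoint parity.**  At exactly pH = pKint with zero couplings every
  proposal has dE = 0 and is accepted, so a single-site trajectory
  alternates deterministically.  Cycle means are still correct; only the
  *final state* of an even-length run is deterministic.  Tests that look
  at segment-final states use odd cycle counts or off-midpoint pH.

## The stochastic-titration loop

`run_stochastic_titration` preserves the method's control flow without an
integrator: for each of `n_segments` iterations it advances an abstract
conformation by `segment_length_ps` (default 20 ps) through the dynamics
backend, obtains the conformation's `SiteSystem` from the energy backend,
runs the protonation MC continuing from the previous state, and — exactly
when the sampled state changed — invokes the solvent-relaxation hook
(`relaxation_length_ps`, default 0.2 ps, frozen solute).  Occupancies are
recorded once per segment, at the MC interruptions.  Times are
bookkeeping passed to the backends; the mock backends (static,
deterministic cycling, table lookup) make the loop testable: with a static
backend the per-site segment means must converge to `enumerate_exact` for
the fixed conformation (the loop adds no bias), and a two-conformation
toggle must be bracketed by the two static answers.  The relaxation hook
is a no-op for mock backends; whether solvent relaxation affects
protonation statistics in the full method is outside what this package
can test.

## Charge localization

PB-based protonation sampling requires that switching a side chain's
protonation state moves integer charge, i.e. no charge propagation
between side chain and backbone.  Additive force fields in the AMBER
family violate this by construction.  `localize_side_chain` restores
locality minimally: with the residue partitioned into backbone
(N,H,C,O…), the Cα group (Cα, Hα), the Cβ group (Cβ and bound
hydrogens) and the side chain proper, the residual
`δ = (side chain + Cβ group) − integer formal side-chain charge` is
subtracted from the Cβ group and added to the Cα group.  Two split
policies are offered: `heavy_only` (default — the whole δ moves between
the heavy atoms, deterministic and minimal) and `proportional`
(distributed within each group by |charge|).  Proline, whose backbone
nitrogen bonds through Cδ, uses a residue-specific group map: the
backbone-side correction spreads evenly over Cα and Cδ, the side-chain
side over Cβ and Cγ.  Blocks flagged `frozen` (e.g. a charged N-terminal
glycine kept in its published form) pass through untouched.  Residuals
above 0.5 e are flagged suspicious but not fatal.

Terminus construction mirrors the same protocol: backbone charges are
averaged over the terminus blocks of the library (Pro and Gly excluded),
the Cα group absorbs the residual so the template keeps integer charges;
neutral termini graft amine (N,H1,H2,H3) or carboxyl
(C,OC1,OC2,HC11…) charges from a neutral-amine / protonated-acid donor
block and re-balance the Cα group to total charge zero.

Numerical conventions: "integer" means within 1e-6 e (typical topology
file precision); residuals below 1e-12 e are treated as float dust and
not moved, which makes localization bitwise idempotent.  Round trips
through the rtp-style text dialect preserve charges at the 6-decimal
printed precision, and unknown sections are preserved verbatim.

## Titration analytics

Per-site curves are fitted with the base-10 Hill equation
`f(pH) = 1/(1 + 10^{n (pH − pKa)})` (n = 1 reduces to
Henderson–Hasselbalch) by bounded nonlinear least squares, pKa
initialized at the grid point nearest half-occupancy and n at 1; a
fixed-n mode is exposed because published fits do not always float the
coefficient.  Parameter errors use a leave-one-out **jackknife over
replicate simulations** (not over pH points): refit each leave-one-out
mean curve, `SE² = (m−1)/m · Σ (θ_i − θ̄)²`; identical replicates give
exactly zero.  Curves that never bracket half-occupancy are flagged
`extrapolated` with a direction tag and refuse downstream calibration;
this mirrors practice for tyrosines, whose pKa typically lies above the
titrated range.

The total titration curve sums mean site charges per pH; the isoelectric
point is the unique zero crossing by linear interpolation, with explicit
errors for no crossing (sign reported) or multiple crossings (all listed).

Model-compound calibration (`calibrate_pkmod`) updates
`pK^mod ← pK^mod + (pKa_exp − pKa_fit)` using the Hill fit of a simulated
model-compound titration; for an isolated site the map is a contraction
and two iterations suffice to reach the experimental target within MC
error, which the suite and the acceptance script verify in closed loop.

## Benchmarking and the bundled pKa tables

`benchmark` computes prediction RMSE, **null-model** RMSE and per-type
mean errors over a table of (residue, type, predicted, experimental,
null) values.  The null model assigns every residue its residue-type
reference pKa measured by NMR on alanine-based pentapeptides
(Ala₂-X-Ala₂) in water — Asp 3.94, Glu 4.25, His 6.54, Cys 8.55,
Tyr 9.84, Lys 10.40, N-terminus 8.00, C-terminus 3.67 — a
structure-blind control.  Tyrosines are excluded by default (flag to
override); rows without experimental values are skipped with a log entry.

Two experimental compilations ship with the package.  The hen egg-white
lysozyme table (18 residues, Tyr excluded) is compiled from the NMR
literature and yields a null-model RMSE of 1.27, matching the value
reported for this benchmark set.  The staphylococcal nuclease table
(17 residues) is a **synthetic reconstruction**: carboxylic-acid pKas from
the hyperstable-variant NMR measurements plus His-46/His-121.  The exact
residue subset and experimental compilation used in published benchmarks
of this protein could not be recovered, and this reconstruction gives a
null-model RMSE of 1.09 rather than the published 0.76; treat
SNase-derived aggregate numbers as illustrative, not comparable.

## Diagnostics

* **KL divergence** between histograms on shared bin edges, in nats
  (base e; the base used in published figures is not stated, so this is a
  documented assumption).  Default edges: Freedman–Diaconis on the pooled
  series.  Empty reference bins opposite occupied ones receive a
  pseudocount of `1/(10 · total count)` before renormalization; the
  divergence is ≥ 0 and exactly 0 iff the normalized histograms are
  bitwise equal.  The cumulative profile recomputes the divergence on
  growing prefixes with fixed edges, so the last value equals the
  full-series divergence; profiles falling below ~0.04 nats are the
  working notion of "indistinguishable" sampling.
* **Pseudodihedrals** (Cβ–Cα–Cα–Cβ and friends) use the standard signed
  torsion with the IUPAC sign convention, range (−180, 180], verified
  against an independent vector-algebra oracle to 1e-9 degrees and
  cross-checked against MDAnalysis (float32, hence 1e-3).  The empirical
  bimodal classification splits the circle into angle1 =
  [−180, −40.5] ∪ [118.5, 180] and angle2 = (−40.5, 118.5); boundary
  values belong to angle1 so the regions partition the circle and
  prevalences sum to one exactly.
* **Interaction fractions** count frames with side-chain distance
  strictly below a cutoff (0.6 nm for contact, 0.4 nm for tight contact in
  the analyses this mirrors), normalized by all analyzed frames of the
  equilibrated segment.  Minimal PDB reading (ATOM records via Biopython,
  Å → nm) supplies per-model minimum side-chain heavy-atom distances.

## Synthetic data

Every generator takes an explicit seed and embeds its parameters, so
tests assert recovery against ground truth; there is no hidden global
random state.  `make_titration_replicates` emulates triplicate fixed-pH
simulations over the integer pH 1–12 grid: exact Hill occupancies plus
i.i.d. Gaussian noise (default σ = 0.02, the scale of replicate scatter in
converged occupancy estimates), clipped to [0,1].  `make_residue_block`
produces topology blocks whose side chain is off-integer by a prescribed
imbalance; `make_synthetic_system` draws intrinsic pKas uniformly
(default 2–11) with Gaussian couplings of configurable scale (≈1.5 pK
exercises both move types; 3 pK guarantees pairs above the pair-move
threshold); `make_pdb_pair` writes multi-MODEL PDBs with exactly known
side-chain separations.  What the generators do **not** emulate:
conformational coupling between protonation and structure, correlated
noise between replicates, and real electrostatics beyond the
screened-Coulomb surrogate — so passing tests demonstrate algorithmic
correctness, not force-field accuracy on real proteins.

## Problem sizes

The test suite and the acceptance script run sampler validations at
2–12 sites with 2·10⁴ MC cycles (50 random systems × 5 pH values),
isolated-site checks at 10⁵ cycles, 10³-block charge-protocol sweeps,
100-dataset fit-recovery studies and 3-replicate calibration loops; the
full suite completes in well under a minute of CPU plus numba
compilation.  These sizes give standard errors a decade below every
tolerance asserted.

## Known limitations

No real dynamics or PB electrostatics (by design); tautomer bookkeeping
supports per-state intrinsic shifts but not the full model-compound
free-energy decomposition of production implementations; the SNase
benchmark table is a reconstruction (above); `enumerate_exact` is capped
at 2²⁰ configurations; MC reproducibility is per-platform (numba's RNG),
though all validation margins dwarf cross-platform float differences.
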
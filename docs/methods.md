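# Methods

## Model overview

`hingeflex` implements a residue/nucleotide-level coarse-grained model for
protein–dsDNA association, together with an AFM-image flexible-fitting
restraint and the trajectory analyses that turn simulations into binding
statistics.

**Protein.** One bead per amino acid at the Cα position. The intra-molecular
potential is structure-based: harmonic bonds `k_b (r − r0)²`, harmonic
angles `k_a (θ − θ0)²`, periodic dihedrals `k_d (1 − cos(φ − φ0))`, all
referenced to the input ("native") structure, plus a 12-10 Gō well
`ε_c [5 (r0/r)¹² − 6 (r0/r)¹⁰]` for residue pairs within 6.5 Å in the native
structure (sequence separation ≥ 4 within a chain). The local terms are
deliberately simpler than sequence-dependent statistical potentials: the
questions the package addresses (where DNA binds, how strongly, whether a
hinge can close around it) are decided by the *inter*-molecular physics, and
the intra-molecular terms only need to hold folds and subunit interfaces
together, which the harmonic-plus-Gō combination does.

**DNA.** Three beads per nucleotide (phosphate, sugar, base) threaded on an
ideal B-form helix (rise 3.38 Å, twist 34.3°/bp; helical radii 8.9 / 6.9 /
2.0 Å — all configurable constants). The 5′-terminal phosphate is omitted,
the common CG convention, so an N-bp duplex has 6N − 2 beads. Duplex shape
stability comes from Gō-type contacts among all non-bonded intra-duplex bead
pairs within 9 Å at construction; there is no melting, base-pairing
thermodynamics, or sequence-dependent shape. Phosphates carry −0.6 e
(counterion-condensation convention), configurable.

**Protein–DNA interaction.** Only two terms act between molecules:

* Debye–Hückel electrostatics
  `U = k_e q_i q_j exp(−r/λ_D) / (ε_k r)`, with
  `λ_D = sqrt(ε0 ε_k k_B T / (2 N_A e² I))` computed from SI constants and
  returned in Å (≈ 9.6 Å at 100 mM, 300 K, ε_k = 78). The Coulomb prefactor
  is 332.0637 kcal·Å/(mol·e²); the dielectric defaults to a fixed 78.
  Interactions are truncated at 5 λ_D with an energy shift. Exclusions: 1-2
  and 1-3 bonded neighbours.
* Excluded volume `ε_ev [(σ/r)¹² − 1]` for r < σ = r_i + r_j, zero beyond
  (ε_ev = 0.6 kcal/mol; Cα radius 2.0 Å so the Cα–Cα core is ~4 Å).
  Excluded volume skips 1-2/1-3/1-4 neighbours and native-contact pairs,
  whose repulsive cores live in the bonded and 12-10 terms.

Surface charges can be assigned three ways: unit charges by residue type,
a least-squares fit that reproduces a reference electrostatic potential
sampled around the molecule (ridge-regularized, with an optional exact
total-charge constraint; the package's analog of surface-charge fitting
against an all-atom reference), or a seeded random permutation of an
existing charge set — the negative control for the claim that the charge
*arrangement*, not just the net charge, dictates the binding surface.

## AFM restraint

A pseudo-AFM image is rendered from coordinates: pixel height is the (soft)
maximum of bead-top heights `z + r` over beads whose lateral position falls
within the pixel's capture half-width (pixel/2 + tip apex radius; apex
defaults to 0, a point tip — real tip-sample mechanics are out of scope).
The smooth variant is a log-sum-exp with sharpness β (default 2 Å⁻¹) and a
lateral quadratic falloff (stiffness 4 Å⁻¹) so that heights are
differentiable in all bead coordinates and converge to the hard maximum for
beads away from pixel boundaries.

The restraint energy is `V = κ k_B T (1 − c.s.)`, where c.s. is the cosine
similarity `Σ H_ref H_sim / (‖H_ref‖ ‖H_sim‖)` between reference and
pseudo-image; κ is dimensionless (units of k_B T). Forces are analytic via
the chain rule through the pixel heights and vanish when the pseudo-image
matches the reference up to scale. If the molecule leaves the imaged region
(all-zero pseudo-image) the similarity is undefined: no force is applied
and the frame is flagged.

**Hinge-angle metrology.** From the highest pixel of the (masked) image,
height sums are accumulated in 10-pixel-long, 5-pixel-wide radial windows
on a 1° grid (bilinear sampling). The two best circular local maxima at
least 20° apart define the arm directions. The window starts 4 px out from
the peak: the near-junction pixels of the *other* arm otherwise bias both
directions toward the bisector (an inward bias of up to ~8° on synthetic
two-rod images). With this offset the construction angle of synthetic
two-arm images is recovered within ~4° over 40–170°. Angle distributions
are fitted with a seeded two-Gaussian EM mixture (k-means initialization).

## Dynamics

Underdamped Langevin dynamics with a BAOAB-ordered splitting whose
friction/noise substep is the exact Ornstein–Uhlenbeck update; it satisfies
fluctuation–dissipation at any friction (harmonic position variance
reproduces k_B T/k within statistical error) and reduces exactly to
velocity Verlet as γ → 0. Friction 0.843 (1/CG-time) and timestep 0.2
(CG-time) follow common CG practice. Mass is uniform and dimensionless,
default 10 CG units; together with γ this sets the (unreported) time scale,
and all rates are quoted per integration step, never in seconds. The bond
constant (50 kcal/mol/Å²) keeps Δt·ω ≈ 0.6 at these masses. Near-collinear
dihedral quadruples have their torsion normals floored (equivalent to
sin θ ≥ 0.05) because the exact torsion force is singular there; the event
is flagged.

Periodic boxes wrap pair interactions by the minimum-image convention while
stored coordinates stay unwrapped; bonded terms always use unwrapped
coordinates. Each run draws its velocities and noise from a
`numpy.random.Generator` seeded from the run config; protocols spawn
independent child seeds from one master seed via `SeedSequence`, so every
batch is reproducible bit-for-bit.

## Analyses

* **Contact profile:** per protein bead, the fraction of frames with any
  DNA bead within 10 Å (configurable; recorded in output headers).
* **Binding events:** hysteretic per-(site, DNA copy) state machine —
  bound below d_on = 10 Å, unbound above d_off = 15 Å (the pre-bound
  dwell-time assays use 8/12 Å to keep the diffusive leg of an escape
  short). Events running to the last frame are censored.
* **Survival / rates:** product-limit (Kaplan–Meier) survival of event
  durations; the dissociation rate is the negated weighted-least-squares
  slope of ln P over P ∈ [0.1, 1] (weights: at-risk counts), with a
  bootstrap-over-events standard error.
* **Q-scores:** fraction of native contacts with current distance below
  1.2× the native distance; inter- and intra-subunit variants select
  contact subsets. The protein–DNA variant counts reference-contacting
  residues within 15 Å of *any* DNA bead, neglecting DNA bead identity so
  the score is robust to the duplex sliding along its axis.
* **Representative structure:** per frame, the vector of minimum distances
  from each binding-site residue to any DNA bead; PCA to the first three
  components; the frame with the most neighbours within radius 10
  (unitless PC space) wins, earliest frame on ties.
* **Conservation:** per query residue, the fraction of aligned sequences
  matching the query character; alignment gaps are excluded from the
  denominator by default (configurable). This simple identity fraction is
  a declared choice — more elaborate conservation scores exist, but the
  downstream use (colouring residues, thresholding at 0.8) only needs a
  monotone per-column agreement measure.

## Synthetic data: what it emulates, and what it does not

The generators produce every fixture the pipeline consumes, with ground
truth stored in metadata so recovery tests never re-derive it.

* **Toy hinge** (`make_toy_hinge`): two 10-bead helical arms joined by a
  soft 3-bead junction loop in a single chain, native inter-arm angle 30°.
  Inter-arm contacts exist only near the junction, so opening breaks them
  while intra-arm contacts persist — the same contact classes (inter- vs
  intra-subunit) used to score the real hinge. Six inner-face beads carry
  +0.5 e each, the analog of the conserved basic residues on the hinge
  inside. A single chain with a bonded junction was chosen over two free
  chains so that restraint release has a defined reclosure pathway at
  desk scale; it plays the role of the intact pivot interface of the real
  doughnut-shaped hinge. The junction loop's angle/dihedral terms are soft
  (2.0 / 0.2 kcal/mol) so a moderate image restraint can open it.
* **Synthetic AFM images** (`synth_afm_image`): two Gaussian-cross-section
  rod ridges meeting at a bright junction bump, additive Gaussian noise,
  heights clipped at zero. They mimic the geometry an open hinge presents
  to the metrology, not real AFM noise spectra, drift, or tip artefacts.
* **Dwell times** (`synth_dwell_times`): exponential draws with optional
  right-censoring — exactly the statistical model the survival analysis
  assumes, so they test the estimator, not the model's realism.
* **Protocol toys:** a 3×3 rigid slab with a cationic patch (binding-site
  analog; the dwell-time assays start from the duplex pre-bound at the
  patch, making dissociation rather than diffusion-limited association the
  observable), and a closed 8-bead ring threaded on a duplex (topological
  trap for the slide-off assay; with the box's z edge matched to the
  helical repeat the duplex is effectively endless and no exit can occur).

Passing these tests demonstrates that the machinery — forces, integrator,
restraint, detectors, estimators — is correct and that the qualitative
physics (screening weakens binding; moderate restraints fit without
distortion; release recloses around retained DNA) emerges at toy scale. It
does not demonstrate quantitative accuracy for condensin-sized systems,
which require the real structures, fitted surface charges, and orders of
magnitude more sampling.

## Problem sizes

The package's default protocol sizes are chosen so each study runs in
minutes on one CPU: fitting runs of 3,000 steps (20 seeds per κ), closure
runs of 25,000 steps (≈ mean closure at ~4,000 steps plus margin), and
dwell-time runs of 35,000 steps (6–8 seeds per salt). The toy fitting
strengths κ = 150 (moderate) and κ = 3000 (over-strong) were calibrated on
the toy hinge the same way the full-scale protocol calibrates its κ — by
scoring intra-subunit integrity against fitting success across a κ ladder —
since the appropriate κ scales with system size and image resolution.

## Known limitations

* No hydrophobic or sequence-specific protein–DNA terms: binding surfaces
  are purely electrostatic/steric predictions.
* No base-pairing thermodynamics; duplexes cannot melt, bend anisotropically
  by sequence, or form non-B geometry.
* The pseudo-AFM renderer uses a point tip by default; finite-apex effects
  are limited to a lateral capture radius, with no tip-sample mechanics.
* Rates are per integration step; mapping to physical time is undefined in
  this model class.
* Energies use a fixed dielectric; an ionic-strength/temperature-dependent
  dielectric is not enabled by default.
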
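# Methods

`cotrafold` simulates and analyses the cotranslational folding of a small
helix-bundle protein released residue by residue from the ribosomal exit
tunnel.  This note documents the model, its assumptions, the calibrated
defaults, and what the synthetic inputs do and do not emulate.

## The physical picture

A nascent α-helical protein leaves the ribosome with much of its secondary
structure already formed, but extended: tertiary assembly happens during
and after extraction from the exit tunnel.  The release speed biases which
folding route is taken.  If the chain is released quickly, the C-terminal
segment can fold first and the chain follows the productive route through
the on-pathway intermediate (I_on); slow release gives the N-terminal
segment time to collapse on its own, populating the misfolded off-pathway
intermediate (I_off), which must unfold before the native state (F) is
reachable.

The package represents this with three ingredients:

1. a **Cα structure-based (Gō-type) model** whose only attractive
   interactions are the native contacts, so the energy landscape is
   funnelled toward the reference structure;
2. a **co-release protocol**: a cylindrical soft-wall confinement plus a
   stepwise schedule that frees one residue per interval τ, N-terminus
   first, so a chain of L residues is fully released at t = L·τ;
3. the **analysis stack**: segment RMSD order parameters, long-range
   contact ratios, binned free-energy landscapes, a four-state classifier
   and censored first-passage statistics.

## The potential

With one bead per residue (unit mass; lengths in Å; energies in units of
the contact well depth ε; temperature in ε/k_B; time in τ = √(mÅ²/ε)):

| term | form | default |
|---|---|---|
| bonds | k_b (r − r₀)² | k_b = 100 ε/Å² |
| pseudo-angles | k_a (θ − θ₀)² | k_a = 20 ε/rad² |
| pseudo-dihedrals | k₁[1 − cos(φ − φ₀)] + k₃[1 − cos 3(φ − φ₀)] | k₁ = 1, k₃ = 0.5 ε |
| native contacts | ε[5(σ/r)¹² − 6(σ/r)¹⁰] | ε = 1; σ = native distance |
| non-native pairs | ε_rep(σ_rep/r)¹² | σ_rep = 4 Å |
| tunnel wall | k_w/2 · max(0, ρ − R_c)² + k_w/2 · max(0, x − x_exit)² | k_w = 10 ε/Å², R_c = 7.5 Å |

Native values (r₀, θ₀, φ₀, σ) are read off the reference structure, so
every bonded term is zero and every contact term −ε at the native
geometry.  Native contacts are all residue pairs with Cα–Cα distance
strictly below 7 Å and sequence separation strictly greater than 3; the
same geometric rule defines snapshot contacts in the analysis.  Non-native
|i−j| > 3 pairs are purely repulsive.  The tunnel wall acts only on
still-confined residues, which also feel a one-sided axial wall at the
tunnel mouth; released residues feel no tunnel interaction at all
(nascent-chain–ribosome attraction is deliberately not modelled).

This engine is a coarse-grained substitute for all-atom explicit-solvent
MD: it preserves the phenomenology that matters here — native-contact-
driven folding and the competition between segment cores — at desk scale.
Engine time is reduced units and is never mapped to nanoseconds;
physical-time quantities appear only where printed values (e.g. passage
times in μs) are themselves the inputs.

## Integration

Langevin dynamics with the BAOAB splitting, chosen for its configurational
accuracy at large steps.  Defaults: dt = 5×10⁻⁴ τ.  The symplectic core
(γ = 0, T = 0) shows a secular energy drift of ~2×10⁻⁵ ε per 10⁴ steps at
this dt (measured by linear regression over 5×10⁴ steps; peak-to-peak
fluctuation ~4×10⁻⁴ ε).  The noise stream is a pure function of the run
seed and call count, so identical configurations reproduce trajectories
bit for bit.  A non-finite energy aborts the run with the offending step
index.

Two numerical guards: (i) the torsion force is skipped within ~10⁻³ of
exact three-atom collinearity, where it is mathematically divergent;
(ii) `validate_timestep` runs 10³ zero-temperature steps at build time and
rejects a dt whose energy diverges.

## Calibrated study conditions

The folding temperature of the default bundle is T_f ≈ 0.6 ε/k_B (the
native state is stable at T ≤ 0.5 and melts from T ≈ 0.7).  Production
defaults, fixed once after an engine-calibration scan and used by the
pipeline, the smoke tests and the acceptance script:

* **temperature 0.45** — comfortably below T_f, warm enough to escape
  early collapse traps;
* **friction 0.25 τ⁻¹** — mildly underdamped; folding is roughly an order
  of magnitude faster than at γ = 1 (at T = 0.45, γ = 0.25 all of ten
  calibration seeds folded within 4×10⁶ steps, median ≈ 9×10⁵; at γ = 1
  only a minority fold in that budget).  `step_langevin` itself defaults
  to the conventional γ = 1; the pipeline overrides it.
* **release interval 5 τ** per residue (release phase 175 τ = 3.5×10⁵
  steps for 35 residues) and a **bulk phase of 1.65×10⁶ steps**, giving
  2×10⁶ steps per seed — about 25 s of wall time per seed on one core.
  These problem sizes keep a five-seed campaign plus its high-temperature
  control in the minutes range.
* high-temperature control: T = 3.0, far above T_f.

## Synthetic inputs

**Native bundle** (`make_helix_bundle`): three ideal α-helices (rise 1.5
Å/residue, radius 2.3 Å, 100°/residue; helix parameters fixed, not
sampled, for reproducibility) of 11 + 7 + 11 residues, packed antiparallel
with axes 9.5 Å apart, joined by 3-residue circular-arc linkers that keep
every consecutive Cα distance at 3.8 Å.  The default 35-residue bundle has
34 native contacts (17 intra-helix i,i+4 pairs, 17 tertiary).  Segments
are auto-defined to overlap on the middle helix — N-segment = helices
1–2, C-segment = helices 2–3 — so a chain with both segments folded is
globally native; the `hp35` preset (global 2–34, N 3–21, C 15–33) is
provided for real villin-headpiece structures supplied as PDB files.
The packing distance of 9.5 Å was fixed during the same calibration scan
as the temperature: it maximises folding reliability while keeping the
minimal inter-helix approach (~4.9 Å) realistic.

**Post-tunnel state** (`make_extended_with_helices`): each helix keeps its
exact native local geometry, rigidly rotated onto the −x axis; linkers are
straight segments at native bond lengths with a ±0.4 Å alternating
transverse offset (a perfectly straight linker would sit exactly on the
torsion singularity).  The chain starts at the tunnel mouth and extends
into the tunnel, within the confinement radius, with **no tertiary
contacts**.  Note that q_nat of this state is ≈ 0.5, not 0: helical
i,i+4 pairs are genuine contacts under the < 7 Å, |i−j| > 3 rule (this is
equally true of real α-helical proteins), so the observable that marks the
extended state is the absence of inter-helix contacts and q_non = 0.

**Scripted series** (`make_scripted_series`): order-parameter trajectories
with known state dwell schedules, each frame's (RMSD_N, RMSD_C, RMSD_global)
drawn from its state's basin centre plus zero-truncated Gaussian noise.
These carry ground-truth labels and exercise the whole analysis stack
without the engine.

What the synthetic data does **not** emulate: real side-chain packing and
sequence-specific stability; helix fraying; the all-atom unfolded-state
ensemble; solvent and ion effects; and the specific stochastic outcomes of
any published all-atom campaign.  Passing tests therefore demonstrate that
the protocol and analysis are implemented correctly and that the engine
folds a funnelled model under confinement-release conditions — not that a
particular real protein folds with particular rates.

## Analysis conventions

* **RMSDs**: optimal proper-rotation (Kabsch) superposition, unweighted,
  each selection superposed independently (global = residues 2–34 for a
  35-mer, excluding the flexible termini).  The RMSD is recomputed from
  the rotated coordinates rather than taken from the solver's residual,
  which loses ~10⁻⁷ Å to cancellation.
* **Contact ratios**: Q_nat = |C ∩ S|/|S|, Q_non = |C \ S|/|S| with S the
  native set and C the snapshot set under the same rule; both share the
  native denominator, so Q_non can exceed 1 in collapsed non-native
  states.  Per-frame values are reported; a block average with a
  configurable window is provided for time profiles.
* **Free-energy landscape**: F = −RT ln(N/N_T) in kcal/mol
  (R = 1.987204×10⁻³ kcal/(mol·K), T defaults to 300 K), pooled over
  trajectories, on half-open square bins [lo, hi) of 0.1 Å anchored at 0 —
  a frame exactly on an edge belongs to the upper bin.  Empty bins are
  masked (NaN), not ±∞, so downstream statistics stay finite.  The modal
  bin attains the minimum by construction and ΣN = N_T exactly.
* **State classifier**: F iff global RMSD < 2 Å (strict); otherwise I_on
  if RMSD_C < t ≤ RMSD_N, I_off for the mirror case, else U.  The segment
  threshold t defaults to the same 2 Å as the folded criterion — basin
  boundaries on published landscapes are a visual convention, so this
  threshold is this package's own, and it is configurable
  (`StateThresholds`).  A frame with both segments below t but global ≥ 2 Å
  is labelled U (partially assembled but not packed).
* **MFPT**: first frame with global RMSD < 2 Å; non-crossing trajectories
  are censored by substituting the cap itself, and the mean is taken over
  all trajectories.  This reproduces the censored-mean convention exactly,
  although it biases the estimate low under heavy censoring; a
  Kaplan–Meier restricted mean is available (`FptResult.kaplan_meier_mean`)
  but is not the default.

## Known limitations

* The tunnel is a featureless soft cylinder (R_c = 7.5 Å, wide enough for
  an α-helix); no atomistic ribosome surface, no chaperones, and the
  wall stiffness/axial containment are this package's own choices.
* Uniform per-residue release interval only (codon-specific rates would
  be a config extension and are untested).
* Reduced→physical time mapping is deliberately not attempted.
* Only the +x tunnel axis is implemented.
* The classifier thresholds and the synthetic bundle geometry are
  conventions; quantitative conclusions about a specific protein require
  supplying its real structure and re-deriving its segment definitions.
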
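# Methods

`bindsurf` re-implements, at desk scale, the computational arm of a
peptide-antagonist design study: quantifying which residues of a
calcium-sensor protein (calmodulin, calbindin-D28k) are buried when the
amyloid-β(1–42) peptide docks onto it, filtering candidate docked poses
against experimental constraints, converting the receptor's interface hot
spots into a short linear mimetic peptide, and fitting the fluorescence
kinetics that measure complex formation, ligand exchange and peptide
inhibition.  This note records the models, the numerical choices, and what
the synthetic data do and do not establish.

## Solvent-accessible surface and interface burial

Accessible surface area (ASA) follows Shrake–Rupley: each atom's van der
Waals sphere is inflated by the probe radius (water, 1.4 Å), covered with a
deterministic Fibonacci-spiral lattice of `n_points` directions (default
960), and the accessible area is the fraction of lattice points lying
outside every neighbour's inflated sphere times the sphere area
4π(r+probe)².  The spiral lattice makes results bit-reproducible — there is
no random number generator anywhere in the surface path.  Atom radii are
Bondi-style (C 1.70, N 1.55, O 1.52, S 1.80 Å; Ca²⁺ 1.37 Å), overridable
through a two-column text table; unknown elements fall back to 1.70 Å with
a warning.  Hydrogens and waters are excluded (deposited structures are
inconsistent about them); metal ions are kept with their chain so
calcium-loaded sensors remain analyzable.

Interface burial of a two-body complex is computed PISA-style: ASA is
evaluated three times with identical parameters — complex, receptor alone,
ligand alone — and each residue reports

    BSA       = ASA_free − ASA_complex
    ratio     = BSA / ASA_free           (clipped to [0, 1])

where `ASA_free` is the residue's area with the *other* partner removed.
Because the identical point lattice is reused, deleting atoms can only
expose points, so `ASA_complex ≤ ASA_free` holds exactly rather than
statistically.  Residues with `ASA_free < 0.1 Å²` or `BSA < 10⁻⁶ Å²` report
ratio 0 to avoid 0/0.  Hot spots are residues of one side with ratio at or
above a threshold (0.5 by default, 0.6 offered; a threshold above 1 selects
nothing), optionally restricted by residue class.  The class partition is
explicit: hydrophobic = {A,V,L,I,M,F,W,P,G,C}, charged = {D,E,K,R,H},
polar = the rest.

Accuracy at the defaults: a single atom is exact by construction; the
two-sphere spherical-cap closed form is matched to <0.3% at 960 points; a
Monte-Carlo rejection-sampling oracle (10⁵ directions per atom, seeded)
agrees within 3% per atom on random clusters, as does an independent
library implementation of the same algorithm.

## Docking-pose filtering

Docked poses arrive as structures (or precomputed burial reports) with a
ΔG value from the docking program as metadata — the package never computes
docking energies.  A pose is accepted when (1) at least
`min_hydrophobic_contacts` (default 2) hydrophobic-class residues of the
peptide's 25–35 segment are buried at ratio ≥ 0.5, and (2) no
calcium-coordinating receptor residue is buried at that level.  The
forbidden set ships as the EF-hand loop positions 1, 3, 5, 7, 9 and 12 of
calmodulin's four loops (residues 20–31, 56–67, 93–104, 129–140 in the
calcium-saturated crystal-structure numbering); whole-loop exclusion is
deliberately not used, since accepted reference models bury loop-adjacent
hydrophobics such as Ile27/Leu32.  Passing poses are ranked by ascending
ΔG, ties broken by overlap with a reference hot-spot set, then by pose id.
Note that the published burial table for the second accepted
calmodulin model contains a single hydrophobic 25–35 contact, so it passes
only with the minimum relaxed to 1 — the historical filter settings are not
recoverable from the published record, and the defaults are calibrated to
the first (template) model.

## Mimetic peptide design

The design protocol linearizes a binding surface:

1. **Ordering.** Hot spots are ordered along a greedy nearest-neighbour
   path through their Cα positions, starting at the highest-ratio residue
   (ties to the lowest residue number).  On random clouds of ≤8 points the
   greedy path stays within 2× the brute-force shortest Hamiltonian path.
2. **Substitution.** Each hot spot maps into the reduced hydrophobic
   alphabet {V,F,M,L,A}: identity on those five, I→V, W/Y→F, C→M,
   G/P/S/T→A; charged and polar residues are expected to be excluded at
   hot-spot selection.
3. **Spacers.** Between consecutive hot spots with Cα gap d, the design
   inserts `min(cap, round(d/3.8) − 1)` alanine spacers, 3.8 Å being the
   virtual bond length of an extended chain — so spacer count depends only
   on d/3.8.  A residue-volume-based spacing rule would be an alternative
   realization; the geometric rule was chosen because it is reproducible
   and the published outcome constrains only the end product.
4. **Length and chemistry.** If the peptide would exceed `max_length`
   (default 10), hot spots are dropped from the low-ratio end and spacers
   recomputed.  C-terminal amidation is an annotation (FASTA header and
   reports); no chemistry is modelled.

**Calibration status of the reference design.** The packaged reference
configuration reproduces the published antagonist VFAFAMAFML from the
template-model hot-spot table.  The published record does not identify
which of the 18 tabulated calmodulin residues formed the interface pairs
that seeded the design, and no threshold-only selection can: the peptide's
non-spacer composition is {V×1, F×3, M×2, L×1}, but the residues tabulated
at ratio ≥ 0.9 contain only one methionine-mapping residue.  The shipped
calibration therefore pins an explicit seven-residue pairing
(Ile27, Phe19, Phe89, Met71, Phe68, Met51, Leu32) together with a synthetic
collinear Cα geometry (spacings 3.8/7.6/7.6/7.6/3.8/3.8 Å) chosen so the
protocol emits the published sequence.  It is one consistent realization of
the protocol, shipped openly as a calibration — not a prediction from
crystallographic coordinates.

## Fluorescence kinetics

Complex formation is monitored as a first-order fluorescence rise

    F(t) = Fmax − (Fmax − F0)·exp(−k·(t − lag)),  t ≥ lag

and ligand exchange as the mirrored decay toward Fmin, optionally preceded
by a lag phase (≈60 s in the calbindin exchange traces).  The reported
fitter is the linearized one the field prints: regress ln(Fmax − F) (or
ln(F − Fmin)) on t; k = −slope; half-time = ln2/k exactly.

Numerical design of the linearized fit:

* **Plateau.** Fmax/Fmin starts as the mean of the final 10% of samples
  (fraction configurable).  When a recording stops before completion this
  estimate is biased by the unresolved amplitude; the plateau is therefore
  refined by maximizing the linearity of the log plot within a bracket
  bounded by the predicted truncation deficit and the plateau's standard
  error, so noise cannot drag it away from the tail estimate.
* **Masking.** Points within max(3× the tail noise floor, 1% of the
  amplitude) of the plateau are excluded from the log transform; the first
  term avoids log-of-noise blow-up, the second bounds the leverage of any
  remaining plateau error.
* **Weighting.** The log transform makes noise heteroscedastic
  (Var[ln r] ≈ σ²/r²), so the slope uses iteratively reweighted least
  squares with weights exp(−2k̂t), i.e. the squared *model* residual.
  Weighting by the measured residual instead correlates the weights with
  the noise and biases k by over 10% at 2% noise; the model-weighted fit is
  unbiased and equivalent to a Gauss–Newton step.
* **Lag detection.** With `lag="auto"`, every sample time in the first
  third of the trace is a candidate; each is scored by the weighted r² of
  its fit, and the earliest lag within 5% of the best score's distance to a
  perfect fit is chosen (a bare argmax can wander late on noisy traces,
  where shrinking windows inflate r² by chance).

Under these choices the generator–fitter round trip recovers k to better
than 10⁻⁴ relative error on noiseless traces (including a 60 s lag decay
truncated at 3000 s) and to better than 5% in every one of 100 seeded
replicates at 1–2% amplitude noise (worst case measured 3.0%).

`time_to_half_rise` reports the first linear-interpolated crossing of
(F0 + Fmax)/2; for a lagged exponential this equals lag + ln2/k, and it is
the observable quoted for formation half-times when a lag is present.

Inhibition titrations follow the one-site hyperbolic model
Y = Y0 − Qmax·x/(IC50 + x), fit by bounded nonlinear least squares
initialized at Y0 = the zero-concentration response, Qmax = Y0 − min
response, IC50 = the concentration nearest the half-drop.  Noiseless
self-consistency recovers (Y0, Qmax, IC50) to ~10⁻¹³ relative.  Confidence
intervals, when requested, come from a seeded residual bootstrap (default
1000 resamples), since the published ± values state no method.

Affinity summaries combine a formation and an exchange fit:
k_on/k_off (equilibrium position), the formation/dissociation half-time
ratio (using the observed time-to-half-rise when a lag is present), and
the relative affinity fold (k_off/k_on)_A / (k_off/k_on)_B between two
complexes.

## Synthetic data: what it emulates and what it does not

The generator supplies every input at desk scale:

* **Traces** — first-order rise/decay with optional lag, 1 s sampling over
  2000 s (rise) / 3000 s (decay), i.i.d. Gaussian noise (default 1% of
  amplitude, matching low-noise cuvette recordings), seeded.  It emulates
  the kinetic *shape* of the assay, not photophysics of the dye,
  oligomerization equilibria, instrument drift, or correlated noise; a
  passing round trip shows the fitters are correct and noise-stable, not
  that real traces are single-exponential.
* **Titrations** — exact one-site hyperbolic responses plus seeded noise.
* **Toy complexes** — two ideal poly-alanine helices (backbone N, CA, C, O
  plus Cβ pseudo-atoms; rise 1.5 Å, twist 100°/residue) facing each other
  at a 9 Å inter-axial distance, the second chain mirrored across the
  midplane.  The planted buried set (default the i, i+3, i+7 face
  {3, 6, 10} of a 12-residue helix) determines the helix phase so those
  residues face the partner; at the default geometry the planted residues
  bury at ratio ≥ 0.44 and all others stay ≤ 0.1, so hot-spot calls at
  threshold 0.3 reproduce the ground truth exactly, and at 100 Å
  separation every ratio is 0.  These are stand-ins for the undeposited
  docked pose files, not models of real packing.
* **Burial tables** — the published per-residue BSA/ASA lists for the two
  calmodulin models and three calbindin models ship as parsed fixtures,
  with the ΔG metadata (−17/−15 and −17/−12/−11.6 kcal/mol).  Those values
  derive from undeposited docked coordinates and are inputs here, not
  reproducible outputs; the burial engine is validated on closed forms,
  the Monte-Carlo oracle and planted toy complexes instead.

## Degenerate inputs and tie-breaks

Coinciding atoms of equal radius raise a degenerate-geometry error (their
mutual occlusion is undefined).  Hot-spot ordering breaks ratio and
distance ties by ascending residue number; truncation drops equal-ratio
hot spots at the higher residue number first.  Pose ranking breaks ΔG ties
by reference-overlap then pose id.  Constant traces and wrong-direction
traces raise "no rise/decay detected"; fewer than five usable points after
masking is a data error; flat titrations report "no inhibition detected".

## Known limitations

* The surface engine handles two-body interfaces; no symmetry mates,
  hydrogen bonds/salt bridges, or dissociation energetics.
* The mimetic designer emits a single linear peptide per hot-spot set; it
  does not score synthesizability, predict structure, or assess
  blood–brain-barrier permeability.
* Kinetic fits are per-trace; no global multi-trace fitting, and binding
  stoichiometry (2:1 vs 2:2) is reported by the experimental narrative,
  not modelled.
* NMR-ensemble conformer choice is a parameter (model 1 by default); which
  conformer the original docking consumed is unknown.
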
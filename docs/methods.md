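# Methods

## Residue–substrate correlation scan

Sequences in a gapped alignment carry two categorical labels: a *group*
(the enzyme family, kept for reporting) and a *substrate profile* (the
specificity class the scan correlates against). For one alignment column
with residues r₁…rₙ and profiles s₁…sₙ, the score is

    score = Σ over unordered pairs (i, j):  +1 if (rᵢ = rⱼ) ⇔ (sᵢ = sⱼ), else −1

"Compared in pairs" is interpreted as **all** unordered sequence pairs,
within and between groups, with substrate equality meaning exact string
match of the two sequences' profile labels. This is the only reading under
which the "same residue when the substrate remained the same" clause can
fire at all (it needs same-profile pairs), and it makes the score a pure
function of the sequence-level labels; the scan is therefore also defined
for groups that are heterogeneous in profile (specialist subfamilies).
The bound |score| ≤ C(n, 2) holds per column, with equality for a perfect
determinant.

Gaps: '-' is a 21st residue symbol, so gap-vs-residue counts as "residue
differed"; '.' is normalised to '-' on read. Columns where the designated
reference sequence is gapped are still scored but reported without a
reference position (reference numbering is the cumulative non-gap count).
Ranking ties are broken by ascending column, making output deterministic.
No phylogenetic down-weighting of related pairs is attempted; the scan is a
screening statistic, not a test with a calibrated null.

## Saturation-library statistics

Degenerate codons are IUPAC triplets expanded by Cartesian product and
translated under the standard genetic code (translation table 1 — the
constructs are expressed in *E. coli*). For a multi-site library the
protein-outcome space is the product of the per-site outcome maps; the
per-outcome degeneracy (number of encoding codon combinations) is carried
throughout, and stop-containing outcomes are counted in the space but the
stop-free count is always reported alongside, since either convention may
be wanted.

Coverage of n unique variants by m uniform draws uses the Poisson
approximation P(all present) = e^−λ with λ = n(1 − 1/n)^m (the expected
number of unseen variants). An exact inclusion–exclusion evaluator
Σⱼ (−1)ʲ C(n, j)(1 − j/n)^m is provided for n ≤ 20 as a cross-check oracle;
at (n = 10, m = 50) the two agree to ~0.001. `required_sample_size`
inverts the approximation by analytic guess plus boundary scan, so the
returned m is exactly minimal under the e^−λ formula.

The probability that a library of L clones contains at least one of k
designated best variants is 1 − (1 − q)^L. The default "equal-outcome"
model takes q = k / (number of distinct outcomes); it requires no knowledge
of *which* outcomes are best and coincides with the codon-weighted model
whenever the designated outcomes have exactly average degeneracy. The
"codon-weighted" model takes q = (Σ degeneracies of the designated
outcomes)/(codon combinations) and defaults to designating the k
highest-degeneracy outcomes. For a three-site NNS library with L = 5 000
and k = 10 the equal-outcome model gives 99.5%, comfortably above the 95%
design criterion.

Plate counts are scaled to total transformants with (n ± z√n)·N, where N is
the reciprocal of the plated fraction; the lower bound is clipped at zero
because a count cannot be negative.

## Helical-lattice geometry

All filament descriptors derive from the signed twist Δφ (degrees per
subunit; negative = left-handed, following cryo-EM convention) and rise
(Å per subunit): subunits/turn = 360/|Δφ|, pitch = rise·360/|Δφ|, and the
axial translation relating the filament's two diad axes is pitch/2. The
expected monomer count in a boxed segment is (box·Å/px ÷ rise) × monomers
per subunit (2 for dimeric nitrilase subunits). Screw operations report
rotations reduced to (−180°, 180°] so that multi-step operations read as
their smallest equivalent angle (e.g. five −72.98° steps → −4.9°); note the
−4.9°/87.4 Å five-step screw and the 43.1 Å half-pitch are distinct
quantities and both are exposed — no composite "diad operation" is guessed.

`generate_filament` assumes the asymmetric unit is pre-oriented with the
helix axis on z (axis fitting belongs to reconstruction software and is out
of scope) and applies pure rigid motions, so intra-subunit distances are
preserved to floating-point precision.

Lid-loop displacement: when the inter-subunit twist changes by Δ at
constant filament radius r, a loop anchor moves 2r·sin(Δ/2) (chord, the
default: actual point-to-point movement) or r·Δ in radians (arc, movement
along the lattice circle). Both are strictly increasing in r and |Δ| —
the geometric reason a twist decrease at constant diameter forces a closed
lid loop into steric clashes with its symmetry mate. Clashes are counted
as inter-set atom pairs closer than a cutoff, default 3.0 Å
(conventional heavy-atom contact threshold; configurable).

## Activity reduction

Specific activity is the absorbance slope (per second) inside the linear
reaction window, divided by the calibration slope (absorbance per nmol
ammonia) and the enzyme mass (mg), giving nmol·s⁻¹·mg⁻¹ = nKat·mg⁻¹
(1 katal = 1 mol·s⁻¹). The linear window is the longest contiguous run of
at least 4 points whose internal least-squares fit reaches R² ≥ 0.99
(threshold configurable; the ≥4-point rule is the assay's stated practice,
the numeric threshold is this package's choice), earliest window winning
ties. A zero-variance (flat) window counts as perfectly linear so that
inactive enzymes reduce cleanly to 0 nKat·mg⁻¹ with a below-detection flag
rather than erroring. An inactivated-enzyme control series, when present,
has its fitted slope subtracted before conversion; negative estimates are
clipped to zero and flagged.

Replicate summaries use inclusive linear-interpolation quartiles (the
common spreadsheet default, matching how such assays are typically
summarised) and the n−1 sample standard deviation, undefined for n = 1.

## Synthetic-data generators

Every generator is a pure function of its scenario dataclass, seed
included (NumPy `default_rng`, no global state), and fixture validity is
checked at generation time.

- **Alignments**: planted determinant columns carry exactly one residue per
  substrate profile (perfect correlation); background columns are either
  fully conserved or label-independent uniform random over the 20 amino
  acids. Defaults (4 groups × 3 sequences, width 40, 3 planted columns)
  mirror a small grouped family scan with three true determinants. The
  generator does not emulate phylogenetic correlation between sequences, so
  planted-recovery tests demonstrate correctness of the scoring rule, not
  robustness to shared ancestry in real families.
- **Library draws**: each clone picks a codon combination uniformly, so
  outcomes appear with their codon degeneracies — the Monte-Carlo oracle
  for the closed-form coverage and top-k probabilities.
- **Helical asymmetric units**: random pseudo-atoms in a radial/axial band
  (defaults 8–15 Å radius, ±2 Å axially — a squat body well inside one
  17.48 Å rise). The optional "closed-lid" arm is constructed
  geometrically, not tuned: its anchor sits at a radius two clash-cutoffs
  outside the body band (so body atoms can never contribute spurious
  contacts) and its tip is placed exactly where the *neighbouring*
  subunit's anchor lands under the reduced twist (−60°). Distance to the
  neighbour's anchor is therefore 0 under the reduced-twist operators and
  2R·sin(6.5°) ≈ 4.8 Å under the native −73° twist, above the 3 Å cutoff.
  (Placing the tip at the midpoint of the two neighbour images would make
  it equidistant from both and could never separate the two twist states.)
  The generator re-checks both clash counts before returning and raises if
  the construction is violated.
- **Kinetics**: absorbance = blank + cal_slope·(activity·mass)·t + Gaussian
  noise, with an optional plateau freezing the mean after a chosen point
  (substrate exhaustion mimic). Defaults — 300 nKat·mg⁻¹ truth, 2 µg
  enzyme, 5-min intervals, 0.001 abs/nmol calibration, 0.01 absorbance
  noise — give absorbance gains of ~0.18 per interval, a realistic
  signal-to-noise for a colorimetric ammonia assay. Calibration standards
  are exact points on the line, so calibration error is excluded from
  parameter-recovery studies by design.

## Problem sizes and numerical choices

Monte-Carlo agreement is asserted at 3 binomial standard errors with 10⁵
trials for coupon-collector coverage at (n = 10, m = 50) and 2×10⁴ trials
for top-k hit rates; the 100-seed activity recovery study asserts the
median within 3 standard errors of the median (1.2533·sd/√n). Rigid-motion
preservation is asserted at 10⁻⁶ Å over 10 filament copies; screw
composition over a random grid of 50 integer step pairs. These sizes make
the statistical assertions stable at the 3-SE level while keeping the
whole suite in seconds.

## Known limitations

- The scan has no null model or significance threshold; it ranks.
- Coverage formulas assume uniform sampling with replacement and 100%
  cloning yield; real libraries have synthesis bias.
- Geometry treats subunits as rigid and the helix axis as exact; no
  account of filament curvature or disorder.
- The activity module fits initial rates only; no Michaelis–Menten
  analysis.
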
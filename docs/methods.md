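# Methods

This note records the models, conventions and numerical choices behind each
analysis in magekit, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Degron affinity matrix (`magekit.degron`)

A saturation substitution array measures an IC50-equivalent potency (nM) for
every single-residue variant of a 13-mer degron peptide: 13 positions x 19
substitutions plus the wild-type peptide, 248 measurements. The raw affinity
of cell (p, r) is the potency ratio

    a(p, r) = reference_potency / potency(p, r)

and the matrix weight is the per-position-normalized affinity
`w(p, r) = a(p, r) / max_r a(p, r)`, so every position's strongest binder has
weight exactly 1. A ratio rather than a free-energy difference is used
because the assay reports relative binding without thermodynamic units, and
ratios reproduce the "N-fold loss" language used for alanine scans. Replicate
potencies are combined by geometric mean (assay noise is multiplicative).

No-binding measurements receive a configurable floor, by default 10^-3 of the
per-position maximum raw affinity. The floor keeps log-scale window scores
bounded; any unmeasured cell is treated the same way.

Key positions are those whose alanine substitution loses at least
`fold_threshold` (default 10) in potency relative to wild type, inclusive at
the boundary. For the PCF11 degron FLVVVHQIRQLFQ this identifies positions
{1, 8, 9, 11, 12} (PCF11 F682, I689, R690, L692, F693).

The consensus pattern assigns each position the class of residues with weight
>= `tolerance` (default 0.25); classes with >= `wildcard_min` members
(default 8) collapse to the wildcard X. The defaults are documented
constants chosen so that a matrix with clean in-class/out-of-class separation
(in-class weights >= 0.8, out-of-class ~0.01, tolerated positions >= 0.6)
yields bracketed classes exactly at the selective positions; both are exposed
as parameters and CLI flags. Rendering uses alphabetical bracket sets and
run-length wildcards (`[FLWY]-X6-[IV]-[KR]-X-[ILMV]-[FLWY]`); a trailing
fully-tolerant run is omitted because an unanchored tail position carries no
information, and parsing pads short patterns back to 13 classes so the
render/parse round trip is an identity.

Window scores are additive log2 weights, `score(w) = sum_p log2 w(p, w_p)`;
a window composed of per-position maxima scores 0 and every deviation is a
negative penalty. Non-standard residues (U, X, B, Z) score at the no-binding
floor and never satisfy a consensus class.

## Proteome scanning (`magekit.scan`)

Every 13-mer window of every sequence is tested against the consensus;
windows are strictly intra-protein and offsets are 1-based, matching residue
numbering conventions. Overlapping hits are all reported, sorted by
(protein id, offset). Scoring and a score threshold are optional; the
consensus-only hit set is always a superset of any thresholded set. Surface
exposure of a matched motif is outside the scanner's scope; hits carry a
free-text annotation column where such evidence can be recorded.

## TR-FRET plate analytics (`magekit.trfret`)

The per-well signal is the emission ratio `10000 x 520nm / 490nm`. Wells
with a non-positive 490 nm count are flagged and dropped, never imputed.
Percent inhibition normalizes the signal between per-plate controls:

    %Inh = 100 - 100 x (signal - mean_pos) / (mean_neg - mean_pos)

with the negative control (DMSO, intact interaction) defining 0% and the
positive control (DMSO without the donor-tagged protein) defining 100%.
Control means are computed per plate; a run-wide override is possible by
constructing `PlateControls` from pooled signals. The Z'-factor is

    Z' = 1 - 3(sd_neg + sd_pos) / |mean_neg - mean_pos|

with the absolute separation in the denominator so the statistic is symmetric
under control-label swap; a plate passes QC when Z' > 0.5.

Dose-response fitting uses the four-parameter logistic
`y = bottom + (top - bottom) / (1 + (IC50/x)^hill)` fit by least squares in
log10-concentration space. Initialization: bottom/top from the response
quartiles, log IC50 from the concentration nearest half-maximal response,
hill = 1. The Hill slope is bounded to [0.2, 5] and log10 IC50 to the
sampled range +/- 3 decades. Replicate wells are averaged per concentration
before fitting. A series whose response span is below `min_span` (default 5,
in response units) is flagged flat and returned unconverged. Plateaus can be
constrained (or fixed, by passing a degenerate interval) — the standard
practice when a potency lies near or below the lowest sampled concentration
and a plateau is therefore not sampled.

Serial dilution designs are `c_i = top / factor^(i-1)`. The three designs
used in the screening workflow are 70 uM 1:3 x 10 levels (low point 3.6 nM),
70 uM 1:2 x 20 levels (0.13 nM) and 100 uM 1:2 x 16 levels (3.1 nM).

## Hit triage and compound properties (`magekit.triage`)

Primary-screen hits are compound wells with %inhibition strictly greater
than the threshold (default 30%), called on single wells; the hit rate is
reported as a percentage to two decimals. Scaffold grouping keys each
compound by its canonical Bemis-Murcko framework (ring systems plus
inter-ring linkers, exocyclic substituents removed); acyclic molecules form
a dedicated no-ring group and unparseable SMILES are collected, never
silently dropped. This is an approximation of proprietary substructure
clustering, adequate for grouping close analogs such as 4-substituted
quinolines.

Apparent permeability is `Papp = (dQ/dt) / (A * C0)` (cm/s) and the efflux
ratio `Papp(B->A) / Papp(A->B)` flags active transport when strictly greater
than 2. Kinetic solubility scales a reference concentration by the
sample/reference UV AUC ratio and a dilution correction (default 2, the 1:1
filtrate/1-propanol mix); the correction is a parameter because vendor
software constants vary.

## Melting-temperature estimation (`magekit.melt`)

Single-channel (dye) curves are fit with the Boltzmann sigmoid
`y(T) = pre + (post - pre) / (1 + exp((Tm - T)/slope))` with slope > 0; a
falling transition is encoded by post < pre, which covers nanoDSF ratios
that decrease through unfolding. Flat curves (span below 1% of the signal
magnitude) are flagged unconverged rather than fit. At least 10 temperature
points are required.

Dual-channel nanoDSF data are analyzed as the pointwise 350/330 ratio,
either by the same Boltzmann fit or by the extremum of a first derivative
after a fixed 5-point moving-average smoothing with parabolic peak
refinement; both methods are provided because instrument software internals
are unpublished, and they agree within 0.5 degC on symmetric transitions.
Linear pre/post baseline drift is supported by the generator but off by
default in the fit model.

Thermal-shift profiles report dTm = Tm(ligand) - Tm(apo) ordered by ligand
concentration, with a monotonicity flag (non-decreasing dTm is the
saturating-binding expectation).

## Structure interface analysis (`magekit.structure`)

Coordinates are read with gemmi (PDB or mmCIF, path or text), keeping the
first model and resolving alternate conformers to the highest-occupancy copy.
Chain superposition pairs C-alpha atoms by author residue number (unpaired
residues — e.g. a disordered linker present in only one protomer — are
excluded and counted) and solves the least-squares rigid alignment in closed
form via SVD with a determinant correction, guaranteeing a proper rotation.
Collinear selections are flagged degenerate. The implementation is
cross-checked in the tests against an independent closed-form alignment and
against brute-force rotation sampling.

Interface contacts are all atom pairs between two disjoint selections within
an inclusive distance cutoff, default 5.0 A, over all atoms including side
chains; the unique contact residues of the first selection summarize the
binding cleft. Waters and hetero atoms are excluded by default with flags to
include them (e.g. for water-mediated salt bridges).

## APA event filtering (`magekit.apa`)

Events carry per-replicate PDUI (distal polyA-site usage, in [0, 1]) for two
conditions, 3'-UTR read coverage and an upstream p-value. The filter keeps
events satisfying all of: coverage strictly > 20; Benjamini-Hochberg
adjusted p <= 0.05, with the adjustment computed across the post-coverage
set (BH is the standard adjustment for such event tables; the method is a
flag); |mean dPDUI| >= 0.2; and mean-PDUI fold change >= 1.5, computed
orientation-symmetrically as max(mean1, mean2)/min(mean1, mean2) since the
ratio's direction is not fixed by convention. dPDUI is mean(group2) -
mean(group1), positive = lengthening. The direction of the global shift
among survivors is tested with an exact binomial test against 0.5,
one-sided toward the stated direction by default.

## Synthetic data (`magekit.synthetic`)

Generators are pure functions of (parameters, seed); plate generation splits
the seed hierarchically per plate so partial regeneration is stable. Noise
conventions: multiplicative log-normal (unit median, stated CV) for
potencies and dose responses; additive Gaussian for raw channel counts and
melt fluorescence.

Default study conditions:

- **Peptide array**: wild type FLVVVHQIRQLFQ at 59 nM reference potency; the
  ground-truth energy model gives out-of-class substitutions at the five
  selective positions a 100-fold loss (inside the 10-200x range typical of
  alanine scans of this degron class), in-class non-wild-type residues 0.8
  relative affinity and tolerated positions 0.6. 248 rows.
- **Primary screen**: 384-well plates, rows A-P; columns 1, 2, 13, 14 are
  reserved for controls (1/13 negative, 2/14 positive, 32 wells each) and
  compounds fill the remaining 20 columns, 320 per plate at 15 uM. Control
  signals 20000 (negative) and 2000 (positive) on the 10000 x 520/490 scale
  with a 10000-count 490 channel. Actives receive uniform %inhibition in
  (35, 95) by default; inactives sit at 0.
- **Dose response**: the 10-level 1:3 design from 70 uM, 3 replicates and 3%
  CV unless stated otherwise.
- **Melt curves**: 25-95 degC grid at 0.5 degC steps, transition slope
  1.5 degC, amplitudes ~2000 counts; dual-channel mode constructs channels
  whose 350/330 ratio is exactly a Boltzmann sigmoid with midpoint at the
  true Tm, because the ratio — not the individual channels — is the
  analyzed observable.
- **APA tables**: 3 replicates per group (a three-tumors-per-group design),
  replicate SD 0.05, baseline PDUI sampled leaving headroom for the shift so
  clamping to [0, 1] is exceptional (clamps warn); p-values from a
  two-sample t-test on replicate PDUIs, which makes null p-values uniform
  and the FDR simulation meaningful.

What the generators do *not* emulate: plate edge effects, liquid-handling
drift and cross-talk; compound autofluorescence and aggregation artifacts;
asymmetric or multiphasic dose responses and melt transitions; sequence
composition biases of real proteomes (background is i.i.d. by default);
correlated replicates and coverage-dependent PDUI precision. Passing
closed-loop tests therefore demonstrates correctness of the estimators under
the stated noise models, not robustness to these real-data pathologies.

## Problem sizes and runtime choices

Test simulations use the sizes stated above: the full-scale screen check
runs 31,407 compounds across 99 plates once; recovery distributions use 100
seeds (IC50, 10-point series) and 50 seeds (Tm); the FDR null simulation
uses 1000 genes x 40-100 seeds. These sizes make the recovery medians
stable while keeping the whole suite fast on a single CPU.

## Known limitations

- The affinity-matrix construction is a documented reconstruction of a
  "weighted matrix" whose exact published construction is unavailable;
  absolute scores are therefore not comparable across matrices built with
  different floors or references.
- The proteome scanner makes no claim about accessibility or disorder of a
  matched motif; real candidate lists depend on the proteome release and on
  structure-based post-filters.
- The 4PL fitter reports a point estimate without confidence intervals; for
  potencies far below the sampled concentration range even the constrained
  fit's uncertainty grows quickly.
- Superposition pairs residues purely by author numbering; structures with
  renumbered or inserted residues need pre-harmonized numbering.
- The APA filter consumes upstream p-values as given; it does not model the
  coverage regression that produced them.
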
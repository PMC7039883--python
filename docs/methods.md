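# Methods

`gsk3screen` implements the two computational arms of a
lithium-mimetic discovery workflow in human iPSC-derived neurons: (1)
post-search processing of a SILAC phosphoproteomics experiment that maps
GSK3 substrates via CHIR-99021 dose response, and (2) the high-content
imaging assay that reads out CRMP2 phosphorylation at T514 relative to
MAP2 in single neurons and drives a plate-based compound screen. Both
arms run against seeded synthetic data generators, so every stage is
testable without the original raw data. This note records the models,
the defaults and why, and what the synthetic benchmarks do and do not
demonstrate.

## Phosphoproteomics arm

### Data model

One record per quantified phosphopeptide: sequence, mapped protein
accessions, phosphosites with per-site localization flags, a decoy flag,
the set of SILAC experiments in which the peptide was identified, and
treated/control abundance ratios per channel, where a channel is one of
two CHIR-99021 conditions (1 and 10 uM) crossed with two label-swap
replicates. Identification evidence (`experiment_ids`) is deliberately
separate from quantification (a present ratio): a peptide can be
identified in an experiment whose ratio did not survive quantification.

### Filter cascade

Four conjunctive rules: identified in both SILAC experiments; not a
decoy; at least one fully localized phosphosite; quantified in both
replicates for at least one condition. Conjunction makes the retained
set order-invariant, which the tests check by permutation and against a
brute-force oracle.

### Normalization and regulation testing

Ratios are log2-transformed and median-centred per channel, so each
channel's median log2 ratio is exactly zero over the peptides quantified
in it (asserted to 1e-9). Missing cells stay missing; channels with no
quantified peptides are skipped with a warning.

Per-peptide regulation in a condition is a two-sided one-sample location
test of the replicate log2 ratios against zero, with Benjamini–Hochberg
correction across scored peptides and a configurable level (default
0.05). Two test variants are provided:

* **`method="t"`** (default): the plain one-sample t-test. With two
  replicates this has one degree of freedom, whose two-sided tail is the
  Cauchy tail `p = 1 - (2/pi) arctan|t|`. It is deliberately
  conservative — even `t = 7` gives `p ≈ 0.09` — and is the right
  reference point for a nominal-p volcano plot.
* **`method="moderated"`**: an empirical-Bayes moderated t-test in the
  style used throughout genomics for few-replicate designs. Per-peptide
  sample variances are shrunk toward a scaled-F prior fitted across the
  whole table (moment matching on log variances, prior degrees of
  freedom solved by inverting the trigamma function), and the test uses
  the posterior variance with augmented degrees of freedom. This is the
  variant that has useful power at n = 2 and is used wherever planted
  effects must actually be recovered.

Degenerate cases are pinned by convention: replicates exactly (0, 0)
give p = 1 (zero effect), zero spread around a non-zero mean gives
p = 0, and peptides with fewer than two replicate values in the tested
condition are flagged unscored rather than dropped. Direction is the
sign of the mean log2 ratio and only assigned to significant peptides.

### Per-protein summaries, motif, network

Regulated-peptide counts are per merged protein group; the GSK3
alpha/beta paralogs are merged by default because their phosphopeptides
are indistinguishable. Ties in the ranking break lexicographically so
output is reproducible.

The phospho-motif is a position frequency matrix over 13-residue windows
(±6) centred on each fully localized, down-regulated S/T site in its
parent protein sequence, gap-padded at protein termini with gaps
excluded from the per-column frequencies. The expected signature is the
GSK3 consensus S/T-X-X-X-pS/T: S/T at the site and at +4. Window length
is configurable (odd, >= 9); no background-proteome enrichment test is
attempted — the matrix is descriptive.

The interaction network is built from an input edge list (two-column TSV
or SIF), restricted to the protein set of interest; connected components
are computed over proteins with degree >= 1 and the connected fraction
reported. The edge evidence itself is always an input, never fetched.

### Synthetic phosphoproteome

The generator plants a configurable fraction (default 0.2) of true
substrates among `n_peptides` (default 1000) spread over synthetic
proteins (~5 peptides each, length 80). True substrates receive the
consensus context (S/T at the site, S/T at +4 in 90% of substrates) and
mean log2 shifts of -0.8 at 1 uM and -1.5 at 10 uM; all channels add
N(0, 0.3) log2 noise. Decoys (5%), unlocalized records (10%),
single-experiment records (5%) and per-channel missingness (5%) exercise
the cascade. Everything is a pure function of the spec and seed.

Because peptides sharing a protein may overlap in position, a planted
context is occasionally overwritten by a later peptide; affected windows
are skipped (logged) during motif extraction. This loses a few percent
of windows and does not move the modal residues.

What passing shows: the cascade, normalization, testing and motif
machinery are correct against planted truth under Gaussian log-ratio
noise with a clean null. What it does not show: robustness to correlated
peptide noise, intensity-dependent variance, or search-engine artifacts
present in real exports.

## Imaging arm

### Segmentation

Nuclei are segmented from the nuclear channel by Gaussian smoothing
(sigma 1 px), global Otsu threshold, hole filling, speck removal, and a
seeded watershed on the distance transform (peak separation 8 px) to
split touching nuclei. Blank or saturated fields — where the foreground
would exceed 30% of the image — return zero objects with a warning
rather than failing. Areas are reported in um2 using the configured
pixel size (default 0.65 um/px, plausible for a 20x objective and
configurable; every size threshold is applied in physical units).

### Four-criterion collar-ring classification

A collar ring (2 um outward dilation of the nucleus, excluding all
nuclear pixels) samples perinuclear MAP2, and the criteria apply in
numbered order, the first failure labelling the rejection:

1. nuclear area within [50, 160] um2, boundaries inclusive (below:
   debris; above: clump). The size is interpreted as area; an
   equivalent-diameter option exists because the unit is ambiguous in
   the source software convention.
2. mean nuclear intensity >= 2197 camera counts (the threshold is
   plainly an intensity, not a pixel count; it is configurable).
3. ring MAP2 mean above a floor, default estimated per image as
   background median + 3 robust sd (MAD-scaled); an absolute override
   exists. On a noise-free background the floor is one count above
   background so flat background never counts as MAP2-positive.
4. ring MAP2 coefficient of variation > 1 marks a neuron. High CV is a
   texture signature: neurites crossing the ring make neuronal MAP2
   patchy, while flat signal (or flat background) has low CV. The rule
   is implemented exactly as printed; an inverted mode is available
   behind a flag.

### Neurite tracing and the well readout

The MAP2-positive mask (Otsu by default, fixed threshold optional) minus
soma regions (nuclei dilated 2 um) is skeletonized; only skeleton
components touching a soma are kept, so free-floating MAP2 debris never
contributes. p-CRMP2 and MAP2 are measured on the retained skeleton
pixels, raw and background-subtracted (per-channel image median).

The well readout is percent p-CRMP2/MAP2: 100 x (well-average neurite
p-CRMP2) / (well-average neurite MAP2). In high-content mode the
averages are over fields, restricted to fields with at least one
classified neuron and a non-empty skeleton (field-level averaging is the
default; the alternative pixel-level pooling is a one-line change in
`measure_well`). Whole-field mode ratios total above-background
intensities with no per-cell gating, emulating a laser-scanning
cytometer. Zero neurons across a well gives a typed missing percent,
never a crash; the MAP2-positive neuron count summed over fields is the
toxicity readout.

### Synthetic plates

Each field (default 256 x 256 px at 0.65 um/px) contains neurons
(nucleus + 4 random-walk neurites of 30-60 steps, 3 px wide),
non-neuronal cells (bright nucleus, no MAP2), debris (< 50 um2) and
clumps (> 160 um2), placed without overlap (bounded retries, then a
typed placement error). Intensities: constant background 200, Gaussian
camera noise sd 20, nuclear mean 3000 +-10%, MAP2 amplitude 1800 above
background on neurites. The p-CRMP2 channel carries `f x` the MAP2
amplitude on the same pixels, where `f` is the well's suppression
factor, so at zero noise the background-subtracted p-CRMP2/MAP2 ratio on
true neurite pixels is exactly `f`. Neurite walks stop before entering
another cell's collar-ring zone so ring statistics stay attributable.

Dose-dependent suppression follows a Hill curve; the default is solved
analytically through the two lithium anchors (87.2% at 1 mM, 68.4% at
2.5 mM with top 1, bottom 0), giving EC50 = 4.63 mM and Hill slope 1.25.
Toxic wells thin the neuron count binomially by a per-well multiplier.
Per-field random streams are spawned from a root seed, making whole
plates byte-reproducible.

Problem sizes (4 fields/well, ~13 objects/field) are the package's
default desk-scale study conditions: they keep a full 96-well screen,
analyzed end to end, at roughly twenty seconds while leaving every
algorithmic step — watershed splitting, ring statistics, skeleton
anchoring — non-trivially exercised. What passing shows: the analysis
recovers planted class labels, counts and suppression factors through
the full image path. What it does not show: performance under uneven
illumination, focus drift, channel bleed-through, densely overlapping
cultures, or morphologically realistic dendritic arbors — the generator
deliberately omits optics.

## Screen analytics

Raw well percents are normalized so a reference averages 100: DMSO
wells, all wells on the plate (the primary-screen convention; per-plate
by default), or lithium-reference wells (for ranking candidates against
a therapeutic lithium dose). Normalization is idempotent and typed
errors name the mode when the reference is missing or zero.

Plate QC is the Z' factor, `1 - 3(sd_pos + sd_neg)/|mean_pos -
mean_neg|`, computed with sample (n-1) standard deviations — stated
explicitly because the sd flavour is conventionally ambiguous. Equal arm
means yield a typed undefined result rather than -inf.

Hit calling bands each compound by mean normalized percent: strong
below 80, candidate in [80, 90), inactive otherwise. The source
brackets (< 80 for GSK3-inhibitor-like, 75-90 for candidates) overlap on
[75, 80); the partition at 80 makes the calls deterministic and both
edges are configurable. A compound whose MAP2-positive neuron-count
ratio against the reference falls below the toxicity floor (default
0.5 — the source names no cutoff) is called toxic regardless of
activity. A compound with no surviving neurons anywhere has an undefined
percent and is called toxic directly.

Treatment significance is the unpaired two-sided t-test (pooled
variance by default, Welch behind a flag) with the star scheme applied
at its printed, inclusive lower edges: * 0.01 <= p < 0.05,
** 0.001 <= p < 0.01, *** 0.0001 <= p < 0.001, **** p < 0.0001.

## Known limitations

* With two replicates the default t-test is near-powerless by design;
  real discovery lists should use the moderated variant, and published
  corrected-significance counts obtained with an unnamed method cannot
  be matched exactly by any particular choice made here.
* The collar-ring CV rule is taken at face value; cultures whose
  non-neuronal cells carry textured MAP2-adjacent signal would need the
  inverted or re-thresholded variants.
* The processed phosphopeptide export of the original study is not
  redistributable here; the acceptance check that replays its published
  counts (2829 retained, 575 nominal, 398 proteins, 37 at >= 3 peptides,
  MAP1B 14, MAP2 8) therefore fails until that file is supplied at
  `data/supplemental_phosphopeptides.tsv`.
* Whole-field mode depends on the neurite-tracing pass for its totals
  and reports zero when no MAP2 mask survives, which slightly
  understates signal in fields with somatic-only staining.
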
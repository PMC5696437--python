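# Methods

`codiverge` asks a single question of comparative genomic data: when two
closely related host species carry nearly identical maternally inherited
endosymbionts, did the symbiont ride through the host speciation
(cladogenic transmission), cross with hybridizing cytoplasm
(introgression), or jump hosts outright (horizontal transfer)?  The
package implements the full inference chain — divergence estimation,
relative-age chronograms, synonymous/nonsynonymous rates, calibration
against documented cladogenic systems, calendar-time conversion — plus a
read-depth CNV scanner for the structural side of the comparison, and a
simulator that generates every input under known truth.

## Divergence and intervals

Pairwise divergence is differences/usable sites, counted per codon
position.  Sites carrying a gap, `N` or any non-ACGT state in either
sequence of a comparison are excluded from that comparison's denominator
(each pair has its own usable-site count); within a concatenated
alignment the reading frame restarts at 1 at every gene boundary, so
codon position is always relative to the gene, never to the global
coordinate.  95% intervals use the Jeffreys (Beta(½,½)) binomial method,
which is well calibrated down to the handful-of-counts regime this data
lives in (tens of differences over ~7×10⁵ sites); exact coverage at that
scale is ~93–96% (computable by summing the binomial pmf, and checked in
the test suite).  Percentage renderings use one significant figure below
0.01% and two otherwise, matching how such divergences are conventionally
reported.

For an ingroup pair (a, b) against an outgroup c, biallelic sites are
split into shared (a = b ≠ c) and private (a ≠ b, with the other ingroup
taxon matching the outgroup) classes.  Sites where all three states
differ are counted and reported but not classified — at divergences of
10⁻⁴ they are vanishingly rare and there is no principled way to
polarize them without more taxa.

## The partitioned strict-clock chronogram

The clock model: a rooted topology (an input, never searched), node ages
relative to a reference node fixed at age 1, and one rate multiplier r_p
per codon position, so the expected substitutions on a branch at position
p are r_p × branch duration.  Fixing the reference age resolves the exact
rate × time non-identifiability (doubling all ages while halving all
rates leaves the likelihood untouched; this invariance is property-
tested).  The substitution model is HKY with empirical base frequencies
pooled over the alignment and a single transition/transversion ratio κ
shared by the partitions.  At the divergences this package targets
(10⁻⁵–10⁻¹ substitutions/site) relative node ages are insensitive to
substitution-model richness — the multiple-hit correction itself is a
sub-percent effect — so richer parameterizations (extra exchangeabilities,
among-site rate variation) would add parameters without moving the
quantity of interest.  Transition probabilities use the closed-form HKY
solution (verified against the matrix exponential in the tests), and the
likelihood is computed by Felsenstein pruning over unique site patterns
per partition.

Fitting is maximum likelihood with a smooth reparametrization that makes
every candidate tree valid by construction: each internal node's age is
its oldest child's age plus exp(x), with the reference node pinned at 1.
Intervals are parametric-bootstrap percentile intervals: resimulate site
patterns under the fitted model, refit, take the 2.5/97.5 percentiles
(default 100 resimulations).  ML plus parametric bootstrap gives interval
semantics equivalent to posterior intervals at these scales while staying
deterministic given a seed; we do not claim numerical identity with any
particular Bayesian implementation.

One numerical guard matters at the bottom of the divergence range: with
~2 expected differences inside the reference clade (a 48-kb alignment at
4×10⁻⁵), a replicate can show zero reference-pair differences, and the
unpenalized MLE of every other relative age then diverges.  The
likelihood therefore carries a weak Jeffreys-style regularizer — half a
pseudo-substitution on the reference-pair path in total,
(1/6)·Σ_p log P(site differs on the reference path at position p) — which
keeps the estimator finite there and is numerically irrelevant once the
reference pair shows more than a handful of differences.  With this
regularizer, percentile bootstrap intervals achieve their nominal
coverage at the 48-kb scale (≥90% required, ~95% observed in the
acceptance suite's 50-replicate studies).

## NG86 synonymous/nonsynonymous analysis

Site counting follows Nei–Gojobori (1986): at each codon position the
synonymous fraction is the fraction of non-stop single-nucleotide
neighbors preserving the amino acid, so every sense codon contributes
exactly 3 sites.  Differences between codons are averaged over all
minimal mutational pathways with equal weights; pathways through stop
codons are excluded, and a codon pair whose pathways are all blocked is
skipped and logged (none exists for pairs at Hamming distance ≤ 2; a few
distance-3 pairs qualify).  k_s = Sd/S and k_a = Nd/N with the
Jukes–Cantor correction applied below the p = 3/4 domain boundary; at
k_s ≤ 0.12 the correction is a ≤9% effect and the estimator's behavior is
dominated by counting, which is verified against brute-force enumeration
over all 61×61 sense-codon pairs.  Site totals average the two sequences'
counts; codons with gaps or ambiguity in either taxon are skipped.

## Transmission-mode classification

All classification logic works on ratios, so it is invariant to rescaling
every divergence by a constant (property-tested).  The observed statistic
is the symbiont/host synonymous-divergence ratio.  The bundled
calibration table records published host pairs with documented cladogenic
symbiont transmission (two wasp species, four bee species in six pairs)
plus the focal measurement; the cladogenic ratios span 0.015–0.30.

Rules, with concordance factor T₁ = 2 and rejection margin T₂ = 10:

* **Cladogenic plausible** — the observed ratio falls within factor T₁ of
  the *span* of cladogenic calibration ratios (and, when a mitochondrial
  divergence is supplied, mito is concordant with nuclear within T₁).
  The span rather than a single summary is deliberate: documented
  cladogenic systems themselves vary ~20-fold, so judging against the
  median alone would reject genuine cladogenic transmission at the fast
  end of that range.  T₁ = 2 reflects that host-nuclear vs cytoplasmic
  divergence-time discordance under cladogenesis is not expected to reach
  a factor of two for typical insect sister species.
* **With mitochondrial data** — concordant mito and (rescaled) symbiont
  divergences both younger than nuclear ⇒ introgression; symbiont
  younger than mito ⇒ horizontal.  The symbiont divergence is rescaled
  onto the host-nuclear scale by the median calibration ratio before
  these comparisons; mito divergence must already be supplied on a
  nuclear-comparable scale.
* **Without mitochondrial data** — introgression and horizontal transfer
  cannot be separated; a ratio below min(calibrations)/T₂ is called
  noncladogenic transfer, anything between that margin and the
  calibration span is indeterminate.

The focal measurement (ratio 2.5×10⁻⁴, ≥60-fold below every calibration)
rejects cladogenesis under any T₂ ≤ 60.

## Calendar time

Two rate conventions coexist in the literature and differ by a factor of
2g: per-lineage rates (t = d / (2 r g), g generations per year, g = 1 for
per-year rates) and pairwise-divergence rates (t = d / r).  Both
published anchor calculations reproduce only under their own convention,
so the convention is an explicit input and is never inferred.  The
default g = 10 for multivoltine flies is prominent and adjustable —
temperate species may have half as many generations, which doubles the
inferred times without affecting any mode classification.  Time intervals
evaluate the rate interval endpoints through the same formula (slow rate
→ older age).

## Read-depth CNV calling

Profiles are per-genome normalized (window mean / genome-wide mean), so
they are invariant to sequencing depth.  Visualization profiles tile the
genome in 1-kb windows; calling uses 500-bp tiles against a control
profile from reads of the reference strain itself.  Per window,
copy estimate = round(sample/control normalized-depth ratio × ploidy),
where ploidy is the reference copy count of the window (2 inside regions
the reference genome carries in duplicate — extra sample copies of such
regions pile reads onto both reference copies, so a 2→3 gain appears as
ratio 1.5).  Runs of ≥ 4 consecutive 500-bp windows (2 kb) with the same
non-reference estimate merge into one call; the smallest biologically
interesting variant in this setting is 2.5 kb, and the 2-kb floor
suppresses single-window noise (at 30× coverage the per-window ratio
standard deviation is ~1%, so false calls are effectively absent — the
null false-call rate is property-tested).  Windows whose control
normalized depth falls below 0.05 are masked as unmappable.  Each call
spanning ≥ 2 windows gets a two-sample Kolmogorov–Smirnov p-value of its
ratio windows against all windows outside the call; single-window calls
report an undefined p-value rather than a fabricated one.  Segmentation
is run-merging, not an HMM, so call boundaries are window-grid-accurate
(±1 window) rather than breakpoint-exact.

## The synthetic-data generator

The generator defines the study conditions; its defaults are the
magnitudes of the system it emulates, not tuning knobs.

**Coding-sequence tracks.**  An ancestral sequence of uniform-random
sense codons evolves along the clock tree.  Substitutions are proposed
per position at an intensity chosen so the *realized* per-position rates
match the requested r_p: proposals creating stops are rejected,
nonsynonymous proposals are thinned (or synonymous ones, for ω > 1) by an
acceptance probability solved numerically so the predicted NG86 k_a/k_s
equals the requested ω, and the proposal intensity is divided by the
resulting expected acceptance.  The proposal kernel has no
transition/transversion bias by default, which makes the NG86 estimator's
equal-weighting assumptions exact and lets the estimator-recovery tests
target ω directly; κ is a parameter when transition bias is wanted.
Multiple hits arise naturally (events apply sequentially), so realized
difference counts saturate exactly as real data does.

Fixtures: `preset_wri_like` — a symbiont trio over 703 genes / 704,883 bp
(scalable), per-position divergences (5.0, 3.2, 4.0)×10⁻⁵, outgroup at
relative age 3.51, ω = 1 (closely related endosymbionts show k_a ≈ k_s);
`preset_host_like` — five host genomes over 18 × 1.5-kb loci,
per-position divergences (1.10×10⁻², 4.73×10⁻³, 9.20×10⁻²), relative
ages 1.96 (outgroup) and 0.72 (second species pair, root at 3.0), ω = 0.05.
The root age of the host tree and all mitochondrial preset ages are
scenario-defined choices, not measured quantities.

**Scenarios.**  All tracks share the host topology.  Mitochondrial rates
equal nuclear rates, so mito divergences are directly on the nuclear
scale (real mitochondria are faster; classification only needs a known
relative scale, and unit scale keeps the truth transparent).  Symbiont
*synonymous* rates are the calibration ratio × host's — matched on the
synonymous scale because that is what k_s compares — implemented by
rescaling the rate targets with each track's acceptance fraction.
Scenario ages: cladogenic, transfer and mito ages both 1 (the host
speciation); introgression, transfer = mito age = 0.1; horizontal,
transfer 0.01 with mito at 1.  The horizontal transfer age is an order of
magnitude below the slowest calibration ratio because a transfer age
within factor ~2 of a calibration is *genuinely* ambiguous from ratios
alone — exactly the ambiguity the no-mito branch of the classifier
refuses to resolve.

**Depth profiles.**  Per-base Poisson depth; a planted variant
(start, end, from, to) multiplies the sample's expected depth by
to/from, the control is uniform, and the default plant set mirrors the
structure of real symbiont resequencing results: a 23-kb loss, two
22.5-kb gains inside the reference-duplicated prophage regions (ploidy
2), and one marginal 2.5-kb gain, over a 1.45-Mb genome at 30×.

**What the simulator does not emulate**, and hence what passing tests do
not show about real data: alignment error and annotation error upstream of
the ortholog set; recombination (none detectable in the real comparison,
but absent by construction here); codon-usage and GC bias (ancestral
codons are uniform); among-site and among-lineage rate variation;
GC-dependent or mappability-dependent depth artifacts.  The pipeline's
behavior under those realities must come from the calibrations and
controls built into the analysis itself, not from these tests.

## Problem sizes and determinism

Every stochastic routine takes a seed or NumPy Generator; identical seeds
give byte-identical outputs.  The test suite's simulation studies use the
sizes the estimators are actually sensitive to: chronogram interval
coverage at 48 kb (the regime where the reference pair can show zero
differences) with 50 replicates × 100 bootstrap refits, CNV recovery
power over 50 simulated 1.45-Mb genomes, interval calibration over 200
binomial draws.  The acceptance script runs the full-scale 704,883-bp
symbiont fixture, where a single replicate reproduces all the headline
counts.
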
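# Methods

This note documents what `dichrom` computes, the conventions it fixes
where the field leaves them open, what the synthetic fixtures emulate,
and what the tests consequently do and do not show about real data.

## Data model and inputs

All coordinates are 0-based half-open on the reference; 1-based forms
appear only in display strings. A fiber is one sequenced molecule with
deduplicated m6A reference positions, sorted non-overlapping protected
footprints ("nucleosomes", which may be bound-protein footprints),
sorted non-overlapping MTase-sensitive patches (MSPs), and per-site
boolean CpG calls. Features are always in reference coordinates
regardless of read strand.

Modified-base BAMs are consumed through pysam's MM/ML parsing. An ML
byte q is read as probability q/255, and a call becomes an event when
q/255 ≥ threshold (default 0.8 for both m6A and mCpG; the thresholds are
configuration, chosen near common practice for this class of caller, not
inferred from any upstream tool). Calls lifted through the alignment skip
insertions; deletions emit nothing. Calls between thresholds are simply
"not called". Per-read footprint interval tags (`ns`/`nl`, `as`/`al`)
are lifted when present; otherwise footprint lists stay empty and the
documented naive segmenter (maximal m6A-free runs ≥ a cutoff become
footprints, complementary runs become MSPs) is available as a fallback.
It is deliberately simple and is not a substitute for a production
segmenter's error model.

Aggregate per-bp tracks follow the counting convention: occurrences
across molecules at a bp divided by molecule coverage at that bp; zero
coverage is NaN, never 0.

## Centromere-core calling

Parameters (all exposed on `CdrParams`): merge gap < 25 bp (strict),
minimum merged array 100 kb, window 1190 bp, step 170 bp, selection
percentile 35, candidate percentile 20, minimum core length 15 kb,
terminal exclusion 70 kb (15 kb variant for arrays whose core abuts a
terminus). Percentiles are computed per merged array with linear
interpolation between order statistics, and "below" is strict; a 1e-9
epsilon keeps exactly-tied window means (a perfectly uniform array) from
being split by float rounding. The candidate mean is the unweighted mean
of member-window means. A candidate intersecting a terminal zone is
dropped entirely, not trimmed. Computing percentiles per array rather
than genome-wide reflects that each array has its own methylation
baseline; this is a declared convention.

**Candidate boundaries.** Each base of an array is covered by up to
window/step = 7 windows at different phases. A base belongs to a
candidate only when it is covered by at least one site-bearing window
and *every* site-bearing window covering it passed the 35th-percentile
cut; maximal runs of such bases are the candidates. Compared with taking
the plain union of passing windows — which drags each boundary outward
by up to a full window width, since a window overlapping a dip by only a
few CpGs already passes — this consensus rule quantizes boundaries to
the step grid. On the planted-dip fixture it localizes core edges to
within one step (±170 bp). Windows with no CpG sites neither select nor
veto.

**Inputs.** The caller consumes a per-site methylation fraction table.
Its intended input is a *bulk* (deep-coverage aggregate) methylation
track, which is how such cores are delineated in practice; the fixture
supplies the generator's expected per-site fractions as that bulk track.
With shallow per-molecule aggregates instead, the rank-based 35th
percentile necessarily selects ~30 % of background windows; recovery of
a strong dip survives, but boundary precision degrades with coverage
noise. An externally supplied core BED (CENP-A CUT&RUN enrichment)
bypasses calling for genomes where hypomethylation cannot be assumed.

## Dichromatin metrics

Di-nucleosome footprints are strictly > 210 bp; large accessible patches
strictly > 150 bp (both exposed). Percentages are per fiber and NaN when
the denominator is zero. Regional summaries assign a fiber to the region
holding ≥ 50 % of its span (ties to the leftmost; otherwise
"unassigned") and count only features fully inside the region.

Patch spacing: observed values are start-to-start distances between
consecutive large patches on the same molecule, both fully contained in
the region (full containment keeps observed and expected consistent);
the expected distance is total sequenced bases in the region divided by
the number of contained large patches, which is algebraically the
published patches-per-bp construction. The patch-count estimate is
(contained patches / sequenced bases) × region length — the expected
number of patches on one full-length traversal of the core. The
interval-span statistic reports the fraction of target-spanning fibers
with a single footprint covering ≥ 90 % of the target; "well-positioned"
has no standard operational definition, so the 0.9 span coverage is a
declared, exposed convention.

## Chromatin repeat spectra

Per fiber: binarize m6A per bp, compute a one-sided periodogram with a
rectangular window at unit sample spacing, no detrending by default (a
mean-removal flag exists; it only affects the zero-frequency bin, which
lies outside the analysis band). Fibers shorter than twice the maximum
period or with fewer than 10 events are skipped with a logged reason.
Because raw DFT frequencies depend on fiber length, per-fiber densities
are linearly interpolated onto an integer repeat-length grid over the
120–300 bp band (covering satellite units of 155–340 bp and nucleosome
repeats of 170–193 bp) before the per-gridpoint median is taken. Peaks
are local maxima ordered by density, ties broken toward the shorter
repeat length. The periodogram is verified against an explicit O(n²)
DFT to 1e-9 relative tolerance.

## CENP-B footprint scoring

Exact IUPAC matching of the 17-mer consensus replaces a q-value-based
motif scanner: with 10 fixed positions the consensus is discriminative
enough that exact matching is the deterministic equivalent at fixture
scale; a `max_mismatches` option covers degenerate boxes. Matches must
contain exactly two CG dinucleotides (counted on the reference 17-mer;
CG content is strand-symmetric). The box "center" is the 9th base in
motif orientation — the printed asymmetric score windows imply some such
convention without stating it, so it is declared here; it can shift all
offsets by at most 1 bp. Minus-strand observation windows are flipped
into motif orientation.

Profiles are per-offset means over observations followed by a width-10
rolling mean using the window [−5, +4], truncated at the ends (no
padding). The footprint score divides the flank mean (offsets −35..−27
and +22..+27, inclusive) by the core mean (−7..+1) plus a 1e-3
pseudocount guarding fully protected cores. Distributions subsample
⌈10 % × n⌉ observations without replacement 1000 times (site × fiber
pairs are the resampling unit), reproducibly from a seed.

Nucleosome-edge positioning records, per (box, molecule), the boundary
of the nearest fully-upstream and fully-downstream footprint relative to
the center, in motif orientation; a footprint covering the center itself
contributes to neither side.

## Synthetic fixtures

The generator emulates the data-generating process the analyses assume:

* **Reference** — a tandem array of one random A/T-rich monomer
  (default 170 bp; the consensus satellite unit is ~171 bp and both are
  selectable), flanked by non-satellite sequence. Every second monomer
  (configurable) carries one exact-consensus CENP-B box instance with N
  positions drawn from {A, T} so each instance keeps exactly its two
  fixed CpGs; the monomer is rejection-sampled to carry no accidental
  consensus match on either strand, including across the tandem
  junction.
* **CpG methylation** — Bernoulli per CG site: 0.05 inside the planted
  core versus 0.85 outside, with a 0.05 per-site dropout to uncalled;
  the bundle also exposes the expected per-site fractions as the bulk
  methylation track.
* **Nucleosomes** — inside the core, one 147 bp footprint per monomer at
  a fixed phase; with probability 0.5 (the reported ~50 % di-nucleosome
  fraction of core footprints) two neighbours merge into one 211–300 bp
  footprint. Outside the core (or when phasing is disabled), arrays are
  placed at the 190 bp euchromatic spacing with a random per-fiber
  phase. Spacing within a fiber is exact; real nucleosome arrays jitter,
  so real spectra are broader than fixture spectra.
* **Accessible patches** — a per-fiber Gamma-mixed Poisson process:
  rate 0.11/kb in the core (matching 6–28 patches per 80–220 kb core)
  and 0.02/kb outside, patch lengths 151–800 bp (strictly "large" under
  the > 150 bp cutoff), with a mean-1 Gamma rate multiplier of variance
  (cluster_factor − 1) drawn once per fiber — the simplest overdispersed
  model of within-molecule patch clustering. Patches carve out
  underlying nucleosomes. Overlap rejection makes the realized rate
  slightly conservative at high densities.
* **CENP-B occupancy** — each overlapping molecule's box state (0/1/2
  methylated box CpGs, drawn from that molecule's methylation before
  dropout) sets the occupancy probability (defaults 0.8/0.1/0.05,
  encoding only the reported direction: methylation abrogates binding).
  Occupied boxes clear nucleosomes within ±(30 + 25) bp of the center
  and plant a 60 bp protein-sized footprint; patches are left intact,
  since bound-protein footprints sit inside accessible patches. This
  clearing (and patch carving) means the realized core di-nucleosome
  fraction is below the raw 0.5 merge rate.
* **m6A stenciling** — every A/T base not under a footprint is
  methylated with probability 0.4; footprinted bases never are. The
  base composition (A/T ≈ 0.6) keeps linkers well above 25 % A/T.

One master seed drives a spawned child-seed tree, so the reference and
any fiber subset regenerate independently and byte-identically.

Preset problem sizes were chosen to make each validated property
statistically decidable: spectral fixtures use 300 fibers × 15 kb; the
core-calling fixture a 300 kb array with a centered 20 kb dip; the
scoring fixture 400 fibers with core methylation 0.5 (so all three mCpG
states are populated — at the 0.05 core default, state 2 has probability
0.0025) and unphased arrays (so the flank/core score reads out box
occupancy rather than array phasing; with the box buried under a phased
nucleosome, unoccupied strata degenerate to a 0/0 ratio). The spacing
fixture uses dense short patches (3/kb, 151–180 bp) on 40 kb fibers so
that fiber-edge truncation of observed gaps (which alone biases the
observed/expected ratio below 1 at sparse densities) is negligible.

## What passing tests do and do not show

The fixtures validate the operators against known truth: that the
periodogram pipeline recovers planted spacings to ±2 bp, that the core
caller localizes a planted dip to ±1 step and applies each filter as
specified, that the footprint score orders strata consistently with
planted occupancy, and that the spacing statistic separates clustered
from Poisson placement. They do not model sequencing error, m6A/mCpG
caller bias, mappability over real higher-order repeats, satellite
sequence divergence, or nucleosome-spacing jitter, so passing them
bounds implementation correctness, not performance on real libraries.

## Numerical conventions

Undefined densities and fractions are NaN, never 0. Strict inequalities
at every published cutoff (> 210, > 150, < percentile, < 25 bp gap).
Percentile ties are protected by a 1e-9 epsilon. The periodogram uses
scipy's one-sided density scaling; its oracle test reproduces that
scaling explicitly. Subsampling is without replacement. Peak ties break
toward shorter repeat lengths; a flat spectrum returns its first grid
point with a warning.

## Known limitations

* The naive segmenter is threshold-based and will miscall fibers with
  locally depressed MTase efficiency; production segmentation should be
  supplied in the input BAM when available.
* BAM footprint tags are lifted by endpoint mapping through aligned
  pairs; footprints spanning large indels may shift by a few bp.
* The core caller's boundary consensus rule is step-quantized; cores
  whose true edges fall mid-step inherit up to one step of error.
* Score distributions assume exchangeable observations within a
  stratum; box-specific sequence effects are averaged, not modeled.
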
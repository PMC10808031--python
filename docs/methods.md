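# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind the `lamina` toolkit, and what the
synthetic-data generators do and do not emulate.

## DamID read structure and counting

DamID marks chromatin contacting a Dam-fusion protein by adenine
methylation at GATC motifs. After DpnI digestion and adaptor-mediated
amplification, an informative read begins with a fixed 17-nt DamID
adaptor (`GGTCGCGGCCGAGGATC`) whose final four bases restore the
genomic GATC of the fragment boundary.

**Trimming** (`preprocess_reads`). Mates of a pair are split and
treated as independent single reads. A read is kept only if its
sequence literally begins with the adaptor; `N` never matches the
anchor. The first 13 bases are removed, leaving `GATC` at the 5' end.
The 3' end is then quality-trimmed (trailing bases with Phred < 20 are
dropped) and a 3' occurrence of the complementary adaptor
(`GATCCTCGGCCGCGACC`) is removed — a full internal occurrence first,
otherwise an adaptor prefix of ≥ 3 nt that is a suffix of the read.
Reads shorter than 22 nt are discarded. The order quality-trim →
adaptor-trim is a documented choice; at the default high-quality
simulation settings the order is immaterial.

**GATC map** (`build_gatc_map`). GATC is its own reverse complement,
so a single forward scan finds all sites. Internal fragments are the
half-open intervals `[motif_i, motif_{i+1})` between consecutive motif
starts — a convention that makes fragments a partition of the span
between the first and last motif. The sub-motif leader and trailer of
each chromosome are terminal and excluded from counting.

**Counting** (`count_fragments`). Alignments with MAPQ ≤ 10 are
excluded (strictly greater than 10 passes). In the default *anchored*
mode a forward-strand read is assigned to the fragment starting at its
alignment start (which must be a motif start); a reverse-strand read
whose alignment end equals a motif start + 4 is assigned to the
fragment *ending* at that motif. Under this convention the two reads
of one DamID amplicon (`GATC ... GATC`) increment the same fragment,
which is what makes the read → count round trip exact. A *containment*
fallback assigns a read to the fragment containing its 5'-most aligned
base. Unassignable reads are tallied and reported, never silently
dropped. PCR-duplicate collapsing is out of scope.

## DamID scores

Per replicate `r` and interval `i`,

    score_{i,r} = log2( (damlam_{i,r} + c) / (dam_{i,r} + c) )

computed on per-million-scaled counts, and the track score is the
arithmetic mean over replicates. In 100-kb-bin mode, scaled fragment
values are summed into bins by fragment midpoint before the ratio
(sum-then-ratio is more stable than averaging per-fragment ratios);
binless mode scores each GATC fragment. Defaults: pseudocount c = 1
scaled unit (the upstream pipeline the convention derives from does
not print its pseudocount; c is configurable), per-million scaling on,
and an interval is *missing* (NaN) when its raw counts are zero in
both channels of any replicate. Missingness deliberately exercises the
HMM's marginalization path. No GC or mappability correction is
attempted.

Note one consequence of per-million scaling: a genome-wide enrichment
pattern `2^delta` enters the score as `delta − log2(E_w[2^delta])`,
i.e. all scores share a constant offset that depends on the
LAD-fraction-weighted mean enrichment. Segmentation is invariant to
this offset. Where the synthetic-data tests check that scores converge
to the planted `delta` values themselves, they therefore run with
per-million scaling off (equal library scale by construction).

## LAD segmentation: two-state Student-t HMM

Score tracks are heavy-tailed, so emissions are Student-t:
`x | state s ~ mu_s + sigma_s * t_nu`, with a shared `nu` (default 5;
`nu="estimate"` re-optimizes it against the observed likelihood each
EM iteration by bounded 1-D search on log nu in [0.5, 100]).

* Each chromosome is an independent observation sequence.
* Baum–Welch EM runs in log space (log-sum-exp); missing bins
  contribute emission likelihood 1 and are marginalized out, so the
  transition structure bridges them.
* M-step for the t family uses the standard scale-mixture weights
  `u = (nu+1) / (nu + ((x−mu)/sigma)^2)`; the joint (mu, sigma) update
  maximizes the EM Q-function exactly, so the observed log-likelihood
  is non-decreasing — asserted at every iteration with a 1e-8 relative
  tolerance for round-off.
* Initialization: mu at the 25th/75th percentiles of the observed
  scores, both sigmas at half the interquartile range, self-transitions
  0.9, uniform initial state probabilities. The final segmentation is
  label-symmetric; states are relabeled so state 1 has the larger mu
  (the LAD state).
* Convergence: |delta log-likelihood| < 1e-6, at most 200 iterations.
  Constant (zero-variance) observations raise a degenerate-fit error;
  an all-missing chromosome is skipped with a warning.
* Decoding is Viterbi (verified against brute-force path enumeration
  for short sequences). Posterior thresholding is not used.

**LAD calling.** Maximal runs of LAD-state intervals merge into single
LADs; runs never cross chromosome boundaries. Missing intervals
flanked by LAD-state intervals on both sides are bridged into the
surrounding LAD by default (domains are continuous blocks), or split
when bridging is disabled. `lad_stats` reports the count and mean
length in kb; an empty set reports an explicit `None` mean, not 0.

**Region comparison.** A UCSC-style cytoband table defines the
partition. Which bands constitute the peri-centromere is a
configuration, not something the table decides by itself: by default
bands stained `acen`/`gvar` are centromeric, and telomeres may be
given either as named bands or as a fixed flank at each chromosome
end. Track intervals join the region containing their midpoint; region
pairs are compared with the Wilcoxon rank-sum test (exact for small
samples, below) and medians are reported.

## Differential LAD classes and annotation

With ≥ 1 bp overlap as the criterion (configurable `min_overlap`): an
fLAD is a wild-type LAD overlapping no mutant LAD, an fiLAD is a
mutant LAD overlapping no wild-type LAD, and cLADs are the shared
rest. Because "number of shared LADs" depends on the counting basis,
all three are reported: WT basis (default), mutant basis, and merged
intersection; the complement identities
`fLAD + cLAD_wt = |WT|` and `fiLAD + cLAD_mut = |mutant|` hold by
construction.

Feature annotation is LAD-wise: a LAD's combination contains
`intron` / `CDS` / `5UTR` / `3UTR` if it overlaps ≥ 1 bp of that
feature in any transcript (introns are per-transcript gaps between
exons, unioned over transcripts), `inter_gene` if ≥ 1 bp lies outside
every gene body, and `no_CDS` if it overlaps at least one gene none of
whose transcripts has a CDS — i.e. `no_CDS` marks non-coding-gene
overlap, a documented interpretation. Counts are aggregated per exact
combination (UpSet-style). Gene export uses ≥ 1 bp gene-body overlap
by default, with a full-containment alternative.

## Distribution Index imaging

The D.I. of a nucleus is the sample standard deviation (ddof = 1;
negligible vs. n−0 at ROI sizes of ~10^4 px, but documented) of pixel
intensity within the nuclear ROI divided by the mean intensity. It is
0 for a homogeneous rim and scale-invariant by construction.
Measurement happens on the 8-bit-converted image, matching the macro
recipe, with a raw-image mode available in principle by passing the
raw array to `compute_di`.

ImageJ-semantics primitives:

* **8-bit conversion**: linear min–max onto [0, 255], rounded;
  a constant image maps to zeros with a warning. (The interactive
  display-range dependence of the original tool cannot be reproduced;
  min–max is the deterministic stand-in.)
* **Huang threshold**: minimizes the Huang–Wang fuzziness (Shannon
  entropy of class membership, `mu(g) = 1/(1+|g−mean_class|/C)`) over
  the 256-bin histogram; ties — common for well-separated histograms,
  where a whole plateau of thresholds is equally good — resolve to the
  plateau midpoint. **Mean threshold**: the image mean. Dark
  background means foreground = pixels strictly above the threshold.
  An empty foreground or background sets a degenerate flag on the
  result instead of failing silently.
* **Median filter**: disc neighborhood (Euclidean radius; 13 px at
  radius 2), edges replicated.
* **Binary morphology**: count-based 8-neighborhood operations —
  erode removes a foreground pixel when ≥ `count` of its 8 neighbors
  are background, dilate is the dual; off-image neighbors are
  background.
* **Particle analysis**: 8-connected components, per-component hole
  filling before area measurement, removal of border-touching
  components, and a minimum area in calibrated µm² when a pixel size
  is set (0.1 µm default, the acquisition pixel size) or in px²
  otherwise. Nested-particle hole filling (a particle inside another's
  hole) is not disambiguated — a known, irrelevant-in-practice corner.

ROI protocols: *lamin* = 8-bit → Huang → particles ≥ 30 µm² → erode ×5
(count 1) → particles ≥ 30 µm²; *npc* = 8-bit → median(2) → Mean →
particles ≥ 5 µm² → dilate ×5 → particles → erode ×10 → particles
(the dilate/erode cycle closes the gaps that punctate pore staining
leaves in the mask); *costain* = lamin protocol on the ROI-source
channel, ROIs transferred to the target channel. The macro the lamin
recipe derives from contains two consecutive auto-threshold calls
("Default dark" then "Huang dark"); the second is taken as operative.

Aggregation follows the acquisition design: 10–12 nuclei per
individual (warned otherwise), per-individual mean D.I., then an
unpaired two-tailed t-test for two groups or one-way ANOVA with
Tukey's multiple comparison for more.

## Nuclear stiffness

Per press cycle the equilibrium is the first frame after which the
span changes by less than `plateau_eps` = 0.1 µm per frame for
`plateau_window` = 4 consecutive frames (2 s at the 0.5-s frame
interval) — this is the package's operationalization of "deformation
reached an equilibrium", and both parameters are configurable. Span
and tip displacement are averaged over the detected plateau window
(waiting for equilibrium is precisely what lets jitter average out);
the baseline span is re-taken at each cycle's first frame. Deformation
= baseline − equilibrium span (µm); force = equilibrium tip deflection
× calibrated tip stiffness `k_tip` (nN/µm; 11.3–12.0 in the
instrument's calibrated range, 12.0 by default in the generator).

Stiffness is the OLS slope of force on deformation *with* an intercept
(through-origin fitting is available but not the default, since offsets
from contact geometry are common); R² < 0.96 triggers a warning, the
fit quality expected of clean elastic data. The 2-µm display binning
of force–deformation plots never enters the regression. Nuclear
stiffness = matched-pair subtraction of the nucleus-free ("cell only")
slope from the nucleus+cell slope; a group-mean subtraction can be
composed from the same pieces. Non-positive net stiffness is flagged,
not clamped. Group comparison uses the Mann–Whitney U test.
Viscoelastic (time-dependent) behavior is not modeled.

## Shared statistics

* **t-tests**: pooled-variance Student form by default (Welch
  optional), two-tailed; paired = one-sample t on differences.
  Zero-variance edge cases resolve to (t = 0, p = 1) for equal means
  and a flagged degenerate result otherwise.
* **ANOVA + Tukey**: one-way F, then Tukey HSD via the studentized
  range on all pairs.
* **Mann–Whitney / Wilcoxon rank-sum** (one function, two names):
  for combined n ≤ 16 the two-sided p is exact — via the null U
  distribution for tie-free data, and by full permutation enumeration
  of the observed values when ties are present. The normal
  approximation with tie correction is used only above that size. The
  tied-small-sample exact path exists because the approximation is
  genuinely poor there (deviations up to ~0.09 in the tail and ~0.5
  near the center at n = 7 against enumeration); enumerating
  C(16, 8) = 12,870 labelings is cheap and removes the error entirely.
  Exact p is defined as 2 × the smaller tail probability, capped at 1.
* **Pearson r** with n ≥ 3 and non-constant inputs enforced.

Normality/variance screening (F test, Brown–Forsythe) is advisory
territory and not implemented as a gate.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given (parameters, seed) and return a
truth object beside the data; no test infers truth from data.

* **DamID counts** (`synth_damid_counts`). Defaults are the
  desk-scale study condition: four 30-Mb chromosomes (~1,200 100-kb
  bins), two replicates, planted LADs 0.3–1.5 Mb long aligned to the
  100-kb scoring grid with 0.5–3 Mb gaps, log2 enrichment +1.5 inside
  and −0.5 outside (2.0 log2-unit contrast), negative-binomial counts
  (Gamma–Poisson, dispersion 0.2 — typical sequencing overdispersion;
  0 gives Poisson) around fragment-length-proportional rates at 3 M
  expected reads per channel. GATC spacing is 50 bp + Exponential(mean
  2 kb): the floor guarantees every fragment supports a full-length
  trimmed read; the 2-kb mean (vs ~256 bp in real sequence) keeps
  fragment arrays small without changing any per-bin statistics.
  Not emulated: mappability structure, GC bias, chromatin-accessibility
  background, replicate batch effects beyond independent sampling —
  so passing recovery tests demonstrates the estimator under the
  stated noise model, not robustness to real-data artifacts.
* **Reads** (`synth_damid_fastq`). Every read is adaptor-bearing and
  anchored at one of its fragment's two boundary motifs, alternating
  ends, with constant Phred-40 qualities; reads are split alternately
  into R1/R2 (downstream treats mates independently). Fragments
  shorter than the nominal genomic read span yield truncated, flagged
  reads. The companion `synth_genome_with_gatc` builds a random genome
  whose GATC sites are exactly the mapped motifs (accidental motifs
  are mutated away), and `perfect_alignments` reconstructs error-free
  coordinates from read provenance — standing in for an external
  aligner on synthetic data only. Sequencing errors, quality decay and
  multi-mapping are not emulated.
* **Rim images** (`synth_nucleus_image`). Surface-view nuclei as
  filled ellipses (radius 60–80 px = 6–8 µm at the 0.1-µm pixel size,
  on a 512×512 canvas), intensity multiplied inside each nucleus by
  `exp(h·G)` with G a unit-variance Gaussian random field smoothed at
  10 px, plus Gaussian read noise. The log-normal multiplicative form
  makes the intensity CV analytically monotone in h (CV =
  sqrt(exp(h²)−1) before quantization), which is what the monotonicity
  tests rely on; h ≈ 0.2 yields D.I. ≈ 0.2 (organized-lamina range)
  and h ≈ 0.4 yields ≈ 0.4 (disorganized range). Optics (PSF,
  z-sectioning), rim-specific edge brightening, and background
  autofluorescence are not emulated.
* **Force traces** (`synth_force_trace`). Defaults k_nucleus = 4.0,
  k_cell = 0.8, k_tip = 12.0 nN/µm; five press cycles to 2–10 µm;
  0.5-s frames; each press ramps over 4 frames, holds a 10-frame
  plateau, releases, rests. Noise is Gaussian tracking jitter with a
  ~1-s correlation time on both the span and tip channels (image
  tracking errors are not frame-independent); marginal SD is the
  `noise_sd` parameter. Plastic deformation, blebbing, rupture and
  viscoelastic creep are not emulated.
* **Gene models** (`synth_gene_model`). Non-overlapping genes with
  2–5 exons, UTRs at transcript ends, CDS over the exonic remainder,
  and a 20% non-coding fraction by default; structural identities
  (introns = exons − 1, CDS ⊂ exons ⊂ gene body) hold by
  construction. Alternative splicing and overlapping genes are not
  emulated.

## Problem sizes

The test suite and the acceptance script run entirely at desk scale:
~1,200 bins / ~59 k fragments for the DamID pipeline, 150-bin tracks
for the repeated EM fits, 512×512 images, ≤ 64×64 masks for the
morphology oracles, 100–150 kb toy genomes for read round trips, and
20-seed ensembles for stiffness recovery — sizes chosen so the full
pipeline, not a shortcut, runs in seconds per property.

## Known limitations

* The HMM is strictly 2-state; weak/intermediate association states
  are out of scope.
* Binless segmentation treats fragments as equally informative
  regardless of length; no length weighting of emissions.
* The cytoband-to-region mapping ships as configuration because band
  nomenclature alone does not determine "peri-centromere".
* `to_8bit` cannot reproduce display-range-dependent conversions of
  interactive tools; analyses comparing D.I. across images assume a
  common conversion rule, which min–max provides.
* Exact Mann–Whitney enumeration stops at combined n = 16; beyond
  that the tie-corrected normal approximation applies.
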
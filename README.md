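# lamina

Quantitative analysis of nuclear-lamina organization in *Drosophila*
muscle — a reusable Python implementation of three measurement
pipelines that are usually buried in one-off scripts and imaging
macros:

1. **DamID-seq LAD calling.** From adaptor-bearing DamID reads to
   lamina-associated domains (LADs): GATC-anchored read trimming and
   per-fragment counting, replicate-averaged
   `log2(Dam-Lam / Dam)` score tracks (100-kb bins or binless), LAD
   segmentation with a two-state hidden Markov model with Student-t
   emissions, differential classification of LADs between genotypes
   (cLAD = shared, fLAD = lost in the mutant, fiLAD = ectopic in the
   mutant), gene-feature annotation (intron / CDS / UTR / intergenic /
   non-coding) and region-wise score comparison against cytoband-derived
   centromeres and telomeres.
2. **Distribution Index (D.I.) imaging.** Heterogeneity of
   nuclear-envelope proteins (B-type lamin, nuclear pore complexes,
   LEM-domain proteins) quantified as the coefficient of variation,
   `D.I. = SD / mean`, of fluorescence intensity inside an eroded
   nuclear ROI. The ROI construction reproduces an ImageJ macro recipe
   primitive by primitive (min–max 8-bit conversion, Huang/Mean
   auto-thresholding, disc median filter, count-based binary
   erosion/dilation, particle analysis).
3. **Nuclear stiffness.** Microneedle force–deformation analysis:
   equilibrium points extracted from press–release cycles
   (force = calibrated tip stiffness x tip deflection, in nN;
   deformation = loss of nuclear span, in µm), stiffness as the OLS
   slope `k` of force on deformation (nN/µm), and the purely nuclear
   stiffness after subtracting a matched nucleus-free measurement.

A `synthetic_data` module generates seeded datasets with planted ground
truth for every stage (negative-binomial DamID counts with planted
LADs, adaptor-bearing reads, rim images with a tunable heterogeneity
field, toy gene models, force traces from known stiffnesses), so the
whole toolkit is testable at desk scale. Shared statistics (pooled
Student's t, one-way ANOVA + Tukey HSD, exact Mann–Whitney U /
Wilcoxon rank-sum, Pearson r) live in `lamina.group_stats`.

The model at the core of the LAD caller: per interval *i* the DamID
score is

    s_i = mean_r log2( (damlam_{i,r} + c) / (dam_{i,r} + c) )

on per-million-scaled counts, and the score sequence per chromosome is
segmented by a 2-state HMM with emissions
`x | state ~ mu_s + sigma_s * t_nu` (shared `nu`, default 5), fitted by
Baum–Welch EM in log space with missing bins marginalized, decoded by
Viterbi; the state with larger `mu` is the LAD state.

## Worked example

```python
import numpy as np
from lamina import synthetic_data as sd
from lamina import *

# --- DamID: simulate counts with planted LADs, score, segment -------
damlam, dam, truth = sd.synth_damid_counts(seed=1)
track = score_track(damlam, dam, mode="bins", chrom_lengths=truth.chrom_lengths)
model, path = fit_segment_hmm(track)
lads = call_lads(path, track.intervals, missing=track.missing)
count, mean_kb = lad_stats(lads)

# --- D.I.: simulate a rim image at heterogeneity h = 0.4 ------------
img, _ = sd.synth_nucleus_image(h=0.4, noise_sd=2.0, seed=7)
rois, img8 = make_roi(img, protocol="lamin")
dis = [compute_di(img8, r) for r in rois]

# --- stiffness: paired traces, k_nucleus = 4.0 nN/um ----------------
total, cell, _ = sd.synth_force_trace(noise_sd=0.1, seed=2)
k, _ = net_stiffness(fit_stiffness(extract_points(total)),
                     fit_stiffness(extract_points(cell)))
```

prints (via the obvious `print` statements):

```
bins: 1200   replicate Pearson r: 0.963
HMM locations mu = (-1.03, 0.97), nu = 5, converged in 12 iterations
LADs called: 45   mean length: 924.4 kb   planted: 45
nucleus 1: 13300 px, mean 68.2, SD 27.7, D.I. 0.406
nucleus 2: 16029 px, mean 78.8, SD 32.5, D.I. 0.412
nucleus 3: 14848 px, mean 78.9, SD 37.7, D.I. 0.477
nucleus+cell slope 5.06 nN/um (R^2 0.992); cell only 0.87;
net nuclear stiffness 4.20 nN/um (true 4.0)
```

Reading the numbers: the two simulated replicates correlate at
r = 0.963 and the HMM recovers all 45 planted LADs (the fitted
emission locations straddle the planted −0.5 / +1.5 log2 enrichments
after per-million normalization); a heterogeneity amplitude of 0.4
produces D.I. ≈ 0.41–0.48, the range seen in strongly disorganized
lamina (homogeneous rims give D.I. = 0 exactly); and the paired-trace
subtraction recovers the planted 4.0 nN/µm nuclear stiffness to within
the tracking-noise uncertainty.

The same steps are available from the shell:

```bash
lamina simulate damid --seed 1 --out sim/
lamina damid-score --damlam sim/damlam_r1.tsv --damlam sim/damlam_r2.tsv \
                   --dam sim/dam_r1.tsv --dam sim/dam_r2.tsv --out score.bedgraph
lamina call-lads --score score.tsv --out lads.bed
lamina di --protocol lamin --images img.tif --out di.tsv
lamina stiffness --total trace_total.csv --cell trace_cell_only.csv --out k.tsv
```

## Layout

| module | contents |
| --- | --- |
| `lamina.gatc_reads` | GATC maps, DamID read trimming, fragment counting |
| `lamina.damid_scores` | score tracks, replicate correlation |
| `lamina.lad_segmentation` | Student-t HMM, LAD calling, region comparison |
| `lamina.lad_comparison` | cLAD/fLAD/fiLAD, gene-model annotation, gene lists |
| `lamina.imaging_di` | ImageJ-macro primitives, ROI protocols, D.I. |
| `lamina.nuclear_mechanics` | force–deformation extraction, stiffness fits |
| `lamina.group_stats` | t, ANOVA+Tukey, Mann–Whitney, Pearson |
| `lamina.synthetic_data` | seeded generators with ground truth |
| `lamina.cli` | `lamina` command-line entry points |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
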
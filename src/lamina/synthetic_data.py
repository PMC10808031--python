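"""Seeded generators emulating each pipeline stage's input data.

Every generator is deterministic given (parameters, seed) and returns a
truth object alongside the data, so downstream recovery can be scored
against planted ground truth:

* :func:`synth_nucleus_image` — surface-view nuclear rim images with a
  tunable multiplicative heterogeneity field,
* :func:`synth_damid_counts` — negative-binomial GATC-fragment counts
  with planted LADs and replicate structure,
* :func:`synth_genome_with_gatc` / :func:`synth_damid_fastq` — a genome
  with exactly the mapped GATC motifs, and adaptor-bearing reads whose
  preprocessing + counting round trip reproduces the planted counts,
* :func:`synth_gene_model` — toy gene models with consistent
  exon/intron/CDS/UTR structure,
* :func:`synth_force_trace` — press-release micromanipulation traces
  generated by known nuclear and cell stiffnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .gatc_reads import DAMID_ADAPTOR, FragmentCounts, GATCMap, ReadRecord
from .lad_comparison import Gene, GeneModel, Transcript
from .nuclear_mechanics import ManipulationTrace

__all__ = [
    "SimImageTruth",
    "SimDamIDTruth",
    "SimTraceTruth",
    "synth_nucleus_image",
    "synth_damid_counts",
    "synth_genome_with_gatc",
    "synth_damid_fastq",
    "perfect_alignments",
    "synth_gene_model",
    "synth_force_trace",
    "plant_lads",
]


# ---------------------------------------------------------------------------
# nuclear surface images
# ---------------------------------------------------------------------------

@dataclass
class SimImageTruth:
    masks: list  # per-nucleus boolean masks (disjoint)
    h: float
    base_intensity: float
    noise_sd: float
    seed: int


def synth_nucleus_image(
    n_nuclei: int = 3,
    shape: tuple[int, int] = (512, 512),
    radius_range: tuple[float, float] = (60.0, 80.0),
    base_intensity: float = 150.0,
    h: float = 0.0,
    blob_scale: float = 10.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.1,
    seed: int = 0,
    margin: int = 16,
    max_tries: int = 500,
) -> tuple[np.ndarray, SimImageTruth]:
    """Draw non-overlapping elliptical nuclei with a heterogeneity field.

    Each nucleus is a filled ellipse (the surface view of the lamin rim)
    at ``base_intensity``, multiplied inside the nucleus by
    ``exp(h * G)`` where ``G`` is a smoothed, unit-variance Gaussian
    random field at correlation length ``blob_scale`` px; Gaussian read
    noise of ``noise_sd`` is then added. At ``h = 0`` and zero noise
    every nucleus is perfectly homogeneous, and the intensity CV inside
    a nucleus grows monotonically with ``h``.
    """
    if h < 0:
        raise ValueError("heterogeneity amplitude h must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    masks: list[np.ndarray] = []
    centers: list[tuple[float, float, float, float]] = []
    tries = 0
    while len(masks) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place nuclei without overlap")
        a = rng.uniform(*radius_range)
        b = rng.uniform(*radius_range)
        cy = rng.uniform(margin + b, H - margin - b)
        cx = rng.uniform(margin + a, W - margin - a)
        ok = all(
            (cy - oy) ** 2 + (cx - ox) ** 2 > (max(a, b) + max(oa, ob) + 4) ** 2
            for oy, ox, oa, ob in centers
        )
        if not ok:
            continue
        mask = ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0
        masks.append(mask)
        centers.append((cy, cx, a, b))

    img = np.zeros(shape, dtype=float)
    for mask in masks:
        field_ = rng.standard_normal(shape)
        field_ = ndimage.gaussian_filter(field_, blob_scale)
        sd = field_.std()
        if sd > 0:
            field_ /= sd
        img[mask] = base_intensity * np.exp(h * field_[mask])
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, shape), 0, None)
    truth = SimImageTruth(masks=masks, h=h, base_intensity=base_intensity,
                          noise_sd=noise_sd, seed=seed)
    return img, truth


# ---------------------------------------------------------------------------
# DamID fragment counts with planted LADs
# ---------------------------------------------------------------------------

@dataclass
class SimDamIDTruth:
    planted_lads: pd.DataFrame  # chrom, start, end
    delta_in: float
    delta_out: float
    dispersion: float
    gatc_map: GATCMap
    chrom_lengths: dict
    seed: int

    def lad_mask_for_bins(self, intervals: pd.DataFrame) -> np.ndarray:
        """True for intervals whose midpoint lies inside a planted LAD."""
        mids = ((intervals["start"] + intervals["end"]) // 2).to_numpy()
        chroms = intervals["chrom"].to_numpy()
        out = np.zeros(len(intervals), dtype=bool)
        for _, lad in self.planted_lads.iterrows():
            out |= (
                (chroms == lad["chrom"]) & (mids >= lad["start"]) & (mids < lad["end"])
            )
        return out


def plant_lads(
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    lad_length_range: tuple[int, int] = (300_000, 1_500_000),
    gap_range: tuple[int, int] = (500_000, 3_000_000),
    snap: int = 100_000,
) -> pd.DataFrame:
    """Place disjoint LADs along each chromosome, aligned to ``snap``."""
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = int(rng.integers(gap_range[0] // 2, gap_range[1]))
        while True:
            lad_len = int(rng.integers(*lad_length_range))
            start = (pos // snap) * snap
            end = ((pos + lad_len) // snap) * snap
            if end >= length - snap:
                break
            if end > start:
                rows.append((chrom, start, end))
            pos = end + int(rng.integers(*gap_range))
            if pos >= length:
                break
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _nb_sample(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via Gamma-Poisson; dispersion 0 is Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def synth_damid_counts(
    chrom_lengths: dict[str, int] | None = None,
    mean_gatc_spacing: float = 2000.0,
    min_gatc_spacing: int = 50,
    planted_lads: pd.DataFrame | None = None,
    delta_in: float = 1.5,
    delta_out: float = -0.5,
    dispersion: float = 0.2,
    library_size: float = 3_000_000.0,
    replicates: int = 2,
    seed: int = 0,
) -> tuple[list[FragmentCounts], list[FragmentCounts], SimDamIDTruth]:
    """Simulate per-fragment DamID counts with planted LADs.

    GATC motif spacing is ``min_gatc_spacing`` plus an exponential with
    the given mean. Dam counts are negative binomial around a rate
    proportional to fragment length (expected ``library_size`` total);
    Dam-Lam rates are the Dam rates scaled by ``2**delta`` with
    ``delta_in`` inside planted LADs and ``delta_out`` outside.
    Replicates are independent draws. Defaults give a genome of ~1,200
    100-kb bins with two replicates, the desk-scale study condition.

    Returns ``(damlam_per_replicate, dam_per_replicate, truth)``.
    """
    if delta_in <= delta_out:
        raise ValueError("delta_in must exceed delta_out")
    if chrom_lengths is None:
        chrom_lengths = {"chr2L": 30_000_000, "chr2R": 30_000_000,
                         "chr3L": 30_000_000, "chr3R": 30_000_000}
    rng = np.random.default_rng(seed)
    motifs = {}
    for chrom, length in chrom_lengths.items():
        n_expect = int(1.2 * length / (mean_gatc_spacing + min_gatc_spacing)) + 10
        gaps = min_gatc_spacing + rng.exponential(mean_gatc_spacing, size=n_expect)
        pos = np.cumsum(gaps).astype(np.int64)
        motifs[chrom] = pos[pos < length - 4]
    gatc_map = GATCMap(motifs=motifs, lengths=dict(chrom_lengths))
    frags = gatc_map.fragments
    if planted_lads is None:
        planted_lads = plant_lads(chrom_lengths, rng)

    lengths = (frags["end"] - frags["start"]).to_numpy(dtype=float)
    mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
    in_lad = np.zeros(len(frags), dtype=bool)
    chroms = frags["chrom"].to_numpy()
    for _, lad in planted_lads.iterrows():
        in_lad |= (chroms == lad["chrom"]) & (mids >= lad["start"]) & (mids < lad["end"])
    delta = np.where(in_lad, delta_in, delta_out)

    dam_rate = library_size * lengths / lengths.sum()
    damlam_rate = dam_rate * 2.0**delta
    dam_list, damlam_list = [], []
    for r in range(1, replicates + 1):
        dam_counts = _nb_sample(rng, dam_rate, dispersion)
        dl_counts = _nb_sample(rng, damlam_rate, dispersion)
        dam_list.append(FragmentCounts(
            fragments=frags.copy(), counts=pd.DataFrame({f"dam_r{r}": dam_counts})
        ))
        damlam_list.append(FragmentCounts(
            fragments=frags.copy(), counts=pd.DataFrame({f"damlam_r{r}": dl_counts})
        ))
    truth = SimDamIDTruth(
        planted_lads=planted_lads, delta_in=delta_in, delta_out=delta_out,
        dispersion=dispersion, gatc_map=gatc_map,
        chrom_lengths=dict(chrom_lengths), seed=seed,
    )
    return damlam_list, dam_list, truth


# ---------------------------------------------------------------------------
# genomes and adaptor-bearing reads
# ---------------------------------------------------------------------------

def synth_genome_with_gatc(
    chrom_lengths: dict[str, int],
    motifs: dict[str, np.ndarray],
    seed: int = 0,
) -> dict[str, str]:
    """Random genome containing GATC exactly at the requested positions.

    Accidental GATC occurrences elsewhere are broken by mutating their
    third base, so :func:`~lamina.gatc_reads.build_gatc_map` on the
    result recovers ``motifs`` exactly.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome = {}
    for chrom, length in chrom_lengths.items():
        arr = rng.choice(bases, size=length)
        planted = np.asarray(motifs.get(chrom, []), dtype=int)
        for p in planted:
            arr[p: p + 4] = list("GATC")
        seq = "".join(arr)
        planted_set = set(int(p) for p in planted)
        # break accidental motifs (re-scan until clean: a mutation can in
        # principle create a new motif upstream)
        while True:
            accidental = []
            pos = seq.find("GATC")
            while pos != -1:
                if pos not in planted_set:
                    accidental.append(pos)
                pos = seq.find("GATC", pos + 1)
            if not accidental:
                break
            chars = list(seq)
            for p in accidental:
                # avoid touching a planted motif's bases
                q = p + 2
                if any(abs(q - sp) < 4 for sp in planted_set if abs(q - sp) < 8):
                    q = p  # fall back to the first base
                chars[q] = "C" if chars[q] != "C" else "A"
            seq = "".join(chars)
        genome[chrom] = seq
    return genome


def synth_damid_fastq(
    gatc_map: GATCMap,
    genome: dict[str, str],
    counts: FragmentCounts,
    adaptor: str = DAMID_ADAPTOR,
    read_length: int = 150,
    quality: int = 40,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord], int]:
    """Emit adaptor-bearing reads reproducing a fragment count table.

    For a fragment with count c, c reads are generated alternating
    between the fragment's two ends: forward reads anchored at the
    fragment's start motif and reverse reads whose alignment would end
    at (fragment end motif + 4). Every read begins with the 17-nt DamID
    adaptor whose terminal GATC stands in for the genomic motif. Reads
    are split alternately into the returned (r1, r2) lists; the number
    of reads truncated by short fragments is returned as well.

    Read ids encode the true origin (``chrom:fragstart:fragend:strand``)
    for :func:`perfect_alignments`.
    """
    comp = str.maketrans("ACGT", "TGCA")
    r1: list[ReadRecord] = []
    r2: list[ReadRecord] = []
    truncated = 0
    serial = 0
    gl_nominal = read_length - len(adaptor)
    col = counts.counts.columns[0]
    for (_, frag), c in zip(counts.fragments.iterrows(), counts.counts[col]):
        chrom, s, e = frag["chrom"], int(frag["start"]), int(frag["end"])
        seq = genome[chrom]
        for k in range(int(c)):
            gl = min(gl_nominal, e - s)  # amplicon bound
            if gl < gl_nominal:
                truncated += 1
            if k % 2 == 0:  # forward from the start motif
                genomic = seq[s + 4: s + 4 + (gl - 4)]
                strand = "+"
            else:  # reverse, 5' end at the end motif
                genomic = seq[e - (gl - 4): e].translate(comp)[::-1]
                strand = "-"
            read_seq = adaptor + genomic
            rid = f"{chrom}:{s}:{e}:{strand}:{serial}"
            serial += 1
            rec = ReadRecord(rid, read_seq, np.full(len(read_seq), quality))
            (r1 if serial % 2 else r2).append(rec)
    return r1, r2, truncated


def perfect_alignments(trimmed_reads) -> pd.DataFrame:
    """Error-free alignment table for reads from :func:`synth_damid_fastq`.

    Stands in for an external short-read aligner on synthetic reads:
    coordinates are reconstructed from the encoded read origin and the
    post-trimming read length (forward reads anchor their start at the
    fragment's start motif; reverse reads anchor their end at the end
    motif + 4).
    """
    rows = []
    for read in trimmed_reads:
        chrom, s, e, strand, _ = read.id.rsplit(":", 4)
        s, e = int(s), int(e)
        L = len(read)
        if strand == "+":
            rows.append((chrom, s, s + L, "+", 42))
        else:
            rows.append((chrom, e + 4 - L, e + 4, "-", 42))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "mapq"])


# ---------------------------------------------------------------------------
# toy gene models
# ---------------------------------------------------------------------------

def synth_gene_model(
    n_genes: int = 20,
    chrom: str = "chrS",
    exon_count_range: tuple[int, int] = (2, 5),
    exon_length_range: tuple[int, int] = (100, 400),
    intron_length_range: tuple[int, int] = (100, 500),
    intergenic_range: tuple[int, int] = (500, 2000),
    utr_length: int = 50,
    noncoding_fraction: float = 0.2,
    seed: int = 0,
) -> GeneModel:
    """Non-overlapping toy genes with consistent feature structure.

    Coding genes carry a 5'UTR at the transcript 5' end, a 3'UTR at the
    3' end, and CDS over the remaining exonic sequence; a
    ``noncoding_fraction`` of genes have exons but no CDS. Gene ids are
    ``g1..gN`` left to right.
    """
    rng = np.random.default_rng(seed)
    genes = []
    pos = int(rng.integers(*intergenic_range))
    for i in range(1, n_genes + 1):
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exons = []
        p = pos
        for j in range(n_exons):
            el = int(rng.integers(*exon_length_range))
            exons.append((p, p + el))
            p += el
            if j < n_exons - 1:
                p += int(rng.integers(*intron_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() >= noncoding_fraction
        tx = Transcript(id=f"g{i}.t1", exons=exons)
        if coding:
            # UTRs at the transcript ends; CDS is the exonic remainder
            first_s, first_e = exons[0]
            last_s, last_e = exons[-1]
            left_utr = (first_s, min(first_s + utr_length, first_e))
            right_utr = (max(last_e - utr_length, last_s), last_e)
            if strand == "+":
                tx.utr5, tx.utr3 = [left_utr], [right_utr]
            else:
                tx.utr5, tx.utr3 = [right_utr], [left_utr]
            for s, e in exons:
                cs = max(s, left_utr[1]) if (s, e) == exons[0] else s
                ce = min(e, right_utr[0]) if (s, e) == exons[-1] else e
                if len(exons) == 1:
                    cs, ce = left_utr[1], right_utr[0]
                if ce > cs:
                    tx.cds.append((cs, ce))
        genes.append(Gene(id=f"g{i}", chrom=chrom, start=exons[0][0],
                          end=exons[-1][1], strand=strand, transcripts=[tx]))
        pos = p + int(rng.integers(*intergenic_range))
    return GeneModel(genes)


def write_gff3(model: GeneModel, path) -> None:
    """Serialize a GeneModel to GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in model.genes:
            fh.write(f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")
            for tx in g.transcripts:
                ts = min(s for s, _ in tx.exons) + 1
                te = max(e for _, e in tx.exons)
                fh.write(f"{g.chrom}\tsynth\tmRNA\t{ts}\t{te}\t.\t{g.strand}\t.\t"
                         f"ID={tx.id};Parent={g.id}\n")
                for ftype, ivs in (("exon", tx.exons), ("CDS", tx.cds),
                                   ("five_prime_UTR", tx.utr5),
                                   ("three_prime_UTR", tx.utr3)):
                    for s, e in ivs:
                        fh.write(f"{g.chrom}\tsynth\t{ftype}\t{s + 1}\t{e}\t.\t"
                                 f"{g.strand}\t.\tParent={tx.id}\n")


# ---------------------------------------------------------------------------
# force traces
# ---------------------------------------------------------------------------

@dataclass
class SimTraceTruth:
    k_nucleus: float
    k_cell: float
    k_tip: float
    cycle_magnitudes: tuple
    noise_sd: float
    seed: int


def _smooth_noise(rng, n: int, sd: float, corr_frames: float = 2.0) -> np.ndarray:
    """Temporally correlated tracking jitter with marginal SD ``sd``."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n + 20)
    smooth = ndimage.gaussian_filter1d(white, corr_frames)[10:-10]
    s = smooth.std()
    return smooth / s * sd if s > 0 else np.zeros(n)


def _build_trace(
    rng,
    k_eff: float,
    k_tip: float,
    cycle_magnitudes,
    baseline_span: float,
    dt: float,
    noise_sd: float,
    condition: str,
    rest_frames: int = 4,
    ramp_frames: int = 4,
    plateau_frames: int = 10,
    release_frames: int = 3,
) -> ManipulationTrace:
    span = [baseline_span] * rest_frames
    tip = [0.0] * rest_frames
    cycles = []
    for d in cycle_magnitudes:
        start = len(span) - 1  # baseline frame just before the press
        for j in range(1, ramp_frames + 1):
            frac = j / ramp_frames
            span.append(baseline_span - d * frac)
            tip.append(k_eff * d * frac / k_tip)
        span.extend([baseline_span - d] * plateau_frames)
        tip.extend([k_eff * d / k_tip] * plateau_frames)
        end = len(span)
        cycles.append((start, end))
        for j in range(release_frames - 1, -1, -1):
            frac = j / release_frames
            span.append(baseline_span - d * frac)
            tip.append(k_eff * d * frac / k_tip)
        span.extend([baseline_span] * rest_frames)
        tip.extend([0.0] * rest_frames)
    n = len(span)
    span = np.asarray(span) + _smooth_noise(rng, n, noise_sd)
    tip = np.asarray(tip) + _smooth_noise(rng, n, noise_sd)
    return ManipulationTrace(
        time_s=np.arange(n) * dt, tip_disp_um=tip, span_um=span,
        k_tip=k_tip, condition=condition, cycles=cycles,
    )


def synth_force_trace(
    k_nucleus: float = 4.0,
    k_cell: float = 0.8,
    k_tip: float = 12.0,
    cycle_magnitudes: tuple = (2.0, 4.0, 6.0, 8.0, 10.0),
    dt: float = 0.5,
    noise_sd: float = 0.0,
    baseline_span: float = 20.0,
    seed: int = 0,
) -> tuple[ManipulationTrace, ManipulationTrace, SimTraceTruth]:
    """Paired press-release traces generated by known stiffnesses.

    The nucleus+cell trace has effective slope ``k_nucleus + k_cell``;
    the cell-only trace has slope ``k_cell``. Each press ramps over a
    few 0.5-s frames to the target deformation, holds an equilibrium
    plateau, then releases back to baseline. Tracking jitter (Gaussian,
    correlated over ~1 s) of ``noise_sd`` um is added to both the span
    and the tip-displacement channels.
    """
    if min(k_nucleus, k_cell, k_tip) <= 0:
        raise ValueError("stiffnesses must be positive")
    rng = np.random.default_rng(seed)
    total = _build_trace(rng, k_nucleus + k_cell, k_tip, cycle_magnitudes,
                         baseline_span, dt, noise_sd, "nucleus+cell")
    cell = _build_trace(rng, k_cell, k_tip, cycle_magnitudes,
                        baseline_span, dt, noise_sd, "cell only")
    truth = SimTraceTruth(k_nucleus=k_nucleus, k_cell=k_cell, k_tip=k_tip,
                          cycle_magnitudes=tuple(cycle_magnitudes),
                          noise_sd=noise_sd, seed=seed)
    return total, cell, truth
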
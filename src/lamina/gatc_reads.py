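"""DamID read preprocessing, GATC maps, and per-fragment read counting.

DamID marks chromatin by adenine methylation at GATC motifs; after DpnI
digestion and adaptor-mediated amplification, every informative sequencing
read begins with a fixed 17-nt DamID adaptor whose last four bases restore
the genomic GATC. This module re-creates that read structure in software:

* :func:`build_gatc_map` scans a genome for GATC motifs and derives the
  internal GATC fragments (the unit of DamID signal),
* :func:`preprocess_reads` performs adaptor anchoring, head trimming,
  3'-quality trimming, 3'-adaptor removal and length filtering,
* :func:`count_fragments` assigns MAPQ-filtered alignments to GATC
  fragments by motif anchoring (default) or 5'-end containment.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DAMID_ADAPTOR",
    "THREE_PRIME_ADAPTOR",
    "ReadRecord",
    "GATCMap",
    "FragmentCounts",
    "build_gatc_map",
    "preprocess_reads",
    "count_fragments",
    "read_fastq",
    "write_fastq",
    "alignments_from_bam",
]

#: 17-nt DamID adaptor found at the 5' end of informative reads.
DAMID_ADAPTOR = "GGTCGCGGCCGAGGATC"
#: Reverse complement of the DamID adaptor, removed from read 3' ends.
THREE_PRIME_ADAPTOR = "GATCCTCGGCCGCGACC"

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A sequencing read: id, DNA sequence, per-base Phred qualities."""

    id: str
    sequence: str
    quality: np.ndarray

    def __post_init__(self):
        self.quality = np.asarray(self.quality, dtype=int)
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"read {self.id}: non-DNA characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GATCMap:
    """Per-chromosome GATC motif positions and derived internal fragments.

    ``motifs[chrom]`` holds sorted 0-based motif start positions;
    fragments are the half-open intervals between consecutive motif
    starts, so they partition the span between the first and last motif.
    The sub-motif leader/trailer of each chromosome is terminal and is
    excluded from counting.
    """

    motifs: dict[str, np.ndarray]
    lengths: dict[str, int]
    fragments: pd.DataFrame = field(init=False)

    def __post_init__(self):
        rows = []
        for chrom in self.motifs:
            m = np.asarray(self.motifs[chrom], dtype=np.int64)
            if m.size and not np.all(np.diff(m) > 0):
                raise ValueError(f"{chrom}: motif starts not strictly increasing")
            self.motifs[chrom] = m
            for s, e in zip(m[:-1], m[1:]):
                rows.append((chrom, int(s), int(e)))
        self.fragments = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class FragmentCounts:
    """Per-GATC-fragment read counts, one integer column per sample."""

    fragments: pd.DataFrame  # chrom, start, end
    counts: pd.DataFrame  # one column per sample/replicate
    totals: dict[str, int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.fragments) != len(self.counts):
            raise ValueError("fragment and count tables differ in length")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for col in self.counts.columns:
            self.totals.setdefault(col, int(self.counts[col].sum()))

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.fragments.reset_index(drop=True), self.counts.reset_index(drop=True)],
            axis=1,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path, column: str) -> None:
        df = self.to_frame()[["chrom", "start", "end", column]]
        df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# GATC map construction
# ---------------------------------------------------------------------------

def build_gatc_map(genome: dict[str, str]) -> GATCMap:
    """Scan each chromosome for GATC motifs and derive internal fragments.

    GATC is its own reverse complement, so a single forward scan finds
    every site on both strands. Characters outside {A,C,G,T,N} are
    rejected.
    """
    motifs: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in genome.items():
        if not seq:
            raise ValueError(f"{chrom}: empty sequence")
        seq = str(seq).upper()
        if not set(seq) <= _DNA:
            bad = sorted(set(seq) - _DNA)
            raise ValueError(f"{chrom}: non-DNA characters {bad}")
        starts = []
        pos = seq.find("GATC")
        while pos != -1:
            starts.append(pos)
            pos = seq.find("GATC", pos + 1)
        motifs[chrom] = np.asarray(starts, dtype=np.int64)
        lengths[chrom] = len(seq)
    return GATCMap(motifs=motifs, lengths=lengths)


def build_gatc_map_from_fasta(path) -> GATCMap:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return build_gatc_map({name: str(fa[name][:]) for name in fa.keys()})


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

def _quality_trim_3p(read: ReadRecord, cutoff: int) -> ReadRecord:
    """Drop 3'-terminal bases until the last base has quality >= cutoff."""
    q = read.quality
    end = len(q)
    while end > 0 and q[end - 1] < cutoff:
        end -= 1
    return ReadRecord(read.id, read.sequence[:end], q[:end])


def _remove_3p_adaptor(read: ReadRecord, adaptor: str, min_overlap: int = 3) -> ReadRecord:
    """Remove a 3' occurrence of ``adaptor`` (and everything after it).

    Matches a full internal occurrence first, then an adaptor prefix of
    length >= ``min_overlap`` that is a suffix of the read.
    """
    seq = read.sequence
    idx = seq.find(adaptor)
    if idx == -1:
        for k in range(min(len(adaptor), len(seq)) - 1, min_overlap - 1, -1):
            if seq.endswith(adaptor[:k]):
                idx = len(seq) - k
                break
    if idx == -1:
        return read
    return ReadRecord(read.id, seq[:idx], read.quality[:idx])


def preprocess_reads(
    pairs,
    damid_adaptor: str = DAMID_ADAPTOR,
    three_prime_adaptor: str = THREE_PRIME_ADAPTOR,
    head_trim: int = 13,
    min_len: int = 22,
    qual_cut: int = 20,
) -> list[ReadRecord]:
    """Select and trim DamID reads from paired-end input.

    Mates are split and treated as independent single reads. A read is
    retained only when its sequence literally begins with the DamID
    adaptor (N never matches). The first ``head_trim`` bases are removed,
    leaving the adaptor's terminal GATC at the 5' end; the 3' end is then
    quality-trimmed at ``qual_cut`` and any 3' occurrence of the
    complementary adaptor removed. Survivors shorter than ``min_len`` are
    discarded. Input order is preserved among survivors.
    """
    if not set(damid_adaptor) <= set("ACGT") or not set(three_prime_adaptor) <= set("ACGT"):
        raise ValueError("adaptors must be plain DNA (A/C/G/T)")
    if head_trim >= len(damid_adaptor):
        raise ValueError("head_trim must be shorter than the DamID adaptor")

    out: list[ReadRecord] = []
    for pair in pairs:
        r1, r2 = pair
        mates = [m for m in (r1, r2) if m is not None]
        for read in mates:
            if not read.sequence.startswith(damid_adaptor):
                continue
            trimmed = ReadRecord(read.id, read.sequence[head_trim:], read.quality[head_trim:])
            trimmed = _quality_trim_3p(trimmed, qual_cut)
            trimmed = _remove_3p_adaptor(trimmed, three_prime_adaptor)
            if len(trimmed) >= min_len:
                out.append(trimmed)
    return out


# ---------------------------------------------------------------------------
# Fragment counting
# ---------------------------------------------------------------------------

def count_fragments(
    alignments: pd.DataFrame,
    gatc_map: GATCMap,
    mode: str = "anchored",
    min_mapq: int = 10,
    column: str = "count",
) -> FragmentCounts:
    """Count MAPQ-filtered alignments per internal GATC fragment.

    ``alignments`` needs columns chrom, start, end, strand, mapq
    (0-based half-open reference coordinates). Alignments with
    MAPQ <= ``min_mapq`` are excluded (strict inequality retained).

    anchored mode (default): a forward-strand read counts for the
    fragment starting at its alignment start when that start is a motif
    start; a reverse-strand read whose alignment end equals a motif
    start + 4 counts for the fragment *ending* at that motif — the two
    mates of one DamID amplicon therefore increment the same fragment.
    containment mode assigns a read to the fragment containing its
    5'-most aligned base. Unassignable reads are tallied per column.
    """
    if gatc_map.n_fragments == 0:
        raise ValueError("GATC map has no internal fragments")
    if mode not in ("anchored", "containment"):
        raise ValueError(f"unknown counting mode {mode!r}")
    required = {"chrom", "start", "end", "strand", "mapq"}
    if not required <= set(alignments.columns):
        raise ValueError(f"alignment table must have columns {sorted(required)}")
    unknown = set(alignments["chrom"]) - set(gatc_map.motifs)
    if unknown:
        raise ValueError(f"alignments refer to unknown chromosomes: {sorted(unknown)}")

    frags = gatc_map.fragments
    counts = np.zeros(len(frags), dtype=np.int64)
    # fragment row lookup per chromosome, keyed by fragment start motif
    frag_index: dict[str, dict[int, int]] = {}
    for chrom, grp in frags.groupby("chrom", sort=False):
        frag_index[chrom] = dict(zip(grp["start"].astype(int), grp.index))

    passing = alignments[alignments["mapq"] > min_mapq]
    unassigned = 0
    for chrom, start, end, strand in zip(
        passing["chrom"], passing["start"], passing["end"], passing["strand"]
    ):
        motifs = gatc_map.motifs[chrom]
        lookup = frag_index.get(chrom, {})
        row = None
        if mode == "anchored":
            if strand == "+":
                m = int(start)
                if m in lookup:
                    row = lookup[m]
            else:
                m = int(end) - 4
                # fragment ending at motif m starts at the previous motif
                i = np.searchsorted(motifs, m)
                if i < motifs.size and motifs[i] == m and i > 0:
                    row = lookup.get(int(motifs[i - 1]))
        else:  # containment of the 5'-most aligned base
            pos = int(start) if strand == "+" else int(end) - 1
            i = np.searchsorted(motifs, pos, side="right") - 1
            if 0 <= i < motifs.size - 1:
                row = lookup.get(int(motifs[i]))
        if row is None:
            unassigned += 1
        else:
            counts[row] += 1

    if unassigned:
        warnings.warn(f"{unassigned} MAPQ-passing alignments were unassignable")
    cdf = pd.DataFrame({column: counts})
    return FragmentCounts(
        fragments=frags.copy(),
        counts=cdf,
        totals={column: int(counts.sum())},
        unassigned={column: unassigned},
    )


# ---------------------------------------------------------------------------
# File I/O helpers
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[ReadRecord]:
    """Read a (optionally gzipped) FASTQ file into ReadRecords."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        return [
            ReadRecord(rec.id, str(rec.seq).upper(),
                       np.asarray(rec.letter_annotations["phred_quality"], dtype=int))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads, path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quality)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def alignments_from_bam(path, min_mapq: int | None = None) -> pd.DataFrame:
    """Load mapped reads from BAM/SAM into the alignment-table layout."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows.append((
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
                aln.mapping_quality,
            ))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "mapq"])
    if min_mapq is not None:
        df = df[df["mapq"] > min_mapq].reset_index(drop=True)
    return df
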
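"""Differential LAD classification and gene-model annotation.

Comparing LAD sets between two genotypes (wild type and mutant) yields
three classes: cLADs shared by both, fLADs present only in the wild
type, and fiLADs that appear ectopically in the mutant. LADs are also
annotated against a gene model into genomic-feature combinations
(intron, CDS, 5UTR, 3UTR, inter_gene, no_CDS) for UpSet-style counting,
and the genes overlapping a LAD set can be exported for external GO
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lad_segmentation import LADSet

__all__ = [
    "GeneModel",
    "Gene",
    "Transcript",
    "ClassifiedLADs",
    "classify_lads",
    "annotate_lads",
    "genes_in_lads",
    "FEATURE_LABELS",
]

FEATURE_LABELS = ("intron", "CDS", "3UTR", "5UTR", "inter_gene", "no_CDS")


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons of this transcript."""
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex[:-1], ex[1:])
                if b_start > a_end]

    @property
    def coding(self) -> bool:
        return bool(self.cds)


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def coding(self) -> bool:
        return any(t.coding for t in self.transcripts)


@dataclass
class GeneModel:
    """Genes with per-transcript exon/CDS/UTR structure (0-based half-open)."""

    genes: list[Gene]

    def __post_init__(self):
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for genes in self._by_chrom.values():
            genes.sort(key=lambda g: g.start)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    @classmethod
    def from_gff(cls, path) -> "GeneModel":
        """Parse a GFF3 or GTF file (dialect auto-detected by gffutils)."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for grec in db.features_of_type("gene"):
            gene = Gene(
                id=grec.id, chrom=grec.seqid,
                start=grec.start - 1, end=grec.end, strand=grec.strand,
            )
            transcripts = list(db.children(grec, level=1))
            tx_like = [t for t in transcripts
                       if t.featuretype in ("mRNA", "transcript", "ncRNA", "tRNA", "rRNA")]
            if not tx_like:  # flat dialects: features directly under the gene
                tx_like = [grec]
            for trec in tx_like:
                tx = Transcript(id=trec.id, exons=[])
                for child in db.children(trec if trec is not grec else grec):
                    iv = (child.start - 1, child.end)
                    ft = child.featuretype.lower()
                    if ft == "exon":
                        tx.exons.append(iv)
                    elif ft == "cds":
                        tx.cds.append(iv)
                    elif ft in ("five_prime_utr", "5utr"):
                        tx.utr5.append(iv)
                    elif ft in ("three_prime_utr", "3utr"):
                        tx.utr3.append(iv)
                if tx.exons or tx.cds:
                    gene.transcripts.append(tx)
            genes.append(gene)
        return cls(genes)


# ---------------------------------------------------------------------------
# interval helpers (inputs are sorted, non-overlapping within a chromosome)
# ---------------------------------------------------------------------------

def _max_overlap(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Largest single-interval overlap of [start, end) with a sorted,
    non-overlapping interval set."""
    if starts.size == 0:
        return 0
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    if hi <= lo:
        return 0
    ov = np.minimum(end, ends[lo:hi]) - np.maximum(start, starts[lo:hi])
    return int(ov.max())


def _per_chrom_arrays(lads: LADSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in lads.intervals.groupby("chrom", sort=False):
        out[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


@dataclass
class ClassifiedLADs:
    """Result of a two-genotype LAD comparison.

    ``clad_counts`` reports the shared-LAD count under all three
    counting bases (wt, mutant, merged intersection); ``clad_count`` is
    the default WT basis.
    """

    clad_counts: dict[str, int]
    flad: pd.DataFrame  # WT LADs absent from the mutant
    filad: pd.DataFrame  # mutant LADs absent from the WT

    @property
    def clad_count(self) -> int:
        return self.clad_counts["wt"]

    def to_bed(self, path) -> None:
        flad = self.flad.assign(cls="fLAD")
        filad = self.filad.assign(cls="fiLAD")
        pd.concat([flad, filad]).to_csv(path, sep="\t", index=False, header=False)


def classify_lads(wt: LADSet, mut: LADSet, min_overlap: int = 1) -> ClassifiedLADs:
    """Classify LADs into cLAD / fLAD / fiLAD by cross-genotype overlap.

    A WT LAD overlapping no mutant LAD by >= ``min_overlap`` bp is an
    fLAD; a mutant LAD overlapping no WT LAD is an fiLAD; overlapping
    LADs are cLADs, counted on the WT basis by default with the mutant
    and merged-intersection bases also reported.
    """
    wt_arr = _per_chrom_arrays(wt)
    mut_arr = _per_chrom_arrays(mut)

    def split(source: LADSet, other: dict):
        shared, absent = [], []
        for _, row in source.intervals.iterrows():
            starts, ends = other.get(row["chrom"], (np.array([]), np.array([])))
            if _max_overlap(row["start"], row["end"], starts, ends) >= min_overlap:
                shared.append(row)
            else:
                absent.append(row)
        cols = ["chrom", "start", "end"]
        return (
            pd.DataFrame(shared, columns=cols).reset_index(drop=True),
            pd.DataFrame(absent, columns=cols).reset_index(drop=True),
        )

    wt_shared, flad = split(wt, mut_arr)
    mut_shared, filad = split(mut, wt_arr)

    # merged-intersection basis: connected components of the overlap graph,
    # counted as merged intervals of all pairwise intersections
    pieces = []
    for chrom, (ws, we) in wt_arr.items():
        ms, me = mut_arr.get(chrom, (np.array([]), np.array([])))
        for s, e in zip(ws, we):
            lo = np.searchsorted(me, s, side="right")
            hi = np.searchsorted(ms, e, side="left")
            for i in range(lo, hi):
                o_s, o_e = max(s, ms[i]), min(e, me[i])
                if o_e - o_s >= min_overlap:
                    pieces.append((chrom, o_s, o_e))
    merged = 0
    if pieces:
        df = pd.DataFrame(pieces, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start"]
        )
        last_chrom, last_end = None, -1
        for _, row in df.iterrows():
            if row["chrom"] != last_chrom or row["start"] > last_end:
                merged += 1
            last_chrom = row["chrom"]
            last_end = max(last_end if row["chrom"] == last_chrom else -1, row["end"])

    return ClassifiedLADs(
        clad_counts={
            "wt": len(wt_shared),
            "mutant": len(mut_shared),
            "merged_intersection": merged,
        },
        flad=flad,
        filad=filad,
    )


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------

def _overlaps_any(start: int, end: int, intervals) -> bool:
    return any(min(end, e) - max(start, s) > 0 for s, e in intervals)


def _lad_combination(chrom: str, start: int, end: int, genes: GeneModel) -> frozenset:
    feats = set()
    covered = []  # gene-body intervals overlapping the LAD
    for gene in genes.genes_on(chrom):
        if gene.start >= end or gene.end <= start:
            continue
        covered.append((gene.start, gene.end))
        if not gene.coding:
            feats.add("no_CDS")
        for tx in gene.transcripts:
            if _overlaps_any(start, end, tx.introns):
                feats.add("intron")
            if _overlaps_any(start, end, tx.cds):
                feats.add("CDS")
            if _overlaps_any(start, end, tx.utr5):
                feats.add("5UTR")
            if _overlaps_any(start, end, tx.utr3):
                feats.add("3UTR")
    # inter_gene: >= 1 bp of the LAD outside every gene body
    covered.sort()
    pos = start
    intergenic = False
    for s, e in covered:
        if s > pos:
            intergenic = True
            break
        pos = max(pos, e)
    if pos < end:
        intergenic = True
    if intergenic:
        feats.add("inter_gene")
    return frozenset(feats)


def annotate_lads(
    lads: LADSet, genes: GeneModel
) -> tuple[list[frozenset], pd.DataFrame]:
    """Annotate each LAD with the set of genomic features it touches.

    A LAD's combination contains intron/CDS/5UTR/3UTR when it overlaps
    >= 1 bp of that feature in any transcript, ``inter_gene`` when part
    of it lies outside all gene bodies, and ``no_CDS`` when it overlaps
    a gene without any CDS. Returns the per-LAD combinations and an
    UpSet-style table of counts per exact combination.
    """
    missing = set(lads.intervals["chrom"]) - genes.chromosomes
    if missing:
        raise ValueError(f"gene model lacks chromosomes: {sorted(missing)}")
    combos = [
        _lad_combination(row["chrom"], row["start"], row["end"], genes)
        for _, row in lads.intervals.iterrows()
    ]
    counts: dict[frozenset, int] = {}
    for c in combos:
        counts[c] = counts.get(c, 0) + 1
    table = pd.DataFrame(
        [
            {"combination": "+".join(sorted(c, key=FEATURE_LABELS.index)),
             "count": n}
            for c, n in sorted(counts.items(), key=lambda kv: -kv[1])
        ]
    )
    return combos, table


def genes_in_lads(lads: LADSet, genes: GeneModel, rule: str = "any_overlap") -> list[str]:
    """Unique, sorted ids of genes intersecting the LAD set.

    ``any_overlap`` (default) takes >= 1 bp of gene-body overlap;
    ``containment`` requires the gene body to lie fully inside one LAD.
    """
    if rule not in ("any_overlap", "containment"):
        raise ValueError(f"unknown rule {rule!r}")
    arr = _per_chrom_arrays(lads)
    hits = set()
    for gene in genes.genes:
        starts, ends = arr.get(gene.chrom, (np.array([]), np.array([])))
        if rule == "any_overlap":
            if _max_overlap(gene.start, gene.end, starts, ends) >= 1:
                hits.add(gene.id)
        else:
            lo = np.searchsorted(starts, gene.start, side="right") - 1
            if lo >= 0 and starts[lo] <= gene.start and ends[lo] >= gene.end:
                hits.add(gene.id)
    return sorted(hits)
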
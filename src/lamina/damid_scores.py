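"""DamID score tracks: replicate-averaged log2(Dam-Lam/Dam).

The DamID score of a genomic interval is log2 of the ratio of
lamin-fused-Dam methylation to free-Dam methylation, averaged across
biological replicates. Scores are computed either per 100-kb bin
(fragment counts summed into bins by fragment midpoint) or binless
(per GATC fragment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gatc_reads import FragmentCounts
from .group_stats import pearson

__all__ = ["NormalizationConfig", "ScoreTrack", "score_track", "replicate_correlation"]


@dataclass
class NormalizationConfig:
    """How raw fragment counts are normalized before the log-ratio.

    per_million scales each column to reads-per-million so scores are
    invariant to library depth. ``pseudocount`` (in scaled units, > 0)
    is added to both channels before the ratio. An interval is marked
    missing when, in any replicate, its raw counts are zero in both
    channels (``missing_if_both_zero``).
    """

    per_million: bool = True
    pseudocount: float = 1.0
    missing_if_both_zero: bool = True

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class ScoreTrack:
    """Genomic intervals with DamID scores (NaN marks missing)."""

    intervals: pd.DataFrame  # chrom, start, end
    score: np.ndarray
    resolution: str  # "bins" or "binless"
    replicate_scores: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if len(self.intervals) != self.score.size:
            raise ValueError("interval/score length mismatch")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.score)

    def to_frame(self) -> pd.DataFrame:
        df = self.intervals.copy()
        df["score"] = self.score
        return df

    def to_bedgraph(self, path) -> None:
        df = self.to_frame().dropna(subset=["score"])
        df.to_csv(path, sep="\t", index=False, header=False)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, resolution: str = "bins") -> "ScoreTrack":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["chrom", "start", "end"]], df["score"].to_numpy(), resolution)


def _bin_intervals(chrom_lengths: dict[str, int], width: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        edges = list(range(0, length, width)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _aggregate(values: np.ndarray, frag_bin: np.ndarray, n_bins: int) -> np.ndarray:
    out = np.zeros(n_bins)
    np.add.at(out, frag_bin, values)
    return out


def score_track(
    damlam: list[FragmentCounts],
    dam: list[FragmentCounts],
    mode: str = "bins",
    bin_width: int = 100_000,
    norm: NormalizationConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> ScoreTrack:
    """Compute the replicate-averaged log2(Dam-Lam/Dam) score track.

    ``damlam`` and ``dam`` are per-replicate single-column fragment count
    tables sharing one fragment set. Per replicate r the interval score is
    ``log2((damlam_r + c) / (dam_r + c))`` on per-million-scaled values
    (sum-then-ratio in bin mode); the final score is the arithmetic mean
    over replicates. Intervals failing the missing-data rule carry NaN.
    """
    norm = norm or NormalizationConfig()
    if len(damlam) != len(dam) or not damlam:
        raise ValueError("need >= 1 matched replicate pair")
    frags = damlam[0].fragments
    for fc in list(damlam) + list(dam):
        if not frags[["chrom", "start", "end"]].equals(fc.fragments[["chrom", "start", "end"]]):
            raise ValueError("fragment sets differ between count tables")
        if fc.counts.iloc[:, 0].sum() == 0:
            raise ValueError("a count column has zero total reads")

    if mode == "bins":
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(g["end"].max()) for c, g in frags.groupby("chrom", sort=False)
            }
        intervals = _bin_intervals(chrom_lengths, bin_width)
        # map each fragment (by midpoint) to its bin row
        bin_row = {}
        for i, (c, s) in enumerate(zip(intervals["chrom"], intervals["start"])):
            bin_row[(c, s // bin_width)] = i
        mid = ((frags["start"] + frags["end"]) // 2).to_numpy()
        frag_bin = np.array(
            [bin_row[(c, m // bin_width)] for c, m in zip(frags["chrom"], mid)],
            dtype=np.int64,
        )
        n = len(intervals)
    elif mode == "binless":
        intervals = frags[["chrom", "start", "end"]].reset_index(drop=True)
        frag_bin = np.arange(len(frags))
        n = len(frags)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rep_scores = {}
    missing = np.zeros(n, dtype=bool)
    c = norm.pseudocount
    for r, (fc_dl, fc_d) in enumerate(zip(damlam, dam), start=1):
        raw_dl = fc_dl.counts.iloc[:, 0].to_numpy(dtype=float)
        raw_d = fc_d.counts.iloc[:, 0].to_numpy(dtype=float)
        if norm.per_million:
            dl = raw_dl / raw_dl.sum() * 1e6
            d = raw_d / raw_d.sum() * 1e6
        else:
            dl, d = raw_dl, raw_d
        dl_binned = _aggregate(dl, frag_bin, n)
        d_binned = _aggregate(d, frag_bin, n)
        rep_scores[f"rep{r}"] = np.log2((dl_binned + c) / (d_binned + c))
        if norm.missing_if_both_zero:
            raw_dl_b = _aggregate(raw_dl, frag_bin, n)
            raw_d_b = _aggregate(raw_d, frag_bin, n)
            missing |= (raw_dl_b == 0) & (raw_d_b == 0)

    rep_df = pd.DataFrame(rep_scores)
    score = rep_df.mean(axis=1).to_numpy()
    score[missing] = np.nan
    rep_df[missing] = np.nan
    return ScoreTrack(intervals, score, resolution=mode, replicate_scores=rep_df)


def replicate_correlation(track_r1: ScoreTrack, track_r2: ScoreTrack) -> tuple[float, int]:
    """Pearson r between two single-replicate tracks over intervals
    non-missing in both; returns ``(r, n_used)``."""
    a, b = track_r1, track_r2
    if len(a) != len(b) or not a.intervals.equals(b.intervals):
        raise ValueError("tracks must share an identical interval set")
    ok = ~a.missing & ~b.missing
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared non-missing intervals")
    return pearson(a.score[ok], b.score[ok])
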
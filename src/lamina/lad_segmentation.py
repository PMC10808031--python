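"""LAD calling: two-state hidden Markov model with Student-t emissions.

Lamina-associated domains (LADs) appear in a DamID score track as long
runs of elevated log2(Dam-Lam/Dam). They are segmented here with a
two-state HMM whose emissions are Student-t distributed (robust to the
heavy tails of log-ratio tracks), fitted by Baum-Welch EM in log space.
Each chromosome is an independent observation sequence; missing bins
contribute emission likelihood 1 (they are marginalized out) so the
chain bridges them naturally. The final state path is decoded with
Viterbi and the state with the larger emission location is the LAD
state.

Also here: LAD summary statistics and the comparison of score
distributions between chromosome arms, peri-centromeres, and telomeres
derived from a UCSC-style cytoband table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .damid_scores import ScoreTrack
from .group_stats import TestResult, mann_whitney

__all__ = [
    "HMMModel",
    "LADSet",
    "RegionPartition",
    "DegenerateFitError",
    "fit_segment_hmm",
    "call_lads",
    "lad_stats",
    "region_comparison",
]


class DegenerateFitError(ValueError):
    """Raised when the observations cannot support a two-state fit."""


@dataclass
class HMMModel:
    """Fitted two-state Student-t HMM.

    State 1 is always the LAD state (larger emission location mu).
    """

    mu: np.ndarray  # (2,) emission locations, score units
    sigma: np.ndarray  # (2,) emission scales, > 0
    nu: float  # shared degrees of freedom
    transitions: np.ndarray  # (2, 2), rows sum to 1
    initial: np.ndarray  # (2,)
    log_likelihoods: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if np.any(self.sigma <= 0) or self.nu <= 0:
            raise ValueError("scales and degrees of freedom must be positive")
        if not np.allclose(self.transitions.sum(axis=1), 1, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    @property
    def lad_state(self) -> int:
        return int(np.argmax(self.mu))

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "nu": float(self.nu),
            "transitions": self.transitions.tolist(),
            "initial": self.initial.tolist(),
            "log_likelihood": self.log_likelihoods[-1] if self.log_likelihoods else None,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass
class LADSet:
    """Non-overlapping LAD intervals, sorted within each chromosome."""

    intervals: pd.DataFrame  # chrom, start, end
    genotype: str = ""
    resolution: str = ""

    def __post_init__(self):
        df = self.intervals.reset_index(drop=True)
        if len(df):
            df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
            if (df["end"] <= df["start"]).any():
                raise ValueError("empty or inverted LAD interval")
            for _, grp in df.groupby("chrom", sort=False):
                if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                    raise ValueError("overlapping LADs within one set")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    def to_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_bed(cls, path, **kw) -> "LADSet":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"])
        return cls(df, **kw)


# ---------------------------------------------------------------------------
# Baum-Welch EM with Student-t emissions
# ---------------------------------------------------------------------------

def _log_emissions(x: np.ndarray, missing: np.ndarray, model: HMMModel) -> np.ndarray:
    """(T, 2) log emission densities; missing rows are 0 (likelihood 1)."""
    logb = np.zeros((x.size, 2))
    obs = ~missing
    for s in range(2):
        logb[obs, s] = stats.t.logpdf(x[obs], model.nu, loc=model.mu[s],
                                      scale=model.sigma[s])
    return logb


def _forward_backward(logb: np.ndarray, log_a: np.ndarray, log_pi: np.ndarray):
    T = logb.shape[0]
    la = np.empty((T, 2))
    lb = np.empty((T, 2))
    la[0] = log_pi + logb[0]
    for t in range(1, T):
        la[t] = logb[t] + logsumexp(la[t - 1][:, None] + log_a, axis=0)
    lb[-1] = 0.0
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(log_a + (logb[t + 1] + lb[t + 1])[None, :], axis=1)
    loglik = logsumexp(la[-1])
    log_gamma = la + lb - loglik
    # xi[t, i, j] for transitions t -> t+1
    log_xi = (
        la[:-1, :, None] + log_a[None, :, :] + (logb[1:] + lb[1:])[:, None, :] - loglik
    )
    return np.exp(log_gamma), np.exp(log_xi), loglik


def _total_loglik(seqs, model: HMMModel) -> float:
    log_a = np.log(model.transitions)
    log_pi = np.log(model.initial)
    total = 0.0
    for x, missing in seqs:
        logb = _log_emissions(x, missing, model)
        T = x.size
        la = log_pi + logb[0]
        for t in range(1, T):
            la = logb[t] + logsumexp(la[:, None] + log_a, axis=0)
        total += logsumexp(la)
    return float(total)


def fit_segment_hmm(
    track: ScoreTrack,
    tolerance: float = 1e-6,
    max_iter: int = 200,
    nu: float | str = 5.0,
    self_transition: float = 0.9,
    min_obs_per_chrom: int = 10,
) -> tuple[HMMModel, np.ndarray]:
    """Fit the two-state Student-t HMM and decode the state path.

    Each chromosome of ``track`` is an independent sequence. ``nu`` is
    either a fixed degrees-of-freedom value (default 5) or ``"estimate"``
    to re-optimize it each iteration against the observed likelihood.
    Convergence is declared when the log-likelihood improves by less
    than ``tolerance``. Returns the model (states relabeled so state 1
    has the larger location) and the per-interval Viterbi path aligned
    to ``track.intervals`` (chromosomes skipped for being all-missing
    carry state 0).
    """
    x_all = track.score
    missing_all = track.missing
    obs = x_all[~missing_all]
    if obs.size == 0:
        raise DegenerateFitError("track has no non-missing observations")
    if np.ptp(obs) == 0:
        raise DegenerateFitError("constant observations: two-state fit is degenerate")

    # per-chromosome sequences
    seqs = []
    seq_slices = []
    chroms = track.intervals["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        x = x_all[idx]
        missing = missing_all[idx]
        n_obs = int((~missing).sum())
        if n_obs == 0:
            warnings.warn(f"{chrom}: all observations missing; skipped")
            continue
        if n_obs < min_obs_per_chrom:
            warnings.warn(
                f"{chrom}: only {n_obs} non-missing intervals (< {min_obs_per_chrom})"
            )
        seqs.append((x, missing))
        seq_slices.append(idx)

    # initialization: locations at the observed quartiles
    q25, q75 = np.percentile(obs, [25, 75])
    iqr = q75 - q25
    sigma0 = max(iqr / 2, 1e-3 * max(np.std(obs), 1e-6), 1e-6)
    estimate_nu = nu == "estimate"
    model = HMMModel(
        mu=np.array([q25, q75]),
        sigma=np.array([sigma0, sigma0]),
        nu=5.0 if estimate_nu else float(nu),
        transitions=np.array([
            [self_transition, 1 - self_transition],
            [1 - self_transition, self_transition],
        ]),
        initial=np.array([0.5, 0.5]),
    )

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        log_a = np.log(model.transitions)
        log_pi = np.log(model.initial)
        ll = 0.0
        pi_acc = np.zeros(2)
        xi_acc = np.zeros((2, 2))
        gamma_obs = []  # (gamma rows, x values) for observed positions
        for x, missing in seqs:
            logb = _log_emissions(x, missing, model)
            gamma, xi, seq_ll = _forward_backward(logb, log_a, log_pi)
            ll += seq_ll
            pi_acc += gamma[0]
            xi_acc += xi.sum(axis=0)
            ok = ~missing
            gamma_obs.append((gamma[ok], x[ok]))

        # EM on the observed likelihood must never decrease
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        model.log_likelihoods.append(float(ll))
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tolerance:
            model.converged = True
            model.n_iter = it
            break
        prev_ll = ll

        # M-step
        gam = np.concatenate([g for g, _ in gamma_obs], axis=0)
        xv = np.concatenate([v for _, v in gamma_obs])
        new_mu = np.empty(2)
        new_sigma = np.empty(2)
        for s in range(2):
            delta2 = ((xv - model.mu[s]) / model.sigma[s]) ** 2
            u = (model.nu + 1) / (model.nu + delta2)  # t scale-mixture weights
            w = gam[:, s] * u
            new_mu[s] = np.sum(w * xv) / np.sum(w)
            var = np.sum(w * (xv - new_mu[s]) ** 2) / np.sum(gam[:, s])
            new_sigma[s] = max(np.sqrt(var), 1e-6)
        model.mu = new_mu
        model.sigma = new_sigma
        trans = xi_acc / xi_acc.sum(axis=1, keepdims=True)
        model.transitions = np.clip(trans, 1e-12, None)
        model.transitions /= model.transitions.sum(axis=1, keepdims=True)
        model.initial = np.clip(pi_acc / pi_acc.sum(), 1e-12, None)
        model.initial /= model.initial.sum()

        if estimate_nu:
            def neg_ll(log_nu):
                trial = HMMModel(model.mu, model.sigma, float(np.exp(log_nu)),
                                 model.transitions, model.initial)
                return -_total_loglik(seqs, trial)

            res = minimize_scalar(neg_ll, bounds=(np.log(0.5), np.log(100.0)),
                                  method="bounded", options={"xatol": 1e-3})
            model.nu = float(np.exp(res.x))
    else:
        model.n_iter = max_iter

    # relabel so state 1 is the LAD state (larger mu)
    if model.mu[1] < model.mu[0]:
        order = [1, 0]
        model.mu = model.mu[order]
        model.sigma = model.sigma[order]
        model.transitions = model.transitions[np.ix_(order, order)]
        model.initial = model.initial[order]

    path = np.zeros(x_all.size, dtype=int)
    for idx, (x, missing) in zip(seq_slices, seqs):
        path[idx] = viterbi(x, missing, model)
    return model, path


def viterbi(x: np.ndarray, missing: np.ndarray, model: HMMModel) -> np.ndarray:
    """Most probable state path for one sequence (log-space Viterbi)."""
    logb = _log_emissions(np.asarray(x, dtype=float), np.asarray(missing, bool), model)
    log_a = np.log(model.transitions)
    T = logb.shape[0]
    delta = np.empty((T, 2))
    back = np.zeros((T, 2), dtype=int)
    delta[0] = np.log(model.initial) + logb[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_a
        back[t] = np.argmax(cand, axis=0)
        delta[t] = logb[t] + np.max(cand, axis=0)
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# LAD calling and summaries
# ---------------------------------------------------------------------------

def call_lads(
    path: np.ndarray,
    intervals: pd.DataFrame,
    missing: np.ndarray | None = None,
    bridge_missing: bool = True,
    lad_state: int = 1,
    genotype: str = "",
    resolution: str = "",
) -> LADSet:
    """Merge maximal runs of LAD-state intervals into LADs.

    Runs never merge across chromosomes. Missing intervals flanked by
    LAD-state intervals are bridged into the surrounding LAD when
    ``bridge_missing``; otherwise they split it.
    """
    path = np.asarray(path)
    if path.size != len(intervals):
        raise ValueError("state path not aligned to intervals")
    if missing is None:
        missing = np.zeros(path.size, dtype=bool)
    missing = np.asarray(missing, dtype=bool)

    rows = []
    chroms = intervals["chrom"].to_numpy()
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        # label per interval: True in-LAD, False out, None missing
        labels: list[bool | None] = [
            None if missing[i] else bool(path[i] == lad_state) for i in idx
        ]
        if bridge_missing:
            # missing runs with LAD on both sides become LAD, else non-LAD
            n = len(labels)
            i = 0
            while i < n:
                if labels[i] is None:
                    j = i
                    while j < n and labels[j] is None:
                        j += 1
                    left = labels[i - 1] if i > 0 else False
                    right = labels[j] if j < n else False
                    fill = bool(left and right)
                    for k in range(i, j):
                        labels[k] = fill
                    i = j
                else:
                    i += 1
        else:
            labels = [False if lab is None else lab for lab in labels]
        run_start = None
        for k, lab in enumerate(labels):
            if lab and run_start is None:
                run_start = k
            if run_start is not None and (not lab or k == len(labels) - 1):
                stop = k if not lab else k + 1
                rows.append((chrom, int(starts[idx[run_start]]), int(ends[idx[stop - 1]])))
                run_start = None
    return LADSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                  genotype=genotype, resolution=resolution)


def lad_stats(lads: LADSet) -> tuple[int, float | None]:
    """Return (LAD count, mean LAD length in kb; None when empty)."""
    n = len(lads)
    if n == 0:
        return 0, None
    lengths = (lads.intervals["end"] - lads.intervals["start"]).to_numpy()
    return n, float(lengths.mean() / 1000.0)


# ---------------------------------------------------------------------------
# Region comparison (arms vs centromeres vs telomeres)
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Disjoint labeled interval sets (arm / centromere / telomere)."""

    regions: dict[str, pd.DataFrame]  # label -> chrom,start,end

    @classmethod
    def from_cytoband(
        cls,
        path,
        centromere_stains: tuple[str, ...] = ("acen", "gvar"),
        telomere_bands: tuple[str, ...] = (),
        telomere_flank: int = 0,
    ) -> "RegionPartition":
        """Build a partition from a UCSC cytoBand.txt-dialect table.

        Bands whose Giemsa stain is in ``centromere_stains`` (or whose
        name is listed in ``telomere_bands``) are labeled; optionally
        the first/last ``telomere_flank`` bp of every chromosome are
        labeled telomere. Everything else is arm.
        """
        bands = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "band", "stain"],
        )
        cen = bands[bands["stain"].isin(centromere_stains)]
        tel_rows = []
        if telomere_bands:
            tel_rows.append(bands[bands["band"].isin(telomere_bands)])
        if telomere_flank > 0:
            for chrom, grp in bands.groupby("chrom"):
                lo, hi = grp["start"].min(), grp["end"].max()
                tel_rows.append(pd.DataFrame({
                    "chrom": [chrom, chrom],
                    "start": [lo, max(hi - telomere_flank, lo)],
                    "end": [min(lo + telomere_flank, hi), hi],
                }))
        tel = (
            pd.concat(tel_rows, ignore_index=True)[["chrom", "start", "end"]]
            if tel_rows else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        arm_rows = []
        cen_tel = pd.concat([cen[["chrom", "start", "end"]], tel], ignore_index=True)
        for chrom, grp in bands.groupby("chrom"):
            blocked = cen_tel[cen_tel["chrom"] == chrom].sort_values("start")
            pos = grp["start"].min()
            hi = grp["end"].max()
            for _, b in blocked.iterrows():
                if b["start"] > pos:
                    arm_rows.append((chrom, pos, b["start"]))
                pos = max(pos, b["end"])
            if pos < hi:
                arm_rows.append((chrom, pos, hi))
        return cls({
            "arm": pd.DataFrame(arm_rows, columns=["chrom", "start", "end"]),
            "centromere": cen[["chrom", "start", "end"]].reset_index(drop=True),
            "telomere": tel.reset_index(drop=True),
        })


def region_comparison(
    track: ScoreTrack, partition: RegionPartition
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Compare score distributions between region classes.

    Track intervals are assigned to the region containing their
    midpoint. Returns the per-region score arrays and a table of
    pairwise Wilcoxon rank-sum results (medians, U, p, exact flag).
    """
    mids = ((track.intervals["start"] + track.intervals["end"]) // 2).to_numpy()
    chroms = track.intervals["chrom"].to_numpy()
    scores: dict[str, list[float]] = {label: [] for label in partition.regions}
    for label, df in partition.regions.items():
        for _, reg in df.iterrows():
            sel = (
                (chroms == reg["chrom"]) & (mids >= reg["start"]) & (mids < reg["end"])
            )
            vals = track.score[sel]
            scores[label].extend(vals[~np.isnan(vals)].tolist())
    region_scores = {k: np.asarray(v) for k, v in scores.items()}
    for label, vals in region_scores.items():
        if vals.size == 0:
            raise ValueError(f"region {label!r} contains no non-missing interval")

    rows = []
    labels = list(region_scores)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res: TestResult = mann_whitney(region_scores[a], region_scores[b])
            rows.append({
                "region_a": a,
                "region_b": b,
                "median_a": float(np.median(region_scores[a])),
                "median_b": float(np.median(region_scores[b])),
                "U": res.statistic,
                "pvalue": res.pvalue,
                "exact": res.exact,
            })
    return region_scores, pd.DataFrame(rows)
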
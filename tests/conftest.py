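import itertools

import numpy as np
import pandas as pd
import pytest

from lamina import synthetic_data as sd


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_genome():
    """Two-motif toy chromosome: motifs at 2 and 10, one internal fragment."""
    return {"toy": "AAGATCTTTTGATCAA"}


@pytest.fixture(scope="session")
def small_damid():
    """Small planted-LAD DamID simulation shared across read/score tests."""
    chrom_lengths = {"chrA": 150_000, "chrB": 100_000}
    planted = pd.DataFrame({"chrom": ["chrA"], "start": [40_000], "end": [90_000]})
    damlam, dam, truth = sd.synth_damid_counts(
        chrom_lengths=chrom_lengths, library_size=4000, dispersion=0.2,
        planted_lads=planted, seed=5,
    )
    genome = sd.synth_genome_with_gatc(chrom_lengths, truth.gatc_map.motifs, seed=5)
    return damlam, dam, truth, genome


# ---------------------------------------------------------------------------
# independent oracles (never the implementation path)
# ---------------------------------------------------------------------------

def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n, nx = len(pooled), len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    us = []
    for combo in itertools.combinations(range(n), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def viterbi_bruteforce(x, missing, model):
    """Maximum-probability state path by enumerating all 2^T paths."""
    from scipy import stats as st

    x = np.asarray(x, float)
    missing = np.asarray(missing, bool)
    T = x.size
    logb = np.zeros((T, 2))
    for s in range(2):
        ok = ~missing
        logb[ok, s] = st.t.logpdf(x[ok], model.nu, loc=model.mu[s],
                                  scale=model.sigma[s])
    la = np.log(model.transitions)
    lpi = np.log(model.initial)
    best, best_lp = None, -np.inf
    for path in itertools.product([0, 1], repeat=T):
        lp = lpi[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += la[path[t - 1], path[t]] + logb[t, path[t]]
        if lp > best_lp:
            best_lp, best = lp, path
    return np.asarray(best)


def flood_fill_count(mask):
    """8-connected component count by BFS flood fill (pure python)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    H, W = mask.shape
    count = 0
    for i in range(H):
        for j in range(W):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if 0 <= na < H and 0 <= nb < W and mask[na, nb] and not seen[na, nb]:
                                seen[na, nb] = True
                                stack.append((na, nb))
    return count


def huang_fuzziness_oracle(hist, t, c):
    """Direct loop-based Huang-Wang fuzziness at threshold t."""
    import math

    total = sum(hist)
    s = 0.0
    for bounds in ((0, t + 1), (t + 1, 256)):
        w = sum(hist[g] for g in range(*bounds))
        if w == 0:
            continue
        mu = sum(g * hist[g] for g in range(*bounds)) / w
        for g in range(*bounds):
            if hist[g] == 0:
                continue
            m = 1.0 / (1.0 + abs(g - mu) / c)
            ent = -m * math.log(m) if m > 0 else 0.0
            if m < 1.0:
                ent -= (1.0 - m) * math.log(1.0 - m)
            s += hist[g] * ent
    return s / total


def huang_threshold_oracle(image8):
    """Exhaustive threshold search minimizing the Huang fuzziness;
    ties resolve to the plateau midpoint."""
    hist = np.bincount(np.asarray(image8).ravel(), minlength=256)
    nz = np.flatnonzero(hist)
    first, last = int(nz[0]), int(nz[-1])
    if first == last:
        return float(first)
    c = last - first
    vals = [huang_fuzziness_oracle(hist, t, c) for t in range(first, last)]
    lo = min(vals)
    winners = [i for i, v in enumerate(vals) if abs(v - lo) <= 1e-12]
    return float(first + (winners[0] + winners[-1]) / 2.0)
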
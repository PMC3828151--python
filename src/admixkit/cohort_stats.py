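"""Cohort-level statistics: sex-biased ancestry, assortative mating,
summed pairwise IBD, and frequency-based FST.

Input tables are plain pandas DataFrames.  An ancestry-proportion table has
one row per individual with columns ``sex`` plus ``auto_<ANC>`` and
``X_<ANC>`` proportions; a parent-pair table has one row per family with
``maternal_<ANC>`` / ``paternal_<ANC>`` columns (the layout produced by
:func:`admixkit.simulate.simulate_parent_pairs`).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import IBDSegmentSet

logger = logging.getLogger("admixkit")


def x_autosome_bias_test(table: pd.DataFrame, ancestry: str):
    """Wilcoxon signed-rank test of X vs autosomal ancestry in females.

    Pairs (X - autosome) differences for the chosen ancestry across female
    individuals; zero differences are dropped (Wilcoxon convention, count
    logged).  Exact null for n <= 25, normal approximation otherwise.  The
    test is two-sided and does not itself indicate direction; the median
    difference is returned alongside for that purpose.

    Returns (median difference, two-sided p, degenerate flag).
    """
    females = table[table["sex"].str.upper().isin(["F", "FEMALE"])]
    if len(females) < 6:
        raise ValueError("need >= 6 females with X and autosomal proportions")
    diffs = (females[f"X_{ancestry}"] - females[f"auto_{ancestry}"]).to_numpy()
    median = float(np.median(diffs))
    nonzero = diffs[diffs != 0]
    dropped = len(diffs) - len(nonzero)
    if dropped:
        logger.info("dropped %d zero differences in signed-rank test", dropped)
    if len(nonzero) == 0:
        return median, 1.0, True
    mode = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", mode=mode)
    return median, float(res.pvalue), False


def mating_correlation_test(pairs: pd.DataFrame, ancestry: str,
                            n_perm: int = 100_000,
                            within_groups: bool = False, seed=None):
    """Assortative-mating permutation test for one ancestry component.

    Pearson correlation between maternal and paternal proportions; the null
    re-pairs fathers with mothers by permutation (globally, or within
    population labels when ``within_groups``), and
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1) (one-sided for positive
    sorting).  Returns (r, p).
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 parent pairs")
    m = pairs[f"maternal_{ancestry}"].to_numpy(dtype=float)
    f = pairs[f"paternal_{ancestry}"].to_numpy(dtype=float)
    if np.std(m) == 0 or np.std(f) == 0:
        raise ValueError("zero variance in parental ancestry proportions")
    r_obs = float(np.corrcoef(m, f)[0, 1])

    rng = np.random.default_rng(seed)
    mc = (m - m.mean()) / m.std()
    fc = (f - f.mean()) / f.std()
    n = len(m)
    if within_groups:
        if "population" not in pairs.columns:
            raise ValueError("within_groups requires a 'population' column")
        groups = [np.flatnonzero((pairs["population"] == g).to_numpy())
                  for g in pairs["population"].unique()]
        count = 0
        for _ in range(n_perm):
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(len(g))]
            if np.mean(mc * fc[perm]) >= np.mean(mc * fc) - 1e-15:
                count += 1
        p = (1 + count) / (n_perm + 1)
    else:
        # vectorized global permutations in manageable chunks
        r_base = np.mean(mc * fc)
        count = 0
        chunk = max(1, min(n_perm, 2_000_000 // max(n, 1)))
        done = 0
        while done < n_perm:
            k = min(chunk, n_perm - done)
            idx = np.argsort(rng.random((k, n)), axis=1)
            r_perm = (mc[None, :] * fc[idx]).mean(axis=1)
            count += int(np.sum(r_perm >= r_base - 1e-15))
            done += k
        p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)


def summed_pairwise_ibd(segments: IBDSegmentSet, group_a, group_b=None,
                        min_len_Mb: float = 2.0):
    """Summed pairwise IBD statistic.

    Per qualifying pair of individuals, segment lengths >= ``min_len_Mb`` are
    summed.  The group statistic is the total over pairs normalized by the
    number of pairs: |A| x |B| between two disjoint groups, or C(|A|, 2)
    within a single group (``group_b`` omitted).

    Returns (per-pair sums as a Series indexed by (id1, id2), statistic).
    """
    group_a = set(map(str, group_a))
    within = group_b is None
    group_b = group_a if within else set(map(str, group_b))
    if not group_a or not group_b:
        raise ValueError("empty group")
    if not within and group_a & group_b:
        raise ValueError("groups must be disjoint for the between-group mode")

    df = segments.df
    df = df[df["length_Mb"] >= min_len_Mb]
    if within:
        pairs = {tuple(sorted(p)) for p in combinations(group_a, 2)}
        denom = len(group_a) * (len(group_a) - 1) / 2
    else:
        pairs = {tuple(sorted((a, b))) for a in group_a for b in group_b}
        denom = len(group_a) * len(group_b)
    if denom == 0:
        raise ValueError("no pairs to normalize by")
    sums = {p: 0.0 for p in pairs}
    for rec in df.itertuples(index=False):
        key = (rec.id1, rec.id2)
        if key in sums:
            sums[key] += rec.length_Mb
    series = pd.Series(sums).sort_index()
    return series, float(series.sum() / denom)


def frequency_fst(p1, p2) -> float:
    """Nei-style FST from two allele-frequency vectors (ratio of sums).

    FST = 1 - H_S / H_T with H_S the mean within-population heterozygosity
    (2 p1 q1 + 2 p2 q2)/2 and H_T the mean total heterozygosity 2 pbar qbar,
    pbar = (p1 + p2)/2, both averaged over loci before the ratio.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors must have equal length")
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    hs = np.mean((2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0)
    pbar = (p1 + p2) / 2.0
    ht = np.mean(2 * pbar * (1 - pbar))
    if ht == 0:
        raise ValueError("FST undefined: all loci identically fixed")
    return float(1.0 - hs / ht)
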
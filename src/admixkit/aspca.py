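"""Ancestry-specific PCA (ASPCA) on masked haplotypes.

Admixed haplotypes are masked to one continental ancestry: alleles are kept
only where the local-ancestry posterior calls that ancestry, every other site
becoming missing.  Masked admixed haplotypes and fully observed reference
haplotypes are then factorized jointly by a regularized alternating
least-squares subspace PCA that minimizes

    sum_observed (x_rc - mu_c - u_r . w_c)^2 + lambda (||U||^2 + ||W||^2)

over scores U and loadings W, with column means taken over observed entries.
On top of the scores the module provides the centroid-deviation bootstrap
test (Fisher-combined t statistics against resampled reference subgroups), a
rank test along a single axis, and size-stratified source assignment from
bivariate normal fits to reference clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .data_model_io import HaplotypePanel, TractSet
from .local_ancestry import WindowModel

logger = logging.getLogger("admixkit")


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

@dataclass
class MaskedHaplotypeMatrix:
    """Haplotype x variant matrix with NaN marking masked entries.

    ``groups`` labels each row ``reference:<pop>`` (fully observed) or
    ``admixed:<pop>``; reference rows must have no missing entries.
    """

    data: np.ndarray               # float, NaN = missing
    row_ids: list
    groups: list
    variant_ids: list
    target_ancestry: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        ref = np.array([g.startswith("reference:") for g in self.groups])
        if ref.any() and np.isnan(self.data[ref]).any():
            raise ValueError("reference rows must be fully observed")

    @property
    def observed_counts(self) -> np.ndarray:
        return (~np.isnan(self.data)).sum(axis=1)

    def is_reference(self) -> np.ndarray:
        return np.array([g.startswith("reference:") for g in self.groups])


def mask_by_ancestry(panel: HaplotypePanel, paths: list, model: WindowModel,
                     target: str, min_global_fraction: float = 0.0,
                     refs: HaplotypePanel | None = None) -> MaskedHaplotypeMatrix:
    """Mask admixed haplotypes down to their ``target``-ancestry segments.

    A haplotype keeps alleles only at variants inside windows whose
    thresholded posterior call equals ``target``; haplotypes whose
    genome-wide fraction of target-called windows falls below
    ``min_global_fraction`` are excluded (logged).  Reference haplotypes for
    the target ancestry's sub-populations may be appended fully observed.
    """
    if len(paths) != panel.n_haplotypes:
        raise ValueError("one AncestryPath required per haplotype row")
    rows, ids, groups = [], [], []
    n_var = len(panel.variants)
    for r, path in enumerate(paths):
        calls = np.asarray(path.calls, dtype=object)
        frac = float((calls == target).mean())
        if frac < min_global_fraction:
            logger.info("haplotype %s excluded: target fraction %.3f < %.3f",
                        panel.haplotype_ids[r], frac, min_global_fraction)
            continue
        keep = np.zeros(n_var, dtype=bool)
        for w, win in enumerate(model.windows):
            if calls[w] == target:
                keep[win.start:win.stop] = True
        row = panel.alleles[r].astype(float)
        row[~keep] = np.nan
        rows.append(row)
        sample, _ = panel.haplotype_ids[r]
        ids.append(panel.haplotype_ids[r])
        groups.append(f"admixed:{panel.labels.get(sample, 'NA')}")
    if not rows:
        raise ValueError("no haplotypes retained after masking")
    if refs is not None:
        for r, hap_id in enumerate(refs.haplotype_ids):
            rows.append(refs.alleles[r].astype(float))
            ids.append(hap_id)
            groups.append(f"reference:{refs.labels.get(hap_id[0], 'REF')}")
    variant_ids = list(panel.variants.df["id"])
    return MaskedHaplotypeMatrix(np.vstack(rows), ids, groups, variant_ids, target)


# ---------------------------------------------------------------------------
# ALS subspace PCA
# ---------------------------------------------------------------------------

@dataclass
class ASPCAModel:
    n_components: int
    col_means: np.ndarray
    scores: np.ndarray            # rows x k
    loadings: np.ndarray          # cols x k (orthonormal columns)
    lam: float
    tol: float
    n_iter: int
    converged: bool
    objective: float
    kept_columns: np.ndarray      # indices into the input columns
    objective_path: np.ndarray | None = None


def fit_aspca(masked: MaskedHaplotypeMatrix, n_components: int = 2,
              lam: float | None = None, tol: float = 1e-6,
              max_iter: int = 1000, seed=None,
              min_observed: int = 500) -> ASPCAModel:
    """Regularized alternating least squares on the observed entries.

    Reference and admixed rows are fitted jointly.  Columns observed in fewer
    than two rows are dropped (logged); rows with fewer than ``min_observed``
    observed sites raise.  Convergence: relative objective change < ``tol``.
    The final factors are orthonormalized (SVD of the fitted low-rank matrix)
    and sign-fixed so each component's largest-|loading| coordinate is
    positive.
    """
    X = masked.data
    obs = ~np.isnan(X)
    if np.any(obs.sum(axis=1) < min_observed):
        bad = np.flatnonzero(obs.sum(axis=1) < min_observed)
        raise ValueError(f"rows with < {min_observed} observed sites: "
                         f"{[masked.row_ids[i] for i in bad[:5]]}")
    col_ok = obs.sum(axis=0) >= 2
    if not col_ok.all():
        logger.info("dropping %d under-observed columns", (~col_ok).sum())
    kept = np.flatnonzero(col_ok)
    X = X[:, kept]
    obs = obs[:, kept]
    R, C = X.shape
    n_obs = int(obs.sum())
    if lam is None:
        lam = 1e-3 * n_obs / R

    O = obs.astype(float)
    col_means = np.nansum(np.where(obs, X, 0.0), axis=0) / obs.sum(axis=0)
    Xc = np.where(obs, X - col_means, 0.0)

    rng = np.random.default_rng(seed)
    k = n_components
    U = rng.normal(scale=1e-2, size=(R, k))
    W = rng.normal(scale=1e-2, size=(C, k))
    eye = np.eye(k)

    def objective(U, W):
        resid = Xc - O * (U @ W.T)
        return float(np.sum(resid**2) + lam * (np.sum(U**2) + np.sum(W**2)))

    prev = objective(U, W)
    path = [prev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # update U rows: (W_obs^T W_obs + lam I) u = W_obs^T x
        A = np.einsum("rc,ck,cl->rkl", O, W, W) + lam * eye
        rhs = Xc @ W
        U = np.linalg.solve(A, rhs[..., None])[..., 0]
        # update W columns
        A = np.einsum("rc,rk,rl->ckl", O, U, U) + lam * eye
        rhs = Xc.T @ U
        W = np.linalg.solve(A, rhs[..., None])[..., 0]
        cur = objective(U, W)
        path.append(cur)
        if prev - cur <= tol * max(abs(prev), 1e-12):
            converged = True
            prev = cur
            break
        prev = cur
    if not converged:
        logger.warning("ASPCA did not converge in %d iterations", max_iter)

    # orthonormalize via the fitted low-rank matrix
    Qu, Ru = np.linalg.qr(U)
    Qw, Rw = np.linalg.qr(W)
    uu, ss, vvt = np.linalg.svd(Ru @ Rw.T)
    scores = Qu @ uu * ss
    loadings = Qw @ vvt.T
    for j in range(k):
        imax = np.argmax(np.abs(loadings[:, j]))
        if loadings[imax, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return ASPCAModel(k, col_means, scores, loadings, float(lam), tol, it,
                      converged, prev, kept, np.asarray(path))


# ---------------------------------------------------------------------------
# Statistical tests on scores
# ---------------------------------------------------------------------------

def _welch_t_pvalue(a_mean, a_var, n_a, b_mean, b_var, n_b):
    """Two-sided Welch t-test p-value from summary statistics (vectorized)."""
    se2 = a_var / n_a + b_var / n_b
    if np.any(se2 <= 0):
        raise ValueError("degenerate variance in t-test")
    t = (a_mean - b_mean) / np.sqrt(se2)
    df = se2**2 / ((a_var / n_a) ** 2 / (n_a - 1) + (b_var / n_b) ** 2 / (n_b - 1))
    return 2.0 * stats.t.sf(np.abs(t), df)


def centroid_deviation_test(scores: np.ndarray, subgroup_a, subgroup_b,
                            admixed, n_boot: int = 10000, seed=None) -> float:
    """One-tailed bootstrap p for the admixed centroid's deviation.

    The observed statistic is Fisher's chi-squared combination,
    S = -2 (ln p1 + ln p2), of two-sample t-tests comparing the admixed group
    against the pooled reference subgroups on each of the first two axes.
    The null distribution resamples the two reference subgroups (e.g.
    Portuguese and Spanish) with replacement and computes the same statistic
    between them, modeling the intrinsic structure of the reference cluster;
    p = (1 + #{S_null >= S_obs}) / (n_boot + 1).
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    scores = np.asarray(scores, dtype=float)[:, :2]
    ia = np.asarray(subgroup_a, dtype=int)
    ib = np.asarray(subgroup_b, dtype=int)
    im = np.asarray(admixed, dtype=int)
    for idx in (ia, ib, im):
        if len(idx) < 3:
            raise ValueError("each group needs >= 3 rows")
    pooled = np.concatenate([ia, ib])

    def fisher_stat(xa, xb):
        pa = _welch_t_pvalue(xa.mean(axis=0), xa.var(axis=0, ddof=1), len(xa),
                             xb.mean(axis=0), xb.var(axis=0, ddof=1), len(xb))
        return -2.0 * np.sum(np.log(np.maximum(pa, 1e-300)))

    s_obs = fisher_stat(scores[im], scores[pooled])

    rng = np.random.default_rng(seed)
    xa = scores[ia]
    xb = scores[ib]
    boot_a = xa[rng.integers(0, len(ia), size=(n_boot, len(ia)))]
    boot_b = xb[rng.integers(0, len(ib), size=(n_boot, len(ib)))]
    ma, va = boot_a.mean(axis=1), boot_a.var(axis=1, ddof=1)
    mb, vb = boot_b.mean(axis=1), boot_b.var(axis=1, ddof=1)
    p_axes = _welch_t_pvalue(ma, va, len(ia), mb, vb, len(ib))
    s_null = -2.0 * np.sum(np.log(np.maximum(p_axes, 1e-300)), axis=1)
    return float((1 + np.sum(s_null >= s_obs)) / (n_boot + 1))


def axis_rank_test(axis_scores: np.ndarray, group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p comparing one score axis between groups.

    Exact null when m + n <= 20 and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(axis_scores, dtype=float)
    a, b = x[np.asarray(group_a, dtype=int)], x[np.asarray(group_b, dtype=int)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


# ---------------------------------------------------------------------------
# Tract length classes
# ---------------------------------------------------------------------------

def split_tracts_by_length(tracts: TractSet, cutoffs_cM=(5.0, 50.0)) -> dict:
    """Split tracts into length classes on a 50-cM cutoff.

    ``short`` is every tract < 50 cM; ``long`` every tract >= 50 cM (the
    boundary value is assigned to the long class); ``medium`` is the
    (5, 50) cM subset of short, the guard class against very short,
    potentially mis-assigned tracts.
    """
    lo, hi = cutoffs_cM
    lens = tracts.lengths_cM
    return {
        "short": TractSet(tracts.df[lens < hi].copy()),
        "medium": TractSet(tracts.df[(lens > lo) & (lens < hi)].copy()),
        "long": TractSet(tracts.df[lens >= hi].copy()),
    }


def sizeclass_sites(masked: MaskedHaplotypeMatrix, class_tracts: TractSet,
                    variants_cM: np.ndarray, variants_chrom: np.ndarray
                    ) -> MaskedHaplotypeMatrix:
    """Restrict each admixed row to sites inside its tracts of one class.

    Reference rows are restricted to the union of the class's sites across
    admixed haplotypes; admixed haplotypes with no tract in the class are
    omitted.
    """
    tdf = class_tracts.df
    data = masked.data.copy()
    is_ref = masked.is_reference()
    keep_rows = []
    union = np.zeros(data.shape[1], dtype=bool)
    for r in range(data.shape[0]):
        if is_ref[r]:
            keep_rows.append(r)
            continue
        hap_id = masked.row_ids[r]
        mine = tdf[[tuple(h) == tuple(hap_id) if isinstance(h, (tuple, list))
                    else h == hap_id for h in tdf["haplotype"]]]
        if not len(mine):
            continue
        inside = np.zeros(data.shape[1], dtype=bool)
        for rec in mine.itertuples(index=False):
            inside |= ((variants_chrom == rec.chrom)
                       & (variants_cM >= rec.start_cM)
                       & (variants_cM <= rec.end_cM))
        row_mask = ~inside
        data[r, row_mask] = np.nan
        union |= inside & ~np.isnan(data[r])
        if np.any(~np.isnan(data[r])):
            keep_rows.append(r)
    cols = np.flatnonzero(union)
    if not len(cols):
        raise ValueError("size class contains no observed sites")
    sub = data[np.ix_(keep_rows, cols)]
    return MaskedHaplotypeMatrix(
        sub, [masked.row_ids[r] for r in keep_rows],
        [masked.groups[r] for r in keep_rows],
        [masked.variant_ids[c] for c in cols], masked.target_ancestry)


# ---------------------------------------------------------------------------
# Bivariate-normal source assignment
# ---------------------------------------------------------------------------

def fit_cluster_gaussians(ref_scores_by_pop: dict) -> dict:
    """Per-population ML (mean, covariance) with eps*I shrinkage.

    Populations with fewer than 3 score rows are dropped with a warning.
    """
    out = {}
    for pop, S in ref_scores_by_pop.items():
        S = np.asarray(S, dtype=float)
        if len(S) < 3:
            logger.warning("population %s dropped: %d reference rows", pop, len(S))
            continue
        mu = S.mean(axis=0)
        C = np.cov(S, rowvar=False, bias=True)
        C = np.atleast_2d(C)
        eps = 1e-4 * max(np.trace(C) / C.shape[0], 1e-8)
        out[pop] = (mu, C + eps * np.eye(C.shape[0]))
    if not out:
        raise ValueError("no population with >= 3 reference rows")
    return out


@dataclass
class SourceAssignment:
    per_individual: pd.DataFrame   # columns: row_id, class, population, probability
    summary: pd.DataFrame          # class, population, mean_prob, sem, rescaled_mean


def assignment_summary(scores_by_class: dict, gaussians: dict) -> SourceAssignment:
    """Posterior source-population probabilities per haplotype and class.

    ``scores_by_class`` maps class name -> (row ids, (n, 2) score array).
    Per row, P(pop) = phi(x; mu_pop, Sigma_pop) / sum_pops phi (computed in
    log space); per population the mean probability over rows and its SEM are
    reported, with means rescaled to sum to one over populations.
    """
    pops = list(gaussians)
    dists = {p: stats.multivariate_normal(mean=m, cov=c)
             for p, (m, c) in gaussians.items()}
    rows, summaries = [], []
    for cls, (ids, S) in scores_by_class.items():
        S = np.asarray(S, dtype=float)
        if len(S) == 0:
            continue
        logphi = np.column_stack([dists[p].logpdf(S) for p in pops])
        logphi = np.atleast_2d(logphi)
        P = np.exp(logphi - logsumexp(logphi, axis=1, keepdims=True))
        for i, rid in enumerate(ids):
            for j, p in enumerate(pops):
                rows.append((rid, cls, p, P[i, j]))
        means = P.mean(axis=0)
        sems = P.std(axis=0, ddof=1) / np.sqrt(len(S)) if len(S) > 1 \
            else np.zeros(len(pops))
        rescaled = means / means.sum()
        for j, p in enumerate(pops):
            summaries.append((cls, p, means[j], sems[j], rescaled[j]))
    per_ind = pd.DataFrame(rows, columns=["row_id", "class", "population",
                                          "probability"])
    summary = pd.DataFrame(summaries, columns=["class", "population",
                                               "mean_prob", "sem",
                                               "rescaled_mean"])
    return SourceAssignment(per_ind, summary)
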
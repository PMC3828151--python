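"""PCA-window HMM local ancestry inference.

The approach: reference haplotypes from K putative ancestral populations are
pooled, and PCA is computed in non-overlapping windows (default 70 SNPs).
Within each window the score distribution of each reference population is
summarized by a bivariate normal; given an admixed haplotype, its window
scores yield per-window log-likelihoods of belonging to each panel.  A hidden
Markov chain over windows with transition matrix

    P(i -> j) = exp(-g d) delta_ij + (1 - exp(-g d)) q_j

(d = inter-window distance in Morgans, g = effective generations since
admixture, q = genome-wide ancestry proportions) is then decoded with the
forward-backward algorithm (posterior calls, thresholded at 0.9) and with
Viterbi (tract-length analyses).  Within-continental deconvolution re-runs
the same machinery on disjoint HMMs restricted to previously called blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import TRACT_COLUMNS, HaplotypePanel, TractSet, VariantTable

logger = logging.getLogger("admixkit")

DEFAULT_WINDOW_SIZE = 70
DEFAULT_N_PCS = 2
DEFAULT_POSTERIOR_THRESHOLD = 0.9
UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Window model
# ---------------------------------------------------------------------------

@dataclass
class Window:
    chrom: object
    start: int          # variant index, inclusive
    stop: int           # variant index, exclusive
    midpoint_cM: float
    first_cM: float
    last_cM: float
    first_bp: int
    last_bp: int


@dataclass
class WindowModel:
    """Per-window PCA loadings and per-population score Gaussians."""

    windows: list
    populations: list
    col_means: list          # per window: (W,) observed column means
    loadings: list           # per window: (n_pcs, W)
    means: np.ndarray        # (n_windows, K, n_pcs)
    covs: np.ndarray         # (n_windows, K, n_pcs, n_pcs)
    informative: np.ndarray  # (n_windows,) bool
    n_pcs: int = DEFAULT_N_PCS
    _cov_inv: np.ndarray | None = field(default=None, repr=False)
    _cov_logdet: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def chrom_window_indices(self, chrom) -> np.ndarray:
        return np.array([i for i, w in enumerate(self.windows) if w.chrom == chrom])

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(w.chrom for w in self.windows))

    def _precompute(self):
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.covs)
            self._cov_logdet = np.linalg.slogdet(self.covs)[1]
        return self._cov_inv, self._cov_logdet


def _make_windows(variants: VariantTable, window_size: int) -> list:
    """Tile each chromosome with windows of ``window_size`` variants.

    A trailing remainder shorter than a full window is merged into the final
    full window rather than kept as an unstable tiny window.
    """
    windows = []
    vdf = variants.df
    for chrom in variants.chroms:
        idx = variants.chrom_slice(chrom)
        n = len(idx)
        if n < window_size:
            raise ValueError(f"chromosome {chrom!r} has {n} variants "
                             f"(< window size {window_size})")
        starts = list(range(0, n - window_size + 1, window_size))
        spans = [(s, s + window_size) for s in starts]
        if spans[-1][1] < n:
            spans[-1] = (spans[-1][0], n)
        for s, e in spans:
            sel = idx[s:e]
            cm = vdf["pos_cM"].to_numpy()[sel]
            bp = vdf["pos_bp"].to_numpy()[sel]
            windows.append(Window(chrom, int(sel[0]), int(sel[-1]) + 1,
                                  float(0.5 * (cm[0] + cm[-1])),
                                  float(cm[0]), float(cm[-1]),
                                  int(bp[0]), int(bp[-1])))
    return windows


def fit_window_model(refs: HaplotypePanel,
                     window_size: int = DEFAULT_WINDOW_SIZE,
                     n_pcs: int = DEFAULT_N_PCS) -> WindowModel:
    """Fit per-window pooled PCA plus per-population score Gaussians.

    PCA is computed on the pooled, column-centered reference alleles of each
    window; each population's scores are then summarized by a mean vector and
    a shrunken covariance (Sigma + eps I, eps = 1e-4 x mean diagonal).
    Windows that are monomorphic across all references are flagged
    uninformative and contribute a flat likelihood.
    """
    hap_labels = np.array(refs.haplotype_labels(), dtype=object)
    populations = sorted(set(hap_labels))
    if len(populations) < 2:
        raise ValueError("need reference haplotypes from >= 2 populations")
    for pop in populations:
        if (hap_labels == pop).sum() < 3:
            raise ValueError(f"population {pop!r} has < 3 reference haplotypes")

    windows = _make_windows(refs.variants, window_size)
    K = len(populations)
    col_means, loadings = [], []
    means = np.zeros((len(windows), K, n_pcs))
    covs = np.zeros((len(windows), K, n_pcs, n_pcs))
    informative = np.ones(len(windows), dtype=bool)

    for w, win in enumerate(windows):
        X = refs.alleles[:, win.start:win.stop].astype(float)
        mu = X.mean(axis=0)
        Xc = X - mu
        col_means.append(mu)
        if not np.any(Xc):
            informative[w] = False
            loadings.append(np.zeros((n_pcs, X.shape[1])))
            covs[w] = np.eye(n_pcs)
            continue
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        V = vt[:n_pcs]
        if V.shape[0] < n_pcs:  # degenerate rank
            V = np.vstack([V, np.zeros((n_pcs - V.shape[0], X.shape[1]))])
        loadings.append(V)
        scores = Xc @ V.T
        for k, pop in enumerate(populations):
            S = scores[hap_labels == pop]
            means[w, k] = S.mean(axis=0)
            C = np.cov(S, rowvar=False)
            C = np.atleast_2d(C)
            eps = 1e-4 * max(np.trace(C) / n_pcs, 1e-8)
            covs[w, k] = C + eps * np.eye(n_pcs)
    return WindowModel(windows, populations, col_means, loadings,
                       means, covs, informative, n_pcs)


def window_loglikelihoods(hap: np.ndarray, model: WindowModel) -> np.ndarray:
    """(n_windows x K) log bivariate-normal density of the haplotype's scores.

    Uninformative windows contribute equal (zero) log-densities.
    """
    cov_inv, cov_logdet = model._precompute()
    K = len(model.populations)
    out = np.zeros((model.n_windows, K))
    const = model.n_pcs * np.log(2 * np.pi)
    for w, win in enumerate(model.windows):
        if not model.informative[w]:
            continue
        x = hap[win.start:win.stop].astype(float) - model.col_means[w]
        s = model.loadings[w] @ x
        d = s[None, :] - model.means[w]                    # (K, n_pcs)
        maha = np.einsum("ki,kij,kj->k", d, cov_inv[w], d)
        out[w] = -0.5 * (const + cov_logdet[w] + maha)
    return out


# ---------------------------------------------------------------------------
# HMM machinery
# ---------------------------------------------------------------------------

def transition_matrix(g: float, d_morgans: float, q: np.ndarray) -> np.ndarray:
    """Bryc-style pulse transition: P = e^{-gd} I + (1 - e^{-gd}) 1 q^T."""
    if g <= 0:
        raise ValueError("g must be positive")
    if d_morgans < 0:
        raise ValueError("distance must be non-negative")
    q = np.asarray(q, dtype=float)
    stay = np.exp(-g * d_morgans)
    return stay * np.eye(len(q)) + (1.0 - stay) * q[None, :]


@dataclass
class PosteriorMatrix:
    """Forward-backward posteriors for one haplotype (windows x K)."""

    probs: np.ndarray
    ancestries: list
    g: float
    loglik: float

    def thresholded_calls(self, threshold: float = DEFAULT_POSTERIOR_THRESHOLD):
        idx = self.probs.argmax(axis=1)
        best = self.probs.max(axis=1)
        labels = np.array(self.ancestries, dtype=object)[idx]
        labels[best < threshold] = UNKNOWN
        return labels


@dataclass
class AncestryPath:
    """Viterbi labels plus thresholded posterior calls per window."""

    viterbi: np.ndarray        # (n_windows,) ancestry labels
    calls: np.ndarray          # (n_windows,) labels or "unknown"
    ancestries: list
    g: float


def _forward(loglik: np.ndarray, g: float, q: np.ndarray,
             distances: np.ndarray):
    """Scaled forward pass; returns (alphas, scaling logs, total loglik)."""
    n, K = loglik.shape
    if np.any(np.all(np.isneginf(loglik), axis=1)):
        raise ValueError("window with all -inf log-likelihoods")
    # per-row max subtracted for numerical stability
    shift = loglik.max(axis=1, keepdims=True)
    emis = np.exp(loglik - shift)
    alpha = np.empty((n, K))
    logs = np.empty(n)
    a = q * emis[0]
    c = a.sum()
    alpha[0] = a / c
    logs[0] = np.log(c) + shift[0, 0]
    for t in range(1, n):
        stay = np.exp(-g * distances[t - 1])
        pred = stay * alpha[t - 1] + (1 - stay) * q * alpha[t - 1].sum()
        a = pred * emis[t]
        c = a.sum()
        if c <= 0:
            raise ValueError("forward pass underflow: impossible window")
        alpha[t] = a / c
        logs[t] = np.log(c) + shift[t, 0]
    return alpha, logs, float(logs.sum())


def posterior_decode(loglik: np.ndarray, g: float, q: np.ndarray,
                     distances: np.ndarray, ancestries=None) -> PosteriorMatrix:
    """Forward-backward posteriors over windows; rows sum to one."""
    q = np.asarray(q, dtype=float)
    n, K = loglik.shape
    alpha, _, total = _forward(loglik, g, q, np.asarray(distances, dtype=float))
    shift = loglik.max(axis=1, keepdims=True)
    emis = np.exp(loglik - shift)
    beta = np.empty((n, K))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        stay = np.exp(-g * distances[t])
        w = emis[t + 1] * beta[t + 1]
        # (P w)_i = stay * w_i + (1-stay) * sum_j q_j w_j
        beta[t] = stay * w + (1 - stay) * float(q @ w)
        beta[t] /= beta[t].max()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    if ancestries is None:
        ancestries = list(range(K))
    return PosteriorMatrix(post, list(ancestries), g, total)


def viterbi_decode(loglik: np.ndarray, g: float, q: np.ndarray,
                   distances: np.ndarray, ancestries=None,
                   threshold: float = DEFAULT_POSTERIOR_THRESHOLD) -> AncestryPath:
    """Maximum a posteriori state path (ties broken toward lowest index)."""
    q = np.asarray(q, dtype=float)
    n, K = loglik.shape
    if ancestries is None:
        ancestries = list(range(K))
    with np.errstate(divide="ignore"):
        logq = np.log(q)
    delta = logq + loglik[0]
    back = np.zeros((n, K), dtype=int)
    for t in range(1, n):
        stay = np.exp(-g * distances[t - 1])
        with np.errstate(divide="ignore"):
            logP = np.log(stay * np.eye(K) + (1 - stay) * q[None, :])
        cand = delta[:, None] + logP          # (from, to)
        back[t] = cand.argmax(axis=0)         # argmax -> lowest index on ties
        delta = cand.max(axis=0) + loglik[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    labels = np.array(ancestries, dtype=object)[path]
    post = posterior_decode(loglik, g, q, distances, ancestries)
    return AncestryPath(labels, post.thresholded_calls(threshold),
                        list(ancestries), g)


def optimize_generations(logliks: list, q: np.ndarray, distances_list: list,
                         bounds=(1.0, 500.0), tol: float = 1e-3) -> float:
    """Maximize the summed forward log-likelihood over g.

    One g is fitted for a whole population of haplotypes (``logliks`` and
    ``distances_list`` are parallel lists).  The search is golden-section on
    log g; a warning is logged when the optimum sits at a bound.
    """
    if not logliks:
        raise ValueError("no haplotypes supplied")
    q = np.asarray(q, dtype=float)

    def negll(logg):
        g = np.exp(logg)
        return -sum(_forward(ll, g, q, d)[2]
                    for ll, d in zip(logliks, distances_list))

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    phi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = negll(c), negll(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = negll(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = negll(d)
    logg = 0.5 * (a + b)
    g = float(np.exp(logg))
    if min(negll(lo), negll(hi)) <= min(fc, fd) or \
            logg - lo < 2 * tol or hi - logg < 2 * tol:
        logger.warning("g optimum at or near search bound (g=%.3g)", g)
    return g


# ---------------------------------------------------------------------------
# Whole-panel painting
# ---------------------------------------------------------------------------

def window_distances(model: WindowModel, win_idx: np.ndarray) -> np.ndarray:
    """Inter-window distances in Morgans (midpoint cM / 100)."""
    mids = np.array([model.windows[i].midpoint_cM for i in win_idx])
    return np.diff(mids) / 100.0


def paint_haplotype(hap: np.ndarray, model: WindowModel, g: float,
                    q: np.ndarray,
                    threshold: float = DEFAULT_POSTERIOR_THRESHOLD):
    """Decode one haplotype chromosome by chromosome.

    Returns (AncestryPath over all windows, list of per-chrom
    PosteriorMatrix) with chromosomes treated as independent chains.
    """
    loglik = window_loglikelihoods(hap, model)
    vit = np.empty(model.n_windows, dtype=object)
    calls = np.empty(model.n_windows, dtype=object)
    posteriors = []
    for chrom in model.chroms:
        wi = model.chrom_window_indices(chrom)
        d = window_distances(model, wi)
        path = viterbi_decode(loglik[wi], g, q, d, model.populations, threshold)
        vit[wi] = path.viterbi
        calls[wi] = path.calls
        posteriors.append(posterior_decode(loglik[wi], g, q, d, model.populations))
    return AncestryPath(vit, calls, model.populations, g), posteriors


def calls_to_tracts(path: AncestryPath, model: WindowModel,
                    use: str = "viterbi") -> TractSet:
    """Merge consecutive same-label windows into continuous tracts.

    Boundaries between tracts are the midpoints between the flanking windows'
    edge variants (cM and bp); chromosome ends use the terminal window edges.
    ``use`` selects the Viterbi labels (tract-length analyses) or the
    thresholded posterior calls.
    """
    labels = path.viterbi if use == "viterbi" else path.calls
    rows = []
    for chrom in model.chroms:
        wi = model.chrom_window_indices(chrom)
        labs = labels[wi]
        wins = [model.windows[i] for i in wi]
        runs = []
        start = 0
        for i in range(1, len(labs)):
            if labs[i] != labs[i - 1]:
                runs.append((start, i - 1))
                start = i
        runs.append((start, len(labs) - 1))
        whole = len(runs) == 1
        for a, b in runs:
            s_cm = wins[a].first_cM if a == 0 else \
                0.5 * (wins[a - 1].last_cM + wins[a].first_cM)
            e_cm = wins[b].last_cM if b == len(wins) - 1 else \
                0.5 * (wins[b].last_cM + wins[b + 1].first_cM)
            s_bp = wins[a].first_bp if a == 0 else \
                (wins[a - 1].last_bp + wins[a].first_bp) // 2
            e_bp = wins[b].last_bp if b == len(wins) - 1 else \
                (wins[b].last_bp + wins[b + 1].first_bp) // 2
            rows.append((path_hap_id(path), chrom, float(s_cm), float(e_cm),
                         int(s_bp), max(int(e_bp), int(s_bp) + 1),
                         labs[a], whole))
    return TractSet(pd.DataFrame(rows, columns=TRACT_COLUMNS))


def path_hap_id(path: AncestryPath):
    return getattr(path, "haplotype_id", "hap")


def paint_panel(panel: HaplotypePanel, model: WindowModel, g: float,
                q: np.ndarray, threshold: float = DEFAULT_POSTERIOR_THRESHOLD):
    """Paint every haplotype in a panel; returns (paths, tracts).

    ``paths`` is a list of AncestryPath (one per haplotype row, annotated
    with its haplotype id); ``tracts`` is the pooled Viterbi TractSet.
    """
    paths = []
    frames = []
    for r, hap_id in enumerate(panel.haplotype_ids):
        path, _ = paint_haplotype(panel.alleles[r], model, g, q, threshold)
        path.haplotype_id = hap_id
        paths.append(path)
        frames.append(calls_to_tracts(path, model).df)
    tracts = TractSet(pd.concat(frames, ignore_index=True))
    return paths, tracts


# ---------------------------------------------------------------------------
# Within-continental deconvolution (disjoint HMMs)
# ---------------------------------------------------------------------------

@dataclass
class BlockResult:
    chrom: object
    start: int
    stop: int
    size_cM: float
    posterior: PosteriorMatrix


def deconvolve_within_tracts(hap: np.ndarray, blocks: list,
                             sub_refs: HaplotypePanel,
                             g: float, q=None,
                             window_size: int = DEFAULT_WINDOW_SIZE,
                             n_pcs: int = DEFAULT_N_PCS) -> list:
    """Fit disjoint HMMs over each previously-called continental block.

    ``blocks`` is a list of (chrom, start_idx, stop_idx) variant index spans
    (e.g. African tracts from a prior continental run).  For each block a
    window model is fitted to the sub-continental references restricted to
    the block's variants and decoded independently: no information flows
    across block boundaries.  Blocks shorter than one window are skipped with
    a warning.
    """
    results = []
    vdf = sub_refs.variants.df
    for chrom, start, stop in blocks:
        if stop - start < window_size:
            logger.warning("block %s:%d-%d shorter than one window; skipped",
                           chrom, start, stop)
            continue
        sub_variants = VariantTable(vdf.iloc[start:stop].reset_index(drop=True))
        sub_panel = HaplotypePanel(sub_refs.alleles[:, start:stop],
                                   sub_refs.samples, sub_variants, sub_refs.labels)
        model = fit_window_model(sub_panel, window_size, n_pcs)
        K = len(model.populations)
        qk = np.full(K, 1.0 / K) if q is None else np.asarray(q, dtype=float)
        loglik = window_loglikelihoods(hap[start:stop], model)
        wi = np.arange(model.n_windows)
        d = window_distances(model, wi)
        post = posterior_decode(loglik, g, qk, d, model.populations)
        cm = vdf["pos_cM"].to_numpy()
        size_cM = float(cm[stop - 1] - cm[start])
        results.append(BlockResult(chrom, start, stop, size_cM, post))
    return results


def subancestry_fraction_by_block_size(block_results: list, target: str,
                                       size_bins,
                                       confidence: float = DEFAULT_POSTERIOR_THRESHOLD
                                       ) -> pd.DataFrame:
    """Fraction of confidently-called windows assigned to ``target``, by
    block-size bin.

    Only windows whose maximum posterior reaches ``confidence`` are counted.
    Bins with no confidently-called windows report a missing fraction.
    """
    edges = np.asarray(size_bins, dtype=float)
    n_bins = len(edges) - 1
    counts_target = np.zeros(n_bins)
    counts_total = np.zeros(n_bins)
    for blk in block_results:
        b = int(np.searchsorted(edges, blk.size_cM, side="right")) - 1
        if b < 0 or b >= n_bins:
            continue
        calls = blk.posterior.thresholded_calls(confidence)
        confident = calls != UNKNOWN
        counts_total[b] += confident.sum()
        counts_target[b] += (calls == target).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts_total > 0, counts_target / counts_total, np.nan)
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "n_windows": counts_total.astype(int),
        "fraction": frac,
    })


# ---------------------------------------------------------------------------
# Truth comparison helper
# ---------------------------------------------------------------------------

def tracts_to_site_labels(tracts: TractSet, variants: VariantTable,
                          haplotype_id) -> np.ndarray:
    """Per-variant ancestry labels implied by a haplotype's tracts."""
    out = np.empty(len(variants), dtype=object)
    sub = tracts.df[tracts.df["haplotype"] == haplotype_id] \
        if not isinstance(haplotype_id, tuple) else \
        tracts.df[[h == haplotype_id for h in tracts.df["haplotype"]]]
    vdf = variants.df
    for chrom, block in sub.groupby("chrom", sort=False):
        idx = variants.chrom_slice(chrom)
        cm = vdf["pos_cM"].to_numpy()[idx]
        edges = block["start_cM"].to_numpy()
        order = np.argsort(edges)
        edges = edges[order]
        labs = block["ancestry"].to_numpy()[order]
        j = np.clip(np.searchsorted(edges, cm, side="right") - 1, 0, len(labs) - 1)
        out[idx] = labs[j]
    return out
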
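"""Tract-length demographic inference for pulse-migration models.

Ancestry along an admixed chromosome is modeled as a Markov process over an
extended state space (ancestry, arrival time): a migrant lineage that entered
``t`` generations ago has experienced ``t - 1`` meioses, so it recombines at
rate ``t - 1`` per Morgan; at a recombination that happened ``u`` generations
ago the lineage switches to a random chromosome of the generation-``u``
population, whose (ancestry, arrival time) distribution follows from the
migration history.  Tract lengths are therefore phase-type distributed, with
chromosome-end censoring producing a finite whole-chromosome mass.

Observed tracts are tallied into 50 equally spaced length bins per ancestry
plus one whole-chromosome bin; bin counts are treated as independent Poisson
draws around the model's expected counts, giving a likelihood that is
maximized over (times, founding proportion, pulse magnitudes) and compared
across model structures by BIC = -2 log L + k log n (n = number of bins x
ancestries, 153 for three ancestries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .data_model_io import TRACT_COLUMNS, HUMAN_AUTOSOME_MORGANS, TractSet
from .simulate import MigrationModel

DEFAULT_N_BINS = 50

#: The three migration histories compared in the study: founding by European
#: and Native American chromosomes followed by an African pulse, optionally
#: with one additional pulse of European or African migrants.
STANDARD_STRUCTURES = ("EUR,NAT+AFR", "EUR,NAT+AFR+EUR", "EUR,NAT+AFR+AFR")


def default_chrom_lengths() -> dict:
    return {f"chr{i + 1}": L for i, L in enumerate(HUMAN_AUTOSOME_MORGANS)}


# ---------------------------------------------------------------------------
# Histogram
# ---------------------------------------------------------------------------

@dataclass
class TractHistogram:
    """Per-ancestry tract counts in equal-width bins plus a whole-chromosome
    bin (the last entry of each count vector)."""

    bin_edges: np.ndarray          # (n_bins + 1,) edges over [0, L_max], Morgans
    counts: dict                   # ancestry -> (n_bins + 1,) counts
    n_haplotypes: int
    chrom_lengths: dict            # chrom -> Morgans

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def ancestries(self) -> list:
        return list(self.counts)

    @property
    def n_datapoints(self) -> int:
        """Number of Poisson data points: ancestries x (bins + whole-chrom)."""
        return len(self.counts) * (self.n_bins + 1)


def bin_tract_lengths(tracts: TractSet, chrom_lengths: dict,
                      n_haplotypes: int | None = None,
                      n_bins: int = DEFAULT_N_BINS,
                      ancestries=None) -> TractHistogram:
    """Tally tract lengths (Morgans) into ``n_bins`` equal bins on
    [0, longest chromosome] plus one whole-chromosome bin.

    Whole-chromosome tracts go to the extra bin regardless of length; the
    last regular bin is right-closed.  A non-whole tract longer than the
    longest chromosome is inconsistent input and raises.
    """
    L_max = float(max(chrom_lengths.values()))
    width = L_max / n_bins
    edges = np.linspace(0.0, L_max, n_bins + 1)
    if ancestries is None:
        ancestries = sorted(set(tracts.df["ancestry"]))
    if n_haplotypes is None:
        n_haplotypes = len(set(map(tuple_or_id, tracts.df["haplotype"])))
    counts = {a: np.zeros(n_bins + 1, dtype=int) for a in ancestries}
    lens = tracts.lengths_morgans
    whole = tracts.df["is_whole_chromosome"].to_numpy(dtype=bool)
    ancs = tracts.df["ancestry"].to_numpy()
    for l, w, a in zip(lens, whole, ancs):
        if a not in counts:
            continue
        if w:
            counts[a][n_bins] += 1
        else:
            if l > L_max * (1 + 1e-9):
                raise ValueError("non-whole-chromosome tract longer than the "
                                 "longest chromosome")
            b = min(int(l / width), n_bins - 1)
            counts[a][b] += 1
    return TractHistogram(edges, counts, n_haplotypes, dict(chrom_lengths))


def tuple_or_id(h):
    return tuple(h) if isinstance(h, (list, tuple)) else h


# ---------------------------------------------------------------------------
# Markov engine
# ---------------------------------------------------------------------------

def _migration_events(model: MigrationModel):
    """(time, {source: magnitude}) sorted by descending time; founding last
    replaces everything (magnitude sums to 1)."""
    events = {float(model.T1): dict(model.founding_proportions)}
    for t, src, m in model.pulses:
        ev = events.setdefault(float(t), {})
        ev[src] = ev.get(src, 0.0) + float(m)
    return sorted(events.items(), key=lambda kv: -kv[0])


def markov_states(model: MigrationModel):
    """Extended states (ancestry, arrival time) with stationary weights.

    The stationary weight of state (s, t) is the present-day genome fraction
    inherited from that migration wave: m(t, s) x prod over later events v<t
    of (1 - M(v)).  States with zero weight are dropped.
    """
    events = _migration_events(model)
    times = np.array([t for t, _ in events])           # descending
    totals = np.array([sum(ev.values()) for _, ev in events])
    states, pi = [], []
    for idx, (t, ev) in enumerate(events):
        # survival through all events strictly later (smaller time)
        surv = np.prod(1.0 - totals[idx + 1:]) if idx + 1 < len(events) else 1.0
        for src, m in ev.items():
            w = m * surv
            if w > 0:
                states.append((src, t))
                pi.append(w)
    return states, np.asarray(pi, dtype=float), times, totals


def _H_function(times, totals):
    """Piecewise-linear H(x) = integral_1^x du / C(u), C(u) = prod_{v<u}(1-M_v)."""
    # breakpoints ascending: 1, then event times ascending
    order = np.argsort(times)
    ts = times[order]
    Ms = totals[order]
    # C on (1, ts[0]] is 1; after passing event ts[k], divide by (1 - M_k)
    def H(x):
        total, lo, C = 0.0, 1.0, 1.0
        for t, M in zip(ts, Ms):
            hi = min(x, t)
            if hi > lo:
                total += (hi - lo) / C
            if x <= t:
                return total
            lo = t
            C *= (1.0 - M)
        if x > lo and C > 0:
            total += (x - lo) / C
        return total
    return H


def markov_generator(model: MigrationModel):
    """States, stationary distribution and generator Q of the ancestry chain.

    Off-diagonal rates: Q_ij = pi_j H(min(t_i, t_j)); total recombination
    rate of state i is t_i - 1 per Morgan, with self-jumps removed from the
    diagonal, so rows sum to zero and pi Q = 0 exactly.
    """
    states, pi, times, totals = markov_states(model)
    H = _H_function(times, totals)
    n = len(states)
    t_arr = np.array([t for _, t in states])
    Hmin = np.array([[H(min(t_arr[i], t_arr[j])) for j in range(n)]
                     for i in range(n)])
    Q = Hmin * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return states, pi, Q


def _int_exp(lam, l1, l2):
    """integral_{l1}^{l2} e^{lam l} dl, stable near lam = 0 (elementwise)."""
    lam = np.asarray(lam)
    small = np.abs(lam * (l2 - l1)) < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(small,
                       np.exp(lam * l1) * (l2 - l1),
                       (np.exp(lam * l2) - np.exp(lam * l1)) / np.where(lam == 0, 1, lam))
    return out


def _int_l_exp(lam, l1, l2):
    """integral_{l1}^{l2} l e^{lam l} dl (elementwise, stable near 0)."""
    lam = np.asarray(lam)
    small = np.abs(lam) < 1e-8
    safe = np.where(small, 1.0, lam)
    with np.errstate(invalid="ignore", divide="ignore"):
        prim2 = np.exp(safe * l2) * (safe * l2 - 1) / safe**2
        prim1 = np.exp(safe * l1) * (safe * l1 - 1) / safe**2
        exact = prim2 - prim1
    approx = (l2**2 - l1**2) / 2.0 * np.exp(lam * (l1 + l2) / 2.0)
    return np.where(small, approx, exact)


def expected_histogram(model: MigrationModel, chrom_lengths: dict,
                       n_haplotypes: int, n_bins: int = DEFAULT_N_BINS,
                       ancestries=None) -> TractHistogram:
    """Expected per-bin tract counts under the Markov chromosome-painting
    model, for ``n_haplotypes`` haploid genomes over the given chromosomes.

    For each ancestry the within-ancestry sub-generator gives phase-type
    tract-length densities; expected counts integrate those densities over
    each bin, separately for interior tracts, tracts abutting a chromosome
    end, and whole-chromosome tracts (the extra bin).
    """
    states, pi, Q = markov_generator(model)
    if ancestries is None:
        ancestries = list(dict.fromkeys(model.ancestries))
    L_max = float(max(chrom_lengths.values()))
    edges = np.linspace(0.0, L_max, n_bins + 1)
    counts = {}
    for anc in ancestries:
        sel = np.array([s == anc for s, _ in states])
        exp_counts = np.zeros(n_bins + 1)
        if not sel.any():
            counts[anc] = exp_counts
            continue
        T = Q[np.ix_(sel, sel)]
        tvec = -T.sum(axis=1)                     # exit rates
        pia = pi[sel]
        b = (pi[~sel] @ Q[np.ix_(~sel, sel)]) if (~sel).any() else np.zeros(sel.sum())
        ones = np.ones(sel.sum())
        lam, P = np.linalg.eig(T)
        Pinv = np.linalg.inv(P)
        c_at = (pia @ P) * (Pinv @ tvec)               # start at 0, exit inside
        c_bt = (b @ P) * (Pinv @ tvec)                 # interior-interior
        c_c1 = (b @ P) * (Pinv @ ones)                 # right-censored
        c_w = (pia @ P) * (Pinv @ ones)                # whole chromosome
        Ls = np.array(list(chrom_lengths.values()))    # (C,)
        l1 = np.minimum(edges[:-1][None, :], Ls[:, None])   # (C, B)
        l2 = np.minimum(edges[1:][None, :], Ls[:, None])
        good = l2 > l1
        lam3 = lam[:, None, None]                      # (E, 1, 1)
        I1 = _int_exp(lam3, l1[None], l2[None])        # (E, C, B)
        I2 = _int_l_exp(lam3, l1[None], l2[None])
        fa = np.einsum("e,ecb->cb", c_at, I1)
        fb = np.einsum("e,ecb->cb", c_bt, Ls[None, :, None] * I1 - I2)
        fc = np.einsum("e,ecb->cb", c_c1, I1)
        exp_counts[:-1] = np.where(good, (fa + fb + fc).real, 0.0).sum(axis=0)
        exp_counts[-1] = float(np.real(np.exp(lam[None, :] * Ls[:, None]) @ c_w).sum())
        counts[anc] = np.maximum(exp_counts * n_haplotypes, 0.0)
    return TractHistogram(edges, counts, n_haplotypes, dict(chrom_lengths))


def stationary_ancestry_proportions(model: MigrationModel) -> dict:
    """Length-weighted present-day ancestry proportions of the Markov chain
    (equal to the migration-recursion present-day proportions)."""
    states, pi, _, _ = markov_states(model)
    out = {}
    for (s, _), w in zip(states, pi):
        out[s] = out.get(s, 0.0) + w
    return out


# ---------------------------------------------------------------------------
# Monte Carlo painting (independent oracle / data generator)
# ---------------------------------------------------------------------------

def sample_tracts_mc(model: MigrationModel, chrom_lengths: dict,
                     n_haplotypes: int, seed,
                     bp_per_morgan: float = 1e8) -> TractSet:
    """Simulate ancestry paintings directly from the Markov jump process.

    For each haplotype and chromosome the extended-state chain is simulated
    along the genetic map: dwell distances are exponential with the state's
    recombination rate (t - 1 per Morgan); at an event the recombination
    generation u is uniform on (1, t) and the new state is drawn from the
    generation-u population composition.  This is an independent sampling
    route used both as a test oracle for :func:`expected_histogram` and as a
    generator of model-true tract data.
    """
    states, pi, times, totals = markov_states(model)
    rng = np.random.default_rng(seed)
    t_arr = np.array([t for _, t in states])
    anc_of = np.array([s for s, _ in states], dtype=object)
    n = len(states)
    p0 = pi / pi.sum()
    rows = []
    hap_ids = np.array([(f"MC{h // 2}", h % 2) for h in range(n_haplotypes)],
                       dtype=object)
    for chrom, L in chrom_lengths.items():
        # advance all haplotype chains along this chromosome in lock-step
        state = rng.choice(n, size=n_haplotypes, p=p0)
        x = np.zeros(n_haplotypes)
        seg_start = np.zeros(n_haplotypes)
        active = np.ones(n_haplotypes, dtype=bool)
        while active.any():
            ai = np.flatnonzero(active)
            si = state[ai]
            rate = t_arr[si] - 1.0
            step = np.where(rate > 0,
                            rng.exponential(1.0, size=len(ai)) / np.maximum(rate, 1e-300),
                            np.inf)
            done = x[ai] + step >= L
            for idx in ai[done]:
                rows.append((tuple(hap_ids[idx]), chrom,
                             seg_start[idx], L, anc_of[state[idx]]))
            active[ai[done]] = False
            live = ai[~done]
            if not len(live):
                break
            x[live] += step[~done]
            # recombination generation u ~ U(1, t_i); new state from the
            # generation-u population composition (arrivals at or before u)
            u = 1.0 + rng.random(len(live)) * (t_arr[state[live]] - 1.0)
            w = np.where(t_arr[None, :] >= u[:, None], pi[None, :], 0.0)
            w /= w.sum(axis=1, keepdims=True)
            new = (w.cumsum(axis=1) > rng.random(len(live))[:, None]).argmax(axis=1)
            switched = anc_of[new] != anc_of[state[live]]
            for idx, nx in zip(live[switched], x[live[switched]]):
                rows.append((tuple(hap_ids[idx]), chrom, seg_start[idx],
                             nx, anc_of[state[idx]]))
                seg_start[idx] = nx
            state[live] = new
    df = pd.DataFrame(rows, columns=["haplotype", "chrom", "start_M", "end_M",
                                     "ancestry"])
    chrom_L = df["chrom"].map(chrom_lengths)
    df["is_whole_chromosome"] = (df["start_M"] == 0.0) & (df["end_M"] >= chrom_L)
    df["start_cM"] = df["start_M"] * 100.0
    df["end_cM"] = df["end_M"] * 100.0
    df["start_bp"] = (df["start_M"] * bp_per_morgan).round().astype(np.int64) + 1
    df["end_bp"] = (df["end_M"] * bp_per_morgan).round().astype(np.int64) + 1
    return TractSet(df[TRACT_COLUMNS])


# ---------------------------------------------------------------------------
# Likelihood, fitting, selection
# ---------------------------------------------------------------------------

def poisson_loglikelihood(observed: np.ndarray, expected: np.ndarray,
                          floor: float = 1e-9) -> float:
    """Sum over bins of o ln(e) - e - ln(o!), with expected floored."""
    o = np.asarray(observed, dtype=float).ravel()
    e = np.maximum(np.asarray(expected, dtype=float).ravel(), floor)
    if np.any(o < 0):
        raise ValueError("negative observed counts")
    return float(np.sum(o * np.log(e) - e - gammaln(o + 1.0)))


def _histogram_loglik(obs: TractHistogram, exp: TractHistogram) -> float:
    return sum(poisson_loglikelihood(obs.counts[a], exp.counts[a])
               for a in obs.ancestries)


@dataclass
class FitResult:
    structure: str
    model: MigrationModel
    params: dict
    loglik: float
    k: int
    n: int
    converged: bool = True

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    def rounded_times(self) -> dict:
        out = {"T1": int(round(self.model.T1))}
        for idx, (t, src, m) in enumerate(self.model.pulses):
            out[f"T{idx + 2}_{src}"] = int(round(t))
        return out


def parse_structure(tag: str):
    """'EUR,NAT+AFR+EUR' -> founding sources ['EUR','NAT'], pulses ['AFR','EUR']."""
    parts = tag.split("+")
    founders = parts[0].split(",")
    if len(founders) != 2 or len(parts) < 2:
        raise ValueError(f"unsupported structure tag {tag!r}")
    return founders, parts[1:]


def _theta_to_model(theta, founders, pulse_sources) -> MigrationModel:
    T1 = 2.0 + np.exp(theta[0])
    f0 = float(expit(theta[1]))
    pulses = []
    for p in range(len(pulse_sources)):
        t = 1.0 + (T1 - 1.0) * float(expit(theta[2 + 2 * p]))
        m = float(expit(theta[3 + 2 * p]))
        t = min(max(t, 1.0 + 1e-6), T1 - 1e-6)
        pulses.append((t, pulse_sources[p], m))
    return MigrationModel(T1, {founders[0]: f0, founders[1]: 1.0 - f0},
                          pulses, N=0)


def _model_to_theta(model: MigrationModel, founders, pulse_sources) -> np.ndarray:
    """Inverse of the fitting transform (for warm starts)."""
    theta = [np.log(max(model.T1 - 2.0, 1e-6)),
             logit(np.clip(model.founding_proportions[founders[0]], 1e-9, 1 - 1e-9))]
    for (t, _src, m) in model.pulses:
        frac = np.clip((t - 1.0) / (model.T1 - 1.0), 1e-9, 1 - 1e-9)
        theta += [logit(frac), logit(np.clip(m, 1e-9, 1 - 1e-9))]
    return np.asarray(theta)


def fit_migration_model(hist: TractHistogram, structure: str,
                        n_restarts: int = 10, seed=None,
                        maxiter: int = 400, warm_start: FitResult | None = None
                        ) -> FitResult:
    """Maximum-likelihood fit of one migration structure by Nelder-Mead.

    Times are optimized on a log scale (T1 = 2 + e^x, pulse times mapped into
    (1, T1) by a logistic), proportions/magnitudes through a logit; the best
    of ``n_restarts`` random starts is kept.  ``warm_start`` may carry the
    fit of a nested (fewer-pulse) structure: its solution, padded with a
    near-zero extra pulse, is added as one more start, which preserves the
    LL ordering of nested models.  k counts all free parameters (4 for the
    simple structure, 6 with an extra pulse).
    """
    founders, pulse_sources = parse_structure(structure)
    rng = np.random.default_rng(seed)
    chrom_lengths = hist.chrom_lengths
    ancestries = hist.ancestries
    k = 2 + 2 * len(pulse_sources)

    def negll(theta):
        try:
            model = _theta_to_model(theta, founders, pulse_sources)
            exp = expected_histogram(model, chrom_lengths, hist.n_haplotypes,
                                     hist.n_bins, ancestries)
            return -_histogram_loglik(hist, exp)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    starts = [np.concatenate([
        [np.log(rng.uniform(5, 25))],       # T1 - 2
        [logit(rng.uniform(0.2, 0.8))],     # founding proportion
    ] + [[logit(rng.uniform(0.2, 0.8)), logit(rng.uniform(0.05, 0.5))]
         for _ in pulse_sources]) for _ in range(n_restarts)]
    if warm_start is not None:
        base = warm_start.model
        pad = list(base.pulses) + [(1.0 + 0.5 * (base.T1 - 1.0), src, 1e-6)
                                   for src in pulse_sources[len(base.pulses):]]
        starts.append(_model_to_theta(
            MigrationModel(base.T1, base.founding_proportions, pad, N=0),
            founders, pulse_sources))
    best = None
    any_ok = False
    for theta0 in starts:
        res = minimize(negll, theta0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6})
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            continue
        any_ok = True
        if best is None or res.fun < best.fun:
            best = res
    if not any_ok:
        raise RuntimeError(f"all restarts failed for structure {structure!r}")
    model = _theta_to_model(best.x, founders, pulse_sources)
    params = {"T1": model.T1, f"founding_{founders[0]}":
              model.founding_proportions[founders[0]]}
    for i, (t, src, m) in enumerate(model.pulses):
        params[f"pulse{i + 1}_time"] = t
        params[f"pulse{i + 1}_source"] = src
        params[f"pulse{i + 1}_magnitude"] = m
    return FitResult(structure, model, params, -float(best.fun), k,
                     hist.n_datapoints, bool(best.success))


def bic_select(fits: list, n: int | None = None) -> FitResult:
    """Pick the fit with the lowest BIC (-2 log L + k log n); ties go to the
    model with fewer parameters."""
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to select among")
    scored = []
    for f in fits:
        nn = n if n is not None else f.n
        scored.append((-2.0 * f.loglik + f.k * np.log(nn), f.k, f))
    scored.sort(key=lambda t: (round(t[0], 12), t[1]))
    return scored[0][2]


def model_final_proportions(fit: FitResult) -> dict:
    """Present-day ancestry proportions implied by the fitted migration
    history (pulses applied in time order to the founding proportions)."""
    model = fit.model
    ancs = model.ancestries
    a = np.array([model.founding_proportions.get(x, 0.0) for x in ancs])
    for t, src, m in sorted(model.pulses, key=lambda p: -p[0]):
        e = np.array([1.0 if x == src else 0.0 for x in ancs])
        a = (1.0 - m) * a + m * e
    return dict(zip(ancs, a))
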
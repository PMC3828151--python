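"""Forward simulation of admixed cohorts with ground-truth ancestry paintings.

The generator emulates the study design the rest of the toolkit assumes:

* K continental founder populations whose allele frequencies are known, with
  optional sub-populations diverged under the Balding–Nichols model;
* an admixed population created by a founding event (two or more sources at
  generation ``T1``) followed by later migration pulses, evolving forward in
  time with Poisson recombination and random mating;
* the true ancestry painting of every sampled haplotype, recorded as a
  :class:`~admixkit.data_model_io.TractSet`;
* parent-pair ancestry tables with tunable assortative-mating correlation and
  a sex-biased shift of X-chromosome proportions.

Simulation is forward (Wright–Fisher, diploid size ``N``) rather than
coalescent because the downstream tract-length machinery assumes Markov
paintings; crossovers are placed uniformly per Morgan without interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import (
    TRACT_COLUMNS,
    HaplotypePanel,
    TractSet,
    VariantTable,
    uniform_variant_table,
)

ANCESTRIES3 = ("EUR", "NAT", "AFR")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class AncestralPopulationModel:
    """Allele frequencies of the source populations.

    ``base_freqs`` maps ancestry label -> frequency vector in (0,1), one per
    variant.  ``subpops`` optionally maps a continental label to
    ``{sub_label: F}`` divergence values; per-sub-population frequencies are
    drawn on demand with :func:`draw_subpopulation_frequencies`.
    """

    base_freqs: dict
    subpops: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.base_freqs.items():
            p = np.asarray(p, dtype=float)
            if np.any(p <= 0) or np.any(p >= 1):
                raise ValueError(f"frequencies for {name} must lie in (0,1)")
            self.base_freqs[name] = p
        for cont, subs in self.subpops.items():
            for sub, F in subs.items():
                if not 0 < F < 1:
                    raise ValueError(f"divergence F for {cont}/{sub} must be in (0,1)")

    @property
    def ancestries(self) -> list:
        return list(self.base_freqs)

    @property
    def n_variants(self) -> int:
        return len(next(iter(self.base_freqs.values())))


@dataclass
class MigrationModel:
    """Founding event plus ordered later migration pulses.

    ``T1`` is the founding time in generations before present (integer >= 2);
    ``founding_proportions`` maps ancestry -> proportion (sums to one);
    ``pulses`` is a list of ``(time, source, magnitude)`` with
    ``1 < time < T1`` and magnitude in [0, 1].  ``N`` is the diploid size
    used by the forward simulator.
    """

    T1: int
    founding_proportions: dict
    pulses: list = field(default_factory=list)
    N: int = 5000

    def __post_init__(self) -> None:
        if self.T1 < 2:
            raise ValueError("founding time T1 must be >= 2 generations")
        total = sum(self.founding_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError("founding proportions must sum to 1")
        for t, src, m in self.pulses:
            if not 1 < t < self.T1:
                raise ValueError("pulse times must lie strictly between 1 and T1")
            if not 0 <= m <= 1:
                raise ValueError("pulse magnitude must be in [0, 1]")

    @property
    def ancestries(self) -> list:
        names = list(self.founding_proportions)
        for _, src, _ in self.pulses:
            if src not in names:
                names.append(src)
        return names


@dataclass
class SimulatedCohort:
    panel: HaplotypePanel
    truth: TractSet
    model: MigrationModel
    seed: int


# ---------------------------------------------------------------------------
# Frequencies and reference panels
# ---------------------------------------------------------------------------

def draw_subpopulation_frequencies(p, F: float, seed) -> np.ndarray:
    """Balding–Nichols draw of sub-population frequencies.

    Each locus frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is ``p``
    and variance ``F p (1-p)``.
    """
    p = np.asarray(p, dtype=float)
    if not 0 < F < 1:
        raise ValueError("divergence F must lie in (0,1)")
    rng = np.random.default_rng(seed)
    scale = (1.0 - F) / F
    out = rng.beta(p * scale, (1.0 - p) * scale)
    # keep frequencies usable as Bernoulli parameters downstream
    return np.clip(out, 1e-9, 1 - 1e-9)


def simulate_reference_haplotypes(freqs, n_haplotypes: int, seed,
                                  variants: VariantTable | None = None,
                                  population: str = "REF") -> HaplotypePanel:
    """Draw ``n_haplotypes`` independent Bernoulli(freq) haplotypes."""
    freqs = np.asarray(freqs, dtype=float)
    if n_haplotypes <= 0:
        raise ValueError("n_haplotypes must be positive")
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (two per sample)")
    rng = np.random.default_rng(seed)
    alleles = (rng.random((n_haplotypes, len(freqs))) < freqs).astype(np.int8)
    if variants is None:
        variants = uniform_variant_table(len(freqs), {"chr1": max(1.0, len(freqs) / 100)})
    samples = [f"{population}{i}" for i in range(n_haplotypes // 2)]
    return HaplotypePanel(alleles, samples, variants,
                          {s: population for s in samples})


# ---------------------------------------------------------------------------
# Ancestry trajectory
# ---------------------------------------------------------------------------

def ancestry_trajectory(model: MigrationModel) -> pd.DataFrame:
    """Expected ancestry proportions at each generation from T1 to present.

    At the founding generation the proportions are the founding values; a
    pulse of magnitude m from source s at generation t rescales the existing
    pool: a(t) = (1 - m) a(t+1) + m e_s.  Rows are indexed by generation
    (T1 down to 1); present-day proportions are the row at generation 1.
    """
    ancs = model.ancestries
    a = np.array([model.founding_proportions.get(k, 0.0) for k in ancs])
    pulses_at = {}
    for t, src, m in model.pulses:
        pulses_at.setdefault(int(t), []).append((src, m))
    rows = {model.T1: a.copy()}
    for t in range(model.T1 - 1, 0, -1):
        for src, m in pulses_at.get(t, []):
            e = np.array([1.0 if k == src else 0.0 for k in ancs])
            a = (1.0 - m) * a + m * e
        rows[t] = a.copy()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ancs)
    return df.sort_index(ascending=False)


def present_day_proportions(model: MigrationModel) -> dict:
    traj = ancestry_trajectory(model)
    return dict(traj.loc[1])


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _recombine(bounds_a, labs_a, bounds_b, labs_b, cross, first, L):
    """Splice two parental paintings at crossover positions (cM).

    Returns merged (bounds, labels) alternating source starting from parent
    ``first`` (0 = a, 1 = b).
    """
    pts = np.concatenate(([0.0], cross, [L]))
    out_bounds = [0.0]
    out_labs = []
    src = first
    for i in range(len(pts) - 1):
        lo, hi = pts[i], pts[i + 1]
        bounds, labs = (bounds_a, labs_a) if src == 0 else (bounds_b, labs_b)
        j0 = np.searchsorted(bounds, lo, side="right") - 1
        j1 = np.searchsorted(bounds, hi, side="left")
        for j in range(j0, j1):
            seg_hi = min(float(bounds[j + 1]), hi)
            lab = labs[j]
            if out_labs and out_labs[-1] == lab:
                out_bounds[-1] = seg_hi
            else:
                out_bounds.append(seg_hi)
                out_labs.append(lab)
        src = 1 - src
    return np.asarray(out_bounds), out_labs


def simulate_admixed_cohort(model: MigrationModel,
                            anc_model: AncestralPopulationModel,
                            chrom_lengths_morgans: dict,
                            n_samples: int,
                            seed,
                            n_variants: int | None = None) -> SimulatedCohort:
    """Forward-simulate an admixed cohort and record its true painting.

    The population holds ``N`` diploid individuals (2N haplotypes).  At
    generation ``T1`` all haplotypes are unadmixed, labeled by the founding
    proportions.  Each subsequent generation every haplotype is a gamete of a
    randomly chosen previous-generation individual, with crossover count
    Poisson(chromosome length in Morgans) and uniform crossover positions.
    At pulse times, a fraction ``m`` of individuals is replaced by unadmixed
    migrants from the pulse source.  ``n_samples`` individuals are drawn
    without replacement at present, alleles are painted from the per-ancestry
    frequencies, and the truth tracts are returned alongside the panel.
    """
    if 2 * model.N < 2 * n_samples:
        raise ValueError("population size too small for requested sample")
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_paint = [np.random.default_rng(s) for s in ss.spawn(2)]

    ancs = model.ancestries
    anc_index = {k: i for i, k in enumerate(ancs)}
    chroms = list(chrom_lengths_morgans)
    n_hap = 2 * model.N

    founding = np.array([model.founding_proportions.get(k, 0.0) for k in ancs])
    founder_anc = rng_pop.choice(len(ancs), size=n_hap, p=founding)

    # population[c][h] = (bounds_cM, labels) painting of haplotype h on chrom c
    population = {}
    for c in chroms:
        L_cm = chrom_lengths_morgans[c] * 100.0
        population[c] = [(np.array([0.0, L_cm]), [int(a)]) for a in founder_anc]

    pulses_at = {}
    for t, src, m in model.pulses:
        pulses_at.setdefault(int(t), []).append((anc_index[src], float(m)))

    for t in range(model.T1 - 1, 0, -1):
        # each new individual draws two parents; each parent gives one gamete
        parents = rng_pop.integers(0, model.N, size=n_hap)
        new_pop = {c: [None] * n_hap for c in chroms}
        for c in chroms:
            L_m = chrom_lengths_morgans[c]
            L_cm = L_m * 100.0
            prev = population[c]
            n_cross = rng_pop.poisson(L_m, size=n_hap)
            firsts = rng_pop.integers(0, 2, size=n_hap)
            for h in range(n_hap):
                p = parents[h]
                ba, la = prev[2 * p]
                bb, lb = prev[2 * p + 1]
                k = n_cross[h]
                if k == 0:
                    new_pop[c][h] = (ba.copy(), list(la)) if firsts[h] == 0 \
                        else (bb.copy(), list(lb))
                else:
                    cross = np.sort(rng_pop.random(k)) * L_cm
                    new_pop[c][h] = _recombine(ba, la, bb, lb, cross, firsts[h], L_cm)
        population = new_pop
        for src_i, m in pulses_at.get(t, []):
            n_rep = int(round(m * model.N))
            replaced = rng_pop.choice(model.N, size=n_rep, replace=False)
            for ind in replaced:
                for c in chroms:
                    L_cm = chrom_lengths_morgans[c] * 100.0
                    population[c][2 * ind] = (np.array([0.0, L_cm]), [src_i])
                    population[c][2 * ind + 1] = (np.array([0.0, L_cm]), [src_i])

    sampled = rng_pop.choice(model.N, size=n_samples, replace=False)
    hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in sampled])

    if n_variants is None:
        n_variants = anc_model.n_variants
    variants = uniform_variant_table(n_variants, chrom_lengths_morgans)
    for k in ancs:
        if k not in anc_model.base_freqs:
            raise ValueError(f"no allele frequencies for ancestry {k!r}")
        if len(anc_model.base_freqs[k]) < len(variants):
            raise ValueError("frequency vectors shorter than variant table; "
                             f"need >= {len(variants)} loci")
    freq_matrix = np.stack([anc_model.base_freqs[k][:len(variants)] for k in ancs])

    samples = [f"ADM{i}" for i in range(n_samples)]
    alleles = np.empty((2 * n_samples, len(variants)), dtype=np.int8)
    tract_rows = []
    vdf = variants.df
    for c in chroms:
        idx = variants.chrom_slice(c)
        pos_cm = vdf["pos_cM"].to_numpy()[idx]
        pos_bp = vdf["pos_bp"].to_numpy()[idx]
        L_cm = chrom_lengths_morgans[c] * 100.0
        bp_per_cm = (pos_bp[-1] - pos_bp[0]) / max(pos_cm[-1], 1e-9)
        for r, h in enumerate(hap_rows):
            bounds, labs = population[c][h]
            seg_of_variant = np.clip(np.searchsorted(bounds, pos_cm, side="right") - 1,
                                     0, len(labs) - 1)
            site_anc = np.array(labs, dtype=int)[seg_of_variant]
            freqs = freq_matrix[site_anc, idx]
            alleles[r, idx] = rng_paint.random(len(idx)) < freqs
            hap_id = (samples[r // 2], r % 2)
            whole = len(labs) == 1
            edges = np.round(pos_bp[0] + bounds * bp_per_cm).astype(np.int64)
            for j in range(1, len(edges)):  # keep bp edges strictly increasing
                edges[j] = max(edges[j], edges[j - 1] + 2)
            for j, lab in enumerate(labs):
                s_bp = int(edges[j]) + (1 if j else 0)
                tract_rows.append((hap_id, c, float(bounds[j]), float(bounds[j + 1]),
                                   s_bp, int(edges[j + 1]), ancs[lab], whole))

    panel = HaplotypePanel(alleles, samples, variants,
                           {s: "ADMIXED" for s in samples})
    truth = TractSet(pd.DataFrame(tract_rows, columns=TRACT_COLUMNS))
    return SimulatedCohort(panel, truth, model, seed)


# ---------------------------------------------------------------------------
# Parent pairs
# ---------------------------------------------------------------------------

def simulate_parent_pairs(n_pairs: int, target_correlation: float,
                          sex_bias: float, seed,
                          ancestries=ANCESTRIES3,
                          bias_toward: str = "NAT",
                          mean_primary: float = 0.4,
                          sd_primary: float = 0.12) -> pd.DataFrame:
    """Parent-pair ancestry proportions with assortative-mating correlation.

    The first ancestry's maternal/paternal proportions are a bivariate
    Gaussian pair with Pearson correlation ``target_correlation`` (clipped to
    stay inside the simplex); the remaining mass is split between the other
    two ancestries by an independent Beta draw.  X-chromosome proportions are
    the autosomal vector shifted by ``sex_bias`` toward ``bias_toward`` and
    renormalized: x = (1 - b) a + b e_bias.
    """
    if not -1.0 <= target_correlation <= 1.0:
        raise ValueError("target_correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, target_correlation], [target_correlation, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_pairs)
    primary = np.clip(mean_primary + sd_primary * z, 0.01, 0.95)

    K = len(ancestries)
    bias_idx = list(ancestries).index(bias_toward)

    def build(pcol):
        rest = 1.0 - pcol
        split = rng.beta(5, 5, size=n_pairs)
        mat = np.column_stack([pcol, rest * split, rest * (1 - split)])
        return mat

    maternal = build(primary[:, 0])
    paternal = build(primary[:, 1])

    e = np.zeros(K)
    e[bias_idx] = 1.0
    maternal_x = (1.0 - sex_bias) * maternal + sex_bias * e
    paternal_x = (1.0 - sex_bias) * paternal + sex_bias * e

    data = {"family": [f"fam{i}" for i in range(n_pairs)]}
    for j, k in enumerate(ancestries):
        data[f"maternal_{k}"] = maternal[:, j]
        data[f"paternal_{k}"] = paternal[:, j]
        data[f"maternal_X_{k}"] = maternal_x[:, j]
        data[f"paternal_X_{k}"] = paternal_x[:, j]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Convenience: three-way study scenario
# ---------------------------------------------------------------------------

def default_frequency_model(n_variants: int, seed,
                            ancestries=ANCESTRIES3,
                            divergence: float = 0.15) -> AncestralPopulationModel:
    """Continental frequency sets diverged from a common ancestral vector.

    Each continental population's frequencies are a Balding–Nichols draw at
    the given divergence from a shared Uniform(0.05, 0.95) ancestral vector.
    The default divergence reflects typical inter-continental human
    differentiation at array SNPs.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ancestries) + 1)
    rng = np.random.default_rng(children[0])
    base = rng.uniform(0.05, 0.95, size=n_variants)
    freqs = {k: draw_subpopulation_frequencies(base, divergence, children[i + 1])
             for i, k in enumerate(ancestries)}
    return AncestralPopulationModel(freqs)
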
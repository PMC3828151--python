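import logging

import numpy as np
import pytest

from admixkit.data_model_io import HaplotypePanel
from admixkit.local_ancestry import fit_window_model, paint_panel
from admixkit.simulate import (
    MigrationModel,
    default_frequency_model,
    simulate_admixed_cohort,
    simulate_reference_haplotypes,
)

logging.getLogger("admixkit").setLevel(logging.ERROR)


def build_reference_panel(anc_model, variants, n_per_pop=24, seed0=900):
    """Stack per-population Bernoulli reference panels on shared variants."""
    alleles, samples, labels = [], [], {}
    for i, pop in enumerate(anc_model.ancestries):
        p = simulate_reference_haplotypes(
            anc_model.base_freqs[pop][: len(variants)], n_per_pop,
            seed=seed0 + i, variants=variants, population=pop)
        alleles.append(p.alleles)
        samples += p.samples
        labels.update(p.labels)
    return HaplotypePanel(np.vstack(alleles), samples, variants, labels)


@pytest.fixture(scope="session")
def study_scenario():
    """A small three-way admixed cohort with references and painting.

    Founding 8 generations ago (60% European / 40% Native American) with an
    African pulse of 25% five generations ago, on one 1.5-Morgan chromosome
    with ~2400 SNPs; per-population Balding-Nichols divergence 0.1 from a
    shared ancestral frequency vector.
    """
    chrom_lengths = {"c1": 1.5}
    anc = default_frequency_model(2500, seed=9, divergence=0.1)
    model = MigrationModel(8, {"EUR": 0.6, "NAT": 0.4}, [(5, "AFR", 0.25)],
                           N=300)
    cohort = simulate_admixed_cohort(model, anc, chrom_lengths, n_samples=12,
                                     seed=10, n_variants=2400)
    refs = build_reference_panel(anc, cohort.panel.variants)
    wm = fit_window_model(refs)
    q = np.array([0.45, 0.3, 0.25])
    paths, tracts = paint_panel(cohort.panel, wm, g=6.0, q=q)
    return {
        "chrom_lengths": chrom_lengths,
        "anc_model": anc,
        "model": model,
        "cohort": cohort,
        "refs": refs,
        "window_model": wm,
        "q": q,
        "paths": paths,
        "tracts": tracts,
    }
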
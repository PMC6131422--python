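import numpy as np
import pytest

import tetrabsa as tb


def make_site(
    bases,
    quals=30,
    forward=None,
    paired=True,
    unique=True,
    nq=30.0,
    contig="c1",
    position=100,
    ref="A",
):
    """Compact SiteObservation builder for hand-written pileups."""
    bases = np.array(list(bases), dtype="U1")
    n = len(bases)

    def expand(value, dtype):
        arr = np.asarray(value)
        if arr.ndim == 0:
            arr = np.full(n, value)
        return arr.astype(dtype)

    if forward is None:
        forward = np.arange(n) % 2 == 0
    return tb.SiteObservation(
        contig=contig,
        position=position,
        ref_allele=ref,
        bases=bases,
        quals=expand(quals, int),
        forward=expand(forward, bool),
        properly_paired=expand(paired, bool),
        unique_mapping=expand(unique, bool),
        neighbourhood_quality=expand(nq, float),
    )


@pytest.fixture(scope="session")
def default_params():
    return tb.CallerParams()


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: one contig, few sites, full bulk design."""
    return tb.SimConfig(
        seed=11,
        n_contigs=1,
        contig_length=20_000,
        n_genes_per_contig=6,
        n_neutral_sites=30,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return tb.simulate_study(small_config)


def run_contrast_stage(study, params, alpha=0.05):
    """Calling + contrast + scoring on an in-memory study."""
    calls_low = tb.call_bulk(study.pileup_low, study.reference, params)
    calls_high = tb.call_bulk(study.pileup_high, study.reference, params)
    contrasts = tb.union_sites(calls_low, calls_high, study.pileup_low, study.pileup_high, params)
    tb.score_contrasts(contrasts, alpha)
    return calls_low, calls_high, contrasts


def run_full_pipeline(study, params, alpha=0.05):
    """Contrast stage plus effect annotation and TAV selection."""
    calls_low, calls_high, contrasts = run_contrast_stage(study, params, alpha)
    variants = []
    for bc in contrasts:
        for i, allele in enumerate(bc.alleles):
            if allele != bc.ref_allele and (bc.counts_low[i] or bc.counts_high[i]):
                variants.append(tb.Variant(bc.contig, bc.position, bc.ref_allele, allele))
    effect_index = tb.annotate_all(variants, study.reference)
    tavs = tb.select_tavs(contrasts, effect_index, alpha)
    return contrasts, tavs
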
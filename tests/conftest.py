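import numpy as np
import pytest

from slinc.aligner import IntergenicSampler
from slinc.fixtures import FixtureConfig, plant_genome_pair
from slinc.lnc_filter import FilterConfig, run_filter_pipeline
from slinc.ortho_evo import (
    classify_pair,
    evo_metrics,
    find_candidate_ortholog,
    reciprocal_orthologs,
)


@pytest.fixture(scope="session")
def fx7():
    """The default planted-genome fixture (seed 7)."""
    return plant_genome_pair(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def filter_result(fx7):
    cfg = FilterConfig(
        genome_a=fx7.genome_a,
        coding_a=fx7.coding_a,
        genome_b=fx7.genome_b,
        coding_b=fx7.coding_b,
        chains=fx7.chains,
        known_panels=fx7.known_panels,
        seed=1,
    )
    kept, report, single_exon = run_filter_pipeline(fx7.candidates_a, cfg)
    return {"kept": kept, "report": report, "single_exon": single_exon}


@pytest.fixture(scope="session")
def ortho_result(fx7, filter_result):
    """Reciprocal ortholog search over the fixture's kept lncRNAs, with
    metrics and classes attached."""
    pad = fx7.recommended_run_config()["pad"]
    rng = np.random.default_rng(2)
    sampler_b = IntergenicSampler(fx7.genome_b, fx7.annotations_b())
    sampler_a = IntergenicSampler(fx7.genome_a, fx7.annotations_a())
    inv = fx7.chains.inverted()
    kept = filter_result["kept"]
    pairs_ab = [
        p
        for p in (
            find_candidate_ortholog(
                tx, fx7.genome_a, fx7.genome_b, fx7.lnc_b, fx7.chains,
                pad=pad, rng_seed=rng, sampler_b=sampler_b, species=("spA", "spB"),
            )
            for tx in sorted(kept, key=lambda t: t.id)
        )
        if p
    ]
    pairs_ba = [
        p
        for p in (
            find_candidate_ortholog(
                tx, fx7.genome_b, fx7.genome_a, kept, inv,
                pad=pad, rng_seed=rng, sampler_b=sampler_a, species=("spB", "spA"),
            )
            for tx in sorted(fx7.lnc_b, key=lambda t: t.id)
        )
        if p
    ]
    confirmed = reciprocal_orthologs(pairs_ab, pairs_ba)
    annots_a = {"mirna": fx7.mirna_a, "snorna": fx7.snorna_a, "coding": fx7.coding_a}
    annots_b = {"mirna": fx7.mirna_b, "snorna": fx7.snorna_b, "coding": fx7.coding_b}
    classes = {}
    for p in confirmed:
        evo_metrics(p, fx7.genome_a, fx7.genome_b)
        classes[p.query.id] = classify_pair(p, annots_a, annots_b)
    return {
        "pairs_ab": pairs_ab,
        "pairs_ba": pairs_ba,
        "confirmed": confirmed,
        "classes": classes,
    }
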
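"""Shared fixtures: small hand-built inputs and the default synthetic cohort.

The session-scoped cohort is generated once (seed fixed) and reused by
every test that exercises pipeline stages on realistic data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cagekit import synthetic as syn
from cagekit.clustering import TagCluster

COHORT_SEED = 101


def make_cluster(tpm, start=100, chrom="chr1", strand="+", tc_id="tc_test"):
    """A TagCluster over consecutive positions with the given TPM profile."""
    tpm = np.asarray(tpm, dtype=float)
    return TagCluster(
        tc_id=tc_id,
        chrom=chrom,
        strand=strand,
        positions=np.arange(start, start + len(tpm)),
        tpm=tpm,
    )


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic study cohort (74 samples, 300 genes, 200
    enhancers with planted DE, links and batch structure)."""
    return syn.simulate_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def gene_models(cohort, tmp_path_factory):
    """Gene models re-read from the GTF the generator writes."""
    from cagekit.io import read_gene_models

    path = tmp_path_factory.mktemp("gtf") / "genes.gtf"
    syn.write_gtf(cohort.truth, str(path))
    return read_gene_models(str(path))


@pytest.fixture(scope="session")
def called_enhancers(cohort, gene_models):
    """Enhancer candidates called on the default cohort, with counts."""
    from cagekit.clustering import pool_ctss
    from cagekit.enhancers import (
        build_exclusion_mask,
        detect_bidirectional_candidates,
        filter_by_support,
    )

    mask = build_exclusion_mask(gene_models)
    joint = pool_ctss(cohort.profiles)
    candidates = detect_bidirectional_candidates(joint, mask)
    candidates, counts = filter_by_support(candidates, cohort.profiles)
    return candidates, counts


@pytest.fixture(scope="session")
def qpcr_panels(cohort):
    return syn.simulate_qpcr(cohort.truth, seed=COHORT_SEED + 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
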
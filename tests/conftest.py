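"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nrlkit as nk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

GENOME_SIZE = 2_600_000


@pytest.fixture(scope="session")
def genome_size():
    return GENOME_SIZE


@pytest.fixture(scope="session")
def anchors500():
    return nk.generate_anchor_sites(500, GENOME_SIZE, seed=101)


@pytest.fixture(scope="session")
def sim186(anchors500):
    """Two-sided arrays, 186 bp spacing both sides, study-condition noise."""
    model = nk.ArrayModel()
    dyads = nk.generate_nucleosome_map(
        anchors500, model, genome_size=GENOME_SIZE, seed=202
    )
    return anchors500, dyads, model


@pytest.fixture(scope="session")
def sim_asym(anchors500):
    """Asymmetric arrays: 190 bp spacing upstream, 170 bp downstream."""
    model = nk.ArrayModel(nrl_up=190, nrl_down=170)
    dyads = nk.generate_nucleosome_map(
        anchors500, model, genome_size=GENOME_SIZE, seed=303
    )
    return anchors500, dyads, model


@pytest.fixture(scope="session")
def pfm():
    return nk.bundled_ctcf_like_pfm()


def make_anchor(centre, strand="+", chrom="chrS", length=19, score=1.0):
    start = centre - length // 2
    iv = nk.GenomicInterval(chrom, start, start + length, strand, score)
    return nk.AnchorSite(iv, centre=centre, strand=strand, score=score)


@pytest.fixture
def anchor_factory():
    return make_anchor
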
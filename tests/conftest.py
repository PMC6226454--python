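"""Shared fixtures: one default synthetic dataset per session, plus the
derived scan/tree objects the integration tests need."""

from __future__ import annotations

import pytest

import famscan
from famscan.reference import MOTIFS
from famscan.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig()  # default study conditions, seed 42


@pytest.fixture(scope="session")
def bundle(config):
    return famscan.generate(config)


@pytest.fixture(scope="session")
def family_proteins(bundle):
    return [p for p in bundle.proteins if p.id in bundle.truth.family_members]


@pytest.fixture(scope="session")
def scan_reports(bundle):
    return famscan.scan_proteome(bundle.proteins, MOTIFS, seed=1)


@pytest.fixture(scope="session")
def family_tree(family_proteins):
    dm = famscan.pairwise_distances(family_proteins)
    return famscan.nj_tree(dm)


@pytest.fixture(scope="session")
def ct_table(bundle, config):
    return famscan.simulate_ct(bundle, config)


@pytest.fixture(scope="session")
def fpkm(bundle, config):
    return famscan.simulate_expression(bundle, config)
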
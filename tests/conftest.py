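"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import pytest

import agshift as ag


@pytest.fixture(scope="session")
def default_dataset():
    """Reference scenario: 200 genes, 20 planted events, seed 42."""
    cfg = ag.SimConfig(seed=42)
    genome, isoforms, truth = ag.make_genome_and_annotation(cfg)
    data = ag.simulate_counts(isoforms, truth, cfg)
    return cfg, genome, isoforms, truth, data


@pytest.fixture(scope="session")
def default_result(default_dataset):
    cfg, genome, isoforms, truth, data = default_dataset
    res = ag.analyze(data.junction_counts, data.coverage, data.sample_groups,
                     genome=genome, isoforms=isoforms,
                     expression=data.expression,
                     orthology=ag.orthology_table(truth))
    return truth, data, res


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny dataset for fast structural tests (both strands, 8 events)."""
    cfg = ag.SimConfig(n_genes=40, n_cryptic_events=8, seed=11)
    genome, isoforms, truth = ag.make_genome_and_annotation(cfg)
    data = ag.simulate_counts(isoforms, truth, cfg)
    return cfg, genome, isoforms, truth, data
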
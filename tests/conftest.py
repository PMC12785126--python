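"""Shared fixtures: the default synthetic benchmark, built once per session."""

from __future__ import annotations

import pytest

from adipolnc.annotation_io import extract_all_sequences
from adipolnc.coding_potential import CodingPotentialScorer
from adipolnc.models import ANNOTATED_LNCRNA, CODING
from adipolnc.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default benchmark: reference/assembled annotations, genome, truth,
    counts — 50 planted novel lncRNAs plus single-violation decoys."""
    cfg = SimulationConfig(seed=11)
    reference, assembled, genome, truth = simulate_annotation(cfg)
    counts = simulate_counts(truth, cfg)
    return {
        "cfg": cfg,
        "reference": reference,
        "assembled": assembled,
        "genome": genome,
        "truth": truth,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def sim_sequences(default_sim):
    return extract_all_sequences(default_sim["genome"], default_sim["assembled"])


@pytest.fixture(scope="session")
def fitted_scorer(default_sim, sim_sequences):
    """Coding-potential scorer trained on the reference coding genes vs
    annotated lncRNAs of the default benchmark."""
    reference = default_sim["reference"]
    coding = [
        sim_sequences[t.transcript_id].sequence
        for t in reference
        if t.annotation_status == CODING
    ]
    noncoding = [
        sim_sequences[t.transcript_id].sequence
        for t in reference
        if t.annotation_status == ANNOTATED_LNCRNA
    ]
    return CodingPotentialScorer().fit(coding, noncoding)
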
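"""Shared fixtures: a small planted-motif dataset and a trained scaled model.

Everything is generated programmatically; the trained model fixture is
session-scoped so the attention/PWM tests share one short training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import epiattend as ea
from epiattend.nn import EPINetwork
from epiattend.training import SplitSpec, split, train

ENH_MOTIF = ea.PlantedMotif("enh_motif", "TGACGTCA", 0.0)
PROM_MOTIF = ea.PlantedMotif("prom_motif", "CCGGAAGT", 0.0)


@pytest.fixture(scope="session")
def scaled_cfg():
    return ea.scaled_test_config()


@pytest.fixture(scope="session")
def small_dataset():
    """100 positives + 500 negatives, clean plants (mutation_rate 0)."""
    records, manifest = ea.generate_dataset(
        100, 5, ENH_MOTIF, PROM_MOTIF, seed=7, enh_len=300, prom_len=200)
    return records, manifest


@pytest.fixture(scope="session")
def trained(small_dataset, scaled_cfg):
    """A scaled model trained briefly on the easy synthetic task, together
    with its splits and manifest."""
    records, manifest = small_dataset
    tr, va, te = split(records, SplitSpec(seed=7))
    net = EPINetwork(scaled_cfg, seed=7)
    history = train(net, tr, va, scaled_cfg, mode="class_weight", seed=7,
                    max_epochs=14, patience=6)
    return {"net": net, "history": history, "train": tr, "val": va,
            "test": te, "manifest": manifest, "cfg": scaled_cfg}
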
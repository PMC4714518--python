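"""Shared fixtures: the seeded synthetic experiment and its derived calls.

The default simulated experiment (2000 genes, seed 7) and the full cascade
computed from it are expensive enough (~10 s together) to share at session
scope; tests treat them as read-only.
"""

from __future__ import annotations

import pytest

from transgen_nhg.diffexpr_classify import (
    build_cascade,
    call_temperature_sensitive,
)
from transgen_nhg.synthetic_data import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def exp7():
    return simulate_experiment(SimConfig(seed=7))


@pytest.fixture(scope="session")
def mrna7(exp7):
    return {"WT": exp7.mrna("WT"), "hrde1": exp7.mrna("hrde1")}


@pytest.fixture(scope="session")
def cascade7(exp7, mrna7):
    wt_calls = call_temperature_sensitive(mrna7["WT"], "WT")
    mut_calls = call_temperature_sensitive(mrna7["hrde1"], "hrde1")
    cascade = build_cascade(wt_calls, mut_calls, mrna7["WT"], mrna7["hrde1"])
    return {"wt": wt_calls, "mut": mut_calls, "cascade": cascade}
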
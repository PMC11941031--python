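"""Shared fixtures: small synthetic references and a cached panel design.

Everything is generated programmatically; expensive objects (the designed
panels) are session-scoped so the suite designs each panel once.
"""

from __future__ import annotations

import pytest

from smmiptools import capture_sim, panel_select, probe_design
from smmiptools.panel_select import SelectionConfig


@pytest.fixture(scope="session")
def small_reference():
    """5-target 15 kb synthetic reference."""
    return capture_sim.make_synthetic_reference(5, 15_000, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_reference):
    genome, targets, _ = small_reference
    return panel_select.design_panel(
        genome, targets, profile=probe_design.DesignProfile.stringent_only(),
        sel_config=SelectionConfig(seed=1))


@pytest.fixture(scope="session")
def acceptance_reference():
    """The 20-target 50 kb reference used by the constraint-satisfaction
    acceptance checks."""
    return capture_sim.make_synthetic_reference(20, 50_000, seed=7)


@pytest.fixture(scope="session")
def acceptance_panel(acceptance_reference):
    genome, targets, _ = acceptance_reference
    return panel_select.design_panel(
        genome, targets, profile=probe_design.DesignProfile.stringent_only(),
        sel_config=SelectionConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_pipeline():
    """simulate -> classify -> call on a 10-probe panel, 300 read pairs per
    probe, default failure-mode parameters (seed 11)."""
    from smmiptools import meth_call, read_classify

    genome, targets, betas = capture_sim.make_synthetic_reference(10, 30_000, seed=7)
    panel = panel_select.design_panel(
        genome, targets, profile=probe_design.DesignProfile.stringent_only(),
        sel_config=SelectionConfig(seed=1))
    params = capture_sim.SimParams(n_read_pairs=3000, seed=11)
    reads, truth = capture_sim.simulate_capture(panel, genome, betas, params)
    index = read_classify.PanelIndex(panel)
    calls = [read_classify.classify_read((s1, s2), index, read_id=rid)
             for (rid, s1), (_, s2) in zip(reads.r1, reads.r2)]
    result = meth_call.call_methylation(calls, index, genome)
    return {"genome": genome, "targets": targets, "betas": betas,
            "panel": panel, "params": params, "reads": reads, "truth": truth,
            "index": index, "calls": calls, "result": result}
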
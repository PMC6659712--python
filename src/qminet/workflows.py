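"""Convenience drivers composing the pipeline stages end to end."""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from . import anc as anc_mod
from . import preprocess
from .anc import ANCResult
from .containers import BeadDistribution, MFIMatrix
from .synthdata import PanelConfig, PlantedEffect, SimulationDesign, probe_of_well, simulate_events


def event_pipeline(
    panel: PanelConfig,
    design: SimulationDesign,
    effects: Sequence[PlantedEffect] = (),
) -> list[BeadDistribution]:
    """Simulate events, gate, classify and pair into bead distributions."""
    events, _ = simulate_events(panel, design, list(effects))
    gated = preprocess.gate_doublets(events)
    classified = preprocess.classify_beads(gated, panel)
    return preprocess.pair_reporter(
        classified, probe_of_well(classified), panel.ip_of_region
    )


def anc_pipeline(
    panel: PanelConfig,
    design: SimulationDesign,
    effects: Sequence[PlantedEffect] = (),
    control_condition: str | None = None,
    treated_condition: str | None = None,
    **anc_kwargs,
) -> ANCResult:
    """Simulated panel through gating, classification, pairing and ANC."""
    dists = event_pipeline(panel, design, effects)
    control = control_condition or design.conditions[0]
    treated = treated_condition or design.conditions[1]
    return anc_mod.run_anc(dists, control, treated, **anc_kwargs)


def mfi_pipeline(
    panel: PanelConfig,
    design: SimulationDesign,
    effects: Sequence[PlantedEffect] = (),
) -> MFIMatrix:
    """Simulated events to a replicate-averaged MFI matrix (CNA input)."""
    dists = event_pipeline(panel, design, effects)
    matrix = preprocess.mfi_matrix_from_distributions(dists)
    return preprocess.average_replicates(matrix)
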
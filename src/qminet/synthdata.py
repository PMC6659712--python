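"""Synthetic QMI bead-array data with known ground truth.

Two generators cover the two entry points of the pipeline:

* :func:`simulate_events` emits bead-level event tables mimicking a
  multiplexed IP-FCM run — an antibody panel of capture-bead regions crossed
  with probe wells, lognormal reporter noise parameterised by its median
  (so MFI targets are exact medians), a detection floor near MFI 100,
  per-experiment multiplicative batch factors, and a configurable fraction
  of doublet events falling outside the doublet-discriminator gate.
* :func:`simulate_mfi_matrix` emits matrix-level MFI data with planted
  correlated modules, a trait-linked log2 shift and additive (log2-scale)
  batch offsets, for exercising network analysis without the event layer.

Every generator returns a :class:`TruthTable` recording what was planted so
recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, UNCLASSIFIED, MFIMatrix

__all__ = [
    "IPAntibody",
    "PanelConfig",
    "SimulationDesign",
    "PlantedEffect",
    "TruthTable",
    "make_panel",
    "simulate_events",
    "simulate_mfi_matrix",
]

#: Doublet-discriminator gate bounds (arbitrary units) used by the simulator;
#: events outside the open interval are doublets.
GATE_LO = 5000.0
GATE_HI = 25000.0


@dataclass(frozen=True)
class IPAntibody:
    """A capture antibody: bead-region id plus 2-D classification centroid."""

    name: str
    region: int
    centroid: tuple[float, float]


@dataclass
class PanelConfig:
    """Capture x probe antibody panel.

    ``interactions`` is the full cross product named ``"IP_Probe"``;
    ``classification_sd`` is the within-region SD of the classification
    channels that :func:`simulate_events` uses (and that bead classification
    should assume).
    """

    ip_antibodies: list[IPAntibody]
    probe_antibodies: list[str]
    classification_sd: float = 25.0

    def __post_init__(self) -> None:
        regions = [ab.region for ab in self.ip_antibodies]
        if len(set(regions)) != len(regions):
            raise ValueError("bead-region identifiers must be unique")
        names = [ab.name for ab in self.ip_antibodies]
        if len(set(names)) != len(names) or len(set(self.probe_antibodies)) != len(
            self.probe_antibodies
        ):
            raise ValueError("antibody names must be unique")

    @property
    def interactions(self) -> list[str]:
        return [
            f"{ip.name}_{probe}"
            for ip in self.ip_antibodies
            for probe in self.probe_antibodies
        ]

    @property
    def n_interactions(self) -> int:
        return len(self.ip_antibodies) * len(self.probe_antibodies)

    @property
    def ip_of_region(self) -> dict[int, str]:
        return {ab.region: ab.name for ab in self.ip_antibodies}

    def centroid_array(self) -> np.ndarray:
        return np.array([ab.centroid for ab in self.ip_antibodies], dtype=float)


@dataclass
class SimulationDesign:
    """Study design and noise model for event-level simulation.

    Defaults reproduce the assay's stated conditions: 4 experiments acting
    as batches, technical duplicates, a few hundred beads per interaction
    per well, and a detection floor at MFI ~ 100.
    """

    n_experiments: int = 4
    conditions: tuple[str, ...] = ("control", "treated")
    n_replicates: int = 2
    beads_per_interaction_per_well: int = 300
    baseline_mfi: float | dict[str, float] = 500.0
    reporter_cv: float = 0.3
    batch_sd: float = 0.2
    background_floor: float = 100.0
    doublet_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_experiments", "n_replicates", "beads_per_interaction_per_well"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        base = self.baseline_mfi
        if np.any(np.asarray(list(base.values()) if isinstance(base, dict) else base) <= 0):
            raise ValueError("baseline_mfi must be > 0")
        if not 0 <= self.doublet_fraction < 1:
            raise ValueError("doublet_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PlantedEffect:
    """A planted multiplicative change of one interaction's baseline MFI.

    ``fold_change=0.6`` means a 40 % dissociation in the affected condition;
    ``experiments_affected=None`` means every experiment.
    """

    interaction: str
    condition: str
    fold_change: float
    experiments_affected: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass
class TruthTable:
    """Ground truth of a simulation: planted effects and latent module labels."""

    effects: list[PlantedEffect] = field(default_factory=list)
    module_labels: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "effects": [asdict(e) for e in self.effects],
            "module_labels": self.module_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        effects = [
            PlantedEffect(
                e["interaction"],
                e["condition"],
                e["fold_change"],
                tuple(e["experiments_affected"]) if e["experiments_affected"] else None,
            )
            for e in payload["effects"]
        ]
        return cls(effects, dict(payload["module_labels"]))


def make_panel(
    n_ip: int, n_probe: int, seed: int = 0, classification_sd: float = 25.0
) -> PanelConfig:
    """Build an ``n_ip`` x ``n_probe`` antibody panel with separable bead regions.

    Region centroids sit on a jittered square grid with spacing
    ``6 * classification_sd``; the jitter is at most one SD per axis, so any
    two centroids are at least 4 SD apart and nearest-centroid classification
    is essentially error-free.
    """
    if n_ip < 1 or n_probe < 1:
        raise ValueError("panel dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_ip)))
    spacing = 6.0 * classification_sd
    grid = np.array([(i % side, i // side) for i in range(n_ip)], dtype=float)
    centroids = 1000.0 + grid * spacing + rng.uniform(
        -classification_sd, classification_sd, size=(n_ip, 2)
    )
    ips = [
        IPAntibody(f"IP{i + 1}", region=i + 1, centroid=tuple(centroids[i]))
        for i in range(n_ip)
    ]
    probes = [f"Probe{j + 1}" for j in range(n_probe)]
    return PanelConfig(ips, probes, classification_sd=classification_sd)


def _baseline_vector(panel: PanelConfig, design: SimulationDesign) -> np.ndarray:
    names = panel.interactions
    if isinstance(design.baseline_mfi, dict):
        unknown = set(design.baseline_mfi) - set(names)
        if unknown:
            raise ValueError(f"baseline_mfi for unknown interactions: {sorted(unknown)}")
        default = 500.0
        return np.array([design.baseline_mfi.get(n, default) for n in names])
    return np.full(len(names), float(design.baseline_mfi))


def simulate_events(
    panel: PanelConfig,
    design: SimulationDesign,
    effects: list[PlantedEffect] | tuple[PlantedEffect, ...] = (),
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate an event table for the full design.

    One well per (experiment, condition, replicate, probe); each well holds
    ``beads_per_interaction_per_well`` beads of every capture region.  The
    reporter of a bead on interaction *i* in experiment *e*, condition *c* is

        lognormal with median  max(floor, baseline_i * batch_e * effect_iec)

    and coefficient of variation ``reporter_cv``.  ``doublet_fraction`` of
    events receive a doublet-discriminator value outside (5000, 25000),
    symmetrically above and below; the rest fall inside the gate.  The region
    column is left unclassified — classification channels are simulated as
    Gaussians around the region centroid and it is the preprocessing step's
    job to recover the region.
    """
    names = panel.interactions
    name_index = {n: i for i, n in enumerate(names)}
    for eff in effects:
        if eff.interaction not in name_index:
            raise ValueError(f"planted effect on unknown interaction {eff.interaction!r}")
        if eff.condition not in design.conditions:
            raise ValueError(f"planted effect on unknown condition {eff.condition!r}")

    rng = np.random.default_rng(design.seed)
    n_ip = len(panel.ip_antibodies)
    n_probe = len(panel.probe_antibodies)
    n_exp, n_cond, n_rep = (
        design.n_experiments,
        len(design.conditions),
        design.n_replicates,
    )
    beads = design.beads_per_interaction_per_well

    batch_factor = 2.0 ** rng.normal(0.0, design.batch_sd, size=n_exp)
    baseline = _baseline_vector(panel, design)

    # multiplicative effect per (interaction, experiment, condition)
    mult = np.ones((len(names), n_exp, n_cond))
    cond_index = {c: k for k, c in enumerate(design.conditions)}
    for eff in effects:
        exps = (
            range(n_exp)
            if eff.experiments_affected is None
            else eff.experiments_affected
        )
        for e in exps:
            mult[name_index[eff.interaction], e, cond_index[eff.condition]] *= (
                eff.fold_change
            )

    # event layout: wells ordered (e, c, r, probe), regions block-wise inside
    n_wells = n_exp * n_cond * n_rep * n_probe
    n_events = n_wells * n_ip * beads

    well_e = np.repeat(np.arange(n_exp), n_cond * n_rep * n_probe)
    well_c = np.tile(np.repeat(np.arange(n_cond), n_rep * n_probe), n_exp)
    well_r = np.tile(np.repeat(np.arange(n_rep), n_probe), n_exp * n_cond)
    well_p = np.tile(np.arange(n_probe), n_exp * n_cond * n_rep)

    ev_well = np.repeat(np.arange(n_wells), n_ip * beads)
    ev_ip = np.tile(np.repeat(np.arange(n_ip), beads), n_wells)
    ev_e = well_e[ev_well]
    ev_c = well_c[ev_well]
    ev_p = well_p[ev_well]
    ev_interaction = ev_ip * n_probe + ev_p

    target = baseline[ev_interaction] * batch_factor[ev_e] * mult[
        ev_interaction, ev_e, ev_c
    ]
    median = np.maximum(design.background_floor, target)
    sigma = np.sqrt(np.log1p(design.reporter_cv**2))
    reporter = np.exp(rng.normal(np.log(median), sigma))

    centroids = panel.centroid_array()
    cl = centroids[ev_ip] + rng.normal(
        0.0, panel.classification_sd, size=(n_events, 2)
    )

    disc = rng.uniform(GATE_LO, GATE_HI, size=n_events)
    is_doublet = rng.random(n_events) < design.doublet_fraction
    n_doub = int(is_doublet.sum())
    if n_doub:
        below = rng.random(n_doub) < 0.5
        out = np.where(
            below,
            rng.uniform(500.0, GATE_LO, size=n_doub),
            rng.uniform(GATE_HI, 40000.0, size=n_doub),
        )
        disc[is_doublet] = out

    cond_names = np.array(design.conditions, dtype=object)
    well_labels = [
        f"E{e + 1}_{cond_names[c]}_R{r + 1}_{panel.probe_antibodies[p]}"
        for e, c, r, p in zip(well_e, well_c, well_r, well_p)
    ]
    sample_labels = [
        f"E{e + 1}_{cond_names[c]}_R{r + 1}"
        for e, c, r in zip(well_e, well_c, well_r)
    ]
    sample_codes, sample_cats = pd.factorize(np.asarray(sample_labels, dtype=object))

    # column-wise assembly avoids pandas consolidating the large float blocks
    events = pd.DataFrame(index=pd.RangeIndex(n_events))
    events["event_id"] = np.arange(n_events)
    events["well_id"] = pd.Categorical.from_codes(ev_well, categories=well_labels)
    events["sample_id"] = pd.Categorical.from_codes(
        sample_codes[ev_well], categories=sample_cats
    )
    events["experiment"] = ev_e + 1
    events["condition"] = pd.Categorical.from_codes(ev_c, categories=list(cond_names))
    events["replicate"] = well_r[ev_well] + 1
    events["region"] = np.full(n_events, UNCLASSIFIED, dtype=np.int64)
    events["cl1"] = np.ascontiguousarray(cl[:, 0])
    events["cl2"] = np.ascontiguousarray(cl[:, 1])
    events["doublet_disc"] = disc
    events["reporter"] = reporter
    assert list(events.columns) == EVENT_COLUMNS
    truth = TruthTable(effects=list(effects))
    return events, truth


def probe_of_well(events: pd.DataFrame) -> dict[str, str]:
    """Recover the well -> probe mapping from simulator well ids."""
    wells = [str(w) for w in events["well_id"].unique()]
    return {w: w.rsplit("_", 1)[1] for w in wells}


def simulate_mfi_matrix(
    n_interactions: int,
    n_samples: int,
    modules: tuple[int, ...] | list[int] = (),
    trait: np.ndarray | list[int] | None = None,
    effect_size: float = 0.0,
    batch: np.ndarray | list | None = None,
    seed: int = 0,
    *,
    trait_module: int = 0,
    baseline_log2: float = 9.0,
    loading: float = 0.8,
    noise_sd: float = 0.6,
    batch_offsets: dict | None = None,
    batch_sd: float = 0.5,
) -> tuple[MFIMatrix, TruthTable]:
    """Simulate an MFI matrix with planted correlated modules.

    On the log2 scale each interaction in module *m* follows

        x = baseline + loading * f_m + batch_offset + trait_shift + noise

    with a shared per-sample latent factor ``f_m ~ N(0,1)``, so the expected
    within-module correlation is ``loading^2 / (loading^2 + noise_sd^2)``
    (0.64 at the defaults).  Interactions beyond ``sum(modules)`` are
    uncorrelated noise.  If ``effect_size`` is nonzero, module
    ``trait_module`` additionally shifts by ``effect_size`` log2 units in
    trait-positive samples.  Batch offsets are additive on the log2 scale
    (multiplicative on MFI); pass ``batch_offsets`` to fix them or let them
    be drawn ``N(0, batch_sd)``.
    """
    modules = list(modules)
    if sum(modules) > n_interactions:
        raise ValueError("module sizes exceed n_interactions")
    trait_arr = np.zeros(n_samples) if trait is None else np.asarray(trait, float)
    if trait_arr.size != n_samples:
        raise ValueError("trait length must equal n_samples")
    if batch is None:
        batch_arr = np.zeros(n_samples, dtype=int)
    else:
        batch_arr = np.asarray(batch)
        if batch_arr.size != n_samples:
            raise ValueError("batch length must equal n_samples")

    rng = np.random.default_rng(seed)
    levels = pd.unique(batch_arr)
    if batch_offsets is None:
        batch_offsets = {
            lev: (0.0 if len(levels) == 1 else rng.normal(0.0, batch_sd))
            for lev in levels
        }
    offsets = np.array([batch_offsets[b] for b in batch_arr])

    labels = np.full(n_interactions, -1, dtype=int)  # -1 = noise
    pos = 0
    for m, size in enumerate(modules):
        labels[pos : pos + size] = m
        pos += size

    x = np.empty((n_interactions, n_samples))
    factors = rng.standard_normal((max(len(modules), 1), n_samples))
    for i in range(n_interactions):
        m = labels[i]
        signal = loading * factors[m] if m >= 0 else 0.0
        x[i] = baseline_log2 + signal + rng.normal(0.0, noise_sd, n_samples)
        if m == trait_module and m >= 0 and effect_size != 0.0:
            x[i] += effect_size * trait_arr
    x += offsets  # broadcast over rows

    names = [f"I{i + 1}" for i in range(n_interactions)]
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    values = pd.DataFrame(2.0**x, index=names, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "condition": np.where(trait_arr > 0, "treated", "control"),
            "experiment": batch_arr,
            "replicate": 1,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_effects = []
    if effect_size != 0.0 and len(modules) > trait_module:
        truth_effects = [
            PlantedEffect(names[i], "treated", float(2.0**effect_size))
            for i in np.flatnonzero(labels == trait_module)
        ]
    truth = TruthTable(
        effects=truth_effects,
        module_labels={names[i]: int(labels[i]) for i in range(n_interactions)},
    )
    return MFIMatrix(values, samples), truth
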
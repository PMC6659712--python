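"""Bead-level preprocessing: gating, classification, pairing and MFI.

The path from raw events to an MFI matrix follows the assay's inclusion
criteria: (i) doublet exclusion on the doublet-discriminator channel with
strict bounds, (ii) assignment of each bead to its capture region from the
classification channels, (iii) pairing of each bead's reporter (PE)
fluorescence with its region and the probe of its well, yielding one reporter
distribution per interaction and well, which is collapsed to a single median
fluorescence intensity (MFI).

The module also houses the small quantification conventions used alongside
the bead assay: averaging IgG-control backgrounds across detergents,
band-densitometry solubility fractions, and pooling of size-exclusion
chromatography fractions in contiguous blocks.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import UNCLASSIFIED, BeadDistribution, MFIMatrix, SolubilityMeasurement
from .synthdata import PanelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "gate_doublets",
    "classify_beads",
    "pair_reporter",
    "compute_mfi",
    "mfi_matrix_from_distributions",
    "average_replicates",
    "igg_background",
    "solubility_fraction",
    "pool_fractions",
]


def gate_doublets(
    events: pd.DataFrame, lo: float = 5000.0, hi: float = 25000.0
) -> pd.DataFrame:
    """Keep events whose doublet discriminator lies strictly inside (lo, hi).

    Events at exactly ``lo`` or ``hi`` are excluded (the bounds are printed
    as strict inequalities).  Retained/total counts are logged and stored in
    ``result.attrs["gate_counts"]``.
    """
    if lo >= hi:
        raise ValueError("gate requires lo < hi")
    disc = events["doublet_disc"].to_numpy()
    keep = (disc > lo) & (disc < hi)
    gated = events.loc[keep]
    gated.attrs["gate_counts"] = {"retained": int(keep.sum()), "total": int(len(events))}
    logger.info("doublet gate: retained %d / %d events", keep.sum(), len(events))
    return gated


def classify_beads(
    events: pd.DataFrame, panel: PanelConfig, max_radius: float = 3.0
) -> pd.DataFrame:
    """Assign each event to the bead region of the nearest centroid.

    Events farther than ``max_radius`` region-SDs from every centroid, or
    exactly equidistant from two nearest centroids, stay unclassified
    (region ``-1``) and are dropped later when distributions are built.
    Events arriving with a region already assigned pass through unchanged.
    """
    centroids = panel.centroid_array()
    if len(np.unique(centroids, axis=0)) != len(centroids):
        raise ValueError("panel has duplicate region centroids")
    regions = np.array([ab.region for ab in panel.ip_antibodies])

    # shallow copy: the region column is replaced, other columns are shared
    out = events.copy(deep=False)
    region = events["region"].to_numpy()
    todo = region == UNCLASSIFIED
    if not todo.any():
        return out
    pts = np.column_stack(
        (events["cl1"].to_numpy()[todo], events["cl2"].to_numpy()[todo])
    )
    limit = max_radius * panel.classification_sd
    if len(centroids) == 1:
        dist = np.hypot(pts[:, 0] - centroids[0, 0], pts[:, 1] - centroids[0, 1])
        assigned = np.where(dist <= limit, regions[0], UNCLASSIFIED)
    else:
        tree = cKDTree(centroids)
        dist, best = tree.query(pts, k=2)
        ok = (dist[:, 0] <= limit) & (dist[:, 0] < dist[:, 1])  # tie -> unclassified
        assigned = np.where(ok, regions[best[:, 0]], UNCLASSIFIED)
    new_region = region.copy()
    new_region[todo] = assigned
    out["region"] = new_region
    n_dropped = int((new_region == UNCLASSIFIED).sum())
    out.attrs["n_unclassified"] = n_dropped
    logger.info(
        "bead classification: %d / %d events unclassified (%.2f%%)",
        n_dropped,
        len(out),
        100.0 * n_dropped / max(len(out), 1),
    )
    return out


def pair_reporter(
    events: pd.DataFrame,
    probe_of_well: Mapping[str, str],
    ip_of_region: Mapping[int, str] | None = None,
) -> list[BeadDistribution]:
    """Pair reporter values with bead regions: one distribution per (IP, probe, well).

    ``probe_of_well`` maps every well id to the detection antibody probed in
    that well; ``ip_of_region`` maps region ids to capture-antibody names
    (region ids are used verbatim when omitted).  Unclassified events are
    dropped; all classified events are conserved across the returned
    distributions.
    """
    wells = {str(w) for w in events["well_id"].unique()}
    missing = wells - set(probe_of_well)
    if missing:
        raise ValueError(f"wells without probe assignment: {sorted(missing)[:5]}")

    classified = events.loc[events["region"].to_numpy() != UNCLASSIFIED]
    well_codes, _ = pd.factorize(classified["well_id"], sort=True)
    regions = classified["region"].to_numpy()
    reporters = classified["reporter"].to_numpy()

    # sort once by (well, region) and slice contiguous blocks
    key = well_codes.astype(np.int64) * (int(regions.max()) + 2) + regions
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    starts = np.flatnonzero(np.r_[True, sorted_key[1:] != sorted_key[:-1]])
    ends = np.r_[starts[1:], sorted_key.size]
    sorted_reporters = reporters[order]

    first_rows = classified.iloc[order[starts]]
    dists: list[BeadDistribution] = []
    for row, s, e in zip(first_rows.itertuples(index=False), starts, ends):
        probe = probe_of_well[str(row.well_id)]
        ip = ip_of_region[row.region] if ip_of_region is not None else str(row.region)
        dists.append(
            BeadDistribution(
                interaction=f"{ip}_{probe}",
                sample_id=str(row.sample_id),
                experiment=row.experiment,
                condition=str(row.condition),
                replicate=row.replicate,
                reporters=sorted_reporters[s:e].copy(),
            )
        )
    return dists


def compute_mfi(dist: BeadDistribution | np.ndarray | Sequence[float]) -> float:
    """Median fluorescence intensity of a bead distribution.

    Even-length distributions use the midpoint of the two central order
    statistics.
    """
    values = dist.reporters if isinstance(dist, BeadDistribution) else np.asarray(dist, float)
    if values.size == 0:
        raise ValueError("cannot compute MFI of an empty distribution")
    return float(np.median(values))


def mfi_matrix_from_distributions(dists: Sequence[BeadDistribution]) -> MFIMatrix:
    """Collapse bead distributions into an interactions x samples MFI matrix.

    Columns are technical-replicate wells (sample ids); duplicate wells for
    the same interaction and sample are pooled at the event level before the
    median is taken, so a (interaction, sample) cell is the MFI of all its
    beads.
    """
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    meta: dict[str, dict] = {}
    for d in dists:
        pooled.setdefault((d.interaction, d.sample_id), []).append(d.reporters)
        meta.setdefault(
            d.sample_id,
            {
                "condition": d.condition,
                "experiment": d.experiment,
                "replicate": d.replicate,
            },
        )
    interactions = sorted({k[0] for k in pooled})
    sample_ids = sorted(meta)
    values = pd.DataFrame(np.nan, index=interactions, columns=sample_ids)
    for (interaction, sample_id), chunks in pooled.items():
        values.at[interaction, sample_id] = compute_mfi(np.concatenate(chunks))
    samples = pd.DataFrame.from_dict(meta, orient="index").loc[sample_ids]
    samples.index.name = "sample_id"
    return MFIMatrix(values, samples)


def average_replicates(
    matrix: MFIMatrix, group_cols: tuple[str, ...] = ("experiment", "condition")
) -> MFIMatrix:
    """Average MFIs across technical replicates of the same biological sample.

    Replicate wells are grouped by ``group_cols`` (experiment and condition
    by default); each group collapses to one column holding the arithmetic
    mean.  Raises if the replicate annotation is absent.
    """
    if "replicate" not in matrix.samples.columns:
        raise ValueError("sample annotations lack a replicate column")
    for col in group_cols:
        if col not in matrix.samples.columns:
            raise ValueError(f"sample annotations lack column {col!r}")

    groups = matrix.samples.groupby(list(group_cols), sort=True, observed=True)
    cols, new_meta = {}, {}
    for key, sub in groups:
        key_t = key if isinstance(key, tuple) else (key,)
        label = "_".join(str(k) for k in key_t)
        cols[label] = matrix.values[sub.index].mean(axis=1)
        new_meta[label] = {c: sub.iloc[0][c] for c in group_cols}
        new_meta[label]["n_replicates"] = len(sub)
    values = pd.DataFrame(cols)
    samples = pd.DataFrame.from_dict(new_meta, orient="index").loc[values.columns]
    samples.index.name = "sample_id"
    return MFIMatrix(values, samples, log2_scale=matrix.log2_scale)


def igg_background(igg_mfis: Mapping[str, float] | Sequence[float]) -> float:
    """Mean IgG-control MFI across detergent conditions (assay background)."""
    values = (
        list(igg_mfis.values()) if isinstance(igg_mfis, Mapping) else list(igg_mfis)
    )
    if not values:
        raise ValueError("need at least one IgG control MFI")
    return float(np.mean(values))


def solubility_fraction(m: SolubilityMeasurement) -> tuple[float, float]:
    """Fraction of a protein in lysate vs pellet from band densitometry.

    Each band density is divided by the total; the two fractions sum to 1.
    """
    total = m.lysate_density + m.pellet_density
    return m.lysate_density / total, m.pellet_density / total


def pool_fractions(
    dists: Sequence[BeadDistribution | np.ndarray], pool_size: int = 4
) -> list[BeadDistribution | np.ndarray]:
    """Pool ordered SEC fractions in contiguous blocks of ``pool_size``.

    Reporter multisets of each block are concatenated; pools are labelled
    by their fraction range ("1-4", "5-8", ...).  A trailing short block
    forms its own pool.
    """
    if len(dists) == 0:
        raise ValueError("no fractions to pool")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    pools = []
    for start in range(0, len(dists), pool_size):
        block = dists[start : start + pool_size]
        label = f"{start + 1}-{start + len(block)}"
        if isinstance(block[0], BeadDistribution):
            proto = block[0]
            pools.append(
                BeadDistribution(
                    interaction=proto.interaction,
                    sample_id=label,
                    experiment=proto.experiment,
                    condition=proto.condition,
                    replicate=proto.replicate,
                    reporters=np.concatenate([b.reporters for b in block]),
                )
            )
        else:
            pools.append(np.concatenate([np.asarray(b, float) for b in block]))
    return pools
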
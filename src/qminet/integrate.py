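"""Merging ANC with CNA and the summary computations around them.

The high-confidence interaction set is the intersection of the two
independent statistical routes: an interaction must be a replicated ANC hit
*and* belong to a trait-associated network module with an FDR-adjusted
probability of module membership below 0.05.  The module also provides the
figure-level computations: collapsing multiple epitope measurements of a
protein pair to the largest absolute log2 fold change, the 10 %-change
detection mask, Ward/Euclidean hierarchical clustering of samples with
approximately-unbiased (AU) cluster support from multiscale bootstrap
resampling, principal component analysis, per-row z-scoring for heatmaps,
and node-edge network export (SIF / GraphML / CSV).
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .anc import ANCHit
from .cna import ModuleSet
from .containers import MFIMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HighConfidenceSet",
    "ClusterTree",
    "Edge",
    "NetworkDiagram",
    "merge_anc_cna",
    "collapse_epitopes",
    "detection_mask",
    "ward_tree",
    "au_pvalues",
    "fit_multiscale",
    "pca_scores",
    "heatmap_row_normalize",
    "export_network",
    "read_network",
]


@dataclass
class HighConfidenceSet:
    """Interactions significant by both ANC and CNA."""

    interactions: list[str]
    log2_fc: dict[str, float]
    direction: dict[str, int]
    counts: dict[str, int]  # anc_hits, cna_members, merged


@dataclass
class ClusterTree:
    """Ward merge tree over samples, optionally with AU/BP support."""

    linkage_matrix: np.ndarray
    leaves: list[str]
    au: np.ndarray | None = None  # percent, one per internal node
    bp: np.ndarray | None = None
    never_observed: np.ndarray | None = None

    def cluster_members(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node, in merge order."""
        n = len(self.leaves)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.leaves[i]]) for i in range(n)
        }
        out = []
        for j, row in enumerate(self.linkage_matrix):
            s = members[int(row[0])] | members[int(row[1])]
            members[n + j] = s
            out.append(s)
        return out


@dataclass(frozen=True)
class Edge:
    """A protein-pair edge of a QMI map."""

    protein_a: str
    protein_b: str
    log2_fc: float
    significant: bool = True
    measurement: str = ""

    @property
    def direction(self) -> str:
        return "increase" if self.log2_fc >= 0 else "decrease"

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))


@dataclass
class NetworkDiagram:
    """Node-edge diagram: at most one edge per unordered protein pair."""

    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [e.pair for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("more than one edge for a protein pair")


def merge_anc_cna(
    anc_hits: Sequence[ANCHit],
    modules: ModuleSet,
    trait_flags: Mapping[str, bool] | None = None,
) -> HighConfidenceSet:
    """Intersect ANC hits with trait-associated CNA module members.

    ``trait_flags`` (module -> associated?) defaults to the module set's own
    trait-correlation significance.  CNA membership requires an FDR-adjusted
    p.MM below 0.05 in a trait-associated module.  Counts for each criterion
    are reported separately in ``counts``.
    """
    if trait_flags is None:
        if modules.module_trait is None:
            raise ValueError("module set has no trait correlations")
        trait_flags = modules.module_trait["significant"].to_dict()

    hit_names = {h.interaction for h in anc_hits}
    cna_members: set[str] = set()
    if modules.membership is not None:
        mm = modules.membership
        for name, row in mm.iterrows():
            if trait_flags.get(row["module"], False) and row["p_mm_adj"] < 0.05:
                cna_members.add(name)

    if hit_names and not (set(modules.labels.index) & hit_names):
        raise ValueError("ANC and CNA cover disjoint interaction universes")

    merged = sorted(hit_names & cna_members)
    by_name = {h.interaction: h for h in anc_hits}
    return HighConfidenceSet(
        interactions=merged,
        log2_fc={n: by_name[n].mean_log2_fc for n in merged},
        direction={n: by_name[n].direction for n in merged},
        counts={
            "anc_hits": len(hit_names),
            "cna_members": len(cna_members),
            "merged": len(merged),
        },
    )


def collapse_epitopes(
    hits: Mapping[tuple[tuple[str, str], str], float],
) -> list[Edge]:
    """One edge per protein pair: keep the largest absolute log2 fold change.

    ``hits`` maps ((protein_a, protein_b), measurement_name) to a log2 fold
    change; different epitope combinations of the same unordered pair
    collapse to the measurement of maximal \\|log2 FC\\|, ties broken by
    lexicographic measurement name (and logged).
    """
    grouped: dict[frozenset[str], list[tuple[str, tuple[str, str], float]]] = {}
    for (pair, measurement), fc in hits.items():
        grouped.setdefault(frozenset(pair), []).append((measurement, pair, fc))
    edges = []
    for pair_set, entries in grouped.items():
        entries.sort(key=lambda e: (-abs(e[2]), e[0]))
        if len(entries) > 1 and abs(entries[0][2]) == abs(entries[1][2]):
            logger.info(
                "epitope collapse tie on %s: kept %s", set(pair_set), entries[0][0]
            )
        measurement, pair, fc = entries[0]
        edges.append(
            Edge(
                protein_a=pair[0],
                protein_b=pair[1],
                log2_fc=fc,
                measurement=measurement,
            )
        )
    return sorted(edges, key=lambda e: (e.protein_a, e.protein_b))


def detection_mask(
    log2_fcs: Sequence[float] | np.ndarray, threshold_percent: float = 10.0
) -> np.ndarray:
    """Flag fold changes below the assay's detection limit.

    A change is below detection when the fold change differs from 1 by
    strictly less than ``threshold_percent`` on the log scale, i.e.
    \\|log2 fc\\| < log2(1 + threshold/100).  A symmetric rule: fc and 1/fc
    receive the same flag, and the exact boundary is not masked.
    """
    if threshold_percent < 0:
        raise ValueError("threshold must be >= 0")
    cut = np.log2(1.0 + threshold_percent / 100.0)
    return np.abs(np.asarray(log2_fcs, float)) < cut


def ward_tree(matrix: MFIMatrix) -> ClusterTree:
    """Ward-linkage hierarchical clustering of samples (Euclidean distance).

    Clusters the sample columns of a (log2, batch-corrected) matrix.  Tie
    merges follow scipy's deterministic lowest-index rule, so the tree is
    reproducible for a given column order and the topology is invariant to
    permuting sample order.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("clustering needs >= 3 samples")
    if matrix.values.columns.has_duplicates:
        raise ValueError("duplicate sample names")
    X = matrix.values.to_numpy(float).T  # samples x features
    Z = linkage(pdist(X, metric="euclidean"), method="ward")
    return ClusterTree(linkage_matrix=Z, leaves=list(matrix.values.columns))


def _cluster_sets_from_linkage(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for j, row in enumerate(Z):
        s = members[int(row[0])] | members[int(row[1])]
        members[n + j] = s
        out.append(s)
    return out


def fit_multiscale(
    scales: np.ndarray, bp: np.ndarray, n_boot: int
) -> tuple[float, float]:
    """Fit the multiscale-bootstrap model to per-scale bootstrap probabilities.

    Weighted least squares of ``z(r) = norminv(1 - BP(r)) = v*sqrt(r) +
    c/sqrt(r)``; returns the signed distance ``v`` and curvature ``c``.  The
    AU support is ``1 - Phi(v - c)`` and the plain bootstrap probability at
    r = 1 corresponds to ``1 - Phi(v + c)``.
    """
    bp = np.clip(np.asarray(bp, float), 0.5 / n_boot, 1.0 - 0.5 / n_boot)
    z = stats.norm.ppf(1.0 - bp)
    sq = np.sqrt(np.asarray(scales, float))
    X = np.column_stack([sq, 1.0 / sq])
    w = n_boot * stats.norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    WX = X * w[:, None]
    coef = np.linalg.solve(X.T @ WX, WX.T @ z)
    return float(coef[0]), float(coef[1])


def au_pvalues(
    matrix: MFIMatrix,
    tree: ClusterTree,
    scales: Sequence[float] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2)),
    n_boot: int = 1000,
    seed: int = 0,
) -> ClusterTree:
    """Approximately-unbiased cluster support by multiscale bootstrap.

    For each scale r, ``n_boot`` resamples of ``ceil(r * n_features)``
    interactions (features) are drawn with replacement, the samples are
    re-clustered (Ward/Euclidean), and BP(r) is the fraction of resampled
    trees containing each original cluster.  ``z(BP)`` is fitted against
    ``v*sqrt(r) + c/sqrt(r)`` by weighted least squares and
    ``AU = 100 * (1 - Phi(v - c))``.  Clusters recovered in every resample
    at every scale get AU = 100; clusters never recovered get AU = 0 and
    are flagged in ``never_observed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    X = matrix.values.to_numpy(float)
    n_features, n_samples = X.shape
    original = [
        frozenset(tree.leaves.index(s) for s in cl) for cl in tree.cluster_members()
    ]
    n_clusters = len(original)
    scales_arr = np.asarray(scales, float)
    counts = np.zeros((len(scales_arr), n_clusters), dtype=np.int64)
    for si, r in enumerate(scales_arr):
        m = max(int(np.ceil(r * n_features)), 2)
        for _ in range(n_boot):
            idx = rng.integers(0, n_features, size=m)
            Zb = linkage(pdist(X[idx].T, metric="euclidean"), method="ward")
            found = set(_cluster_sets_from_linkage(Zb, n_samples))
            for ci, cl in enumerate(original):
                if cl in found:
                    counts[si, ci] += 1
    bp_all = counts / n_boot

    au = np.empty(n_clusters)
    bp_at_1 = np.empty(n_clusters)
    never = np.zeros(n_clusters, dtype=bool)
    at_one = int(np.argmin(np.abs(scales_arr - 1.0)))
    for ci in range(n_clusters):
        bp_c = bp_all[:, ci]
        bp_at_1[ci] = 100.0 * bp_c[at_one]
        if np.all(bp_c == 1.0):
            au[ci] = 100.0
        elif np.all(bp_c == 0.0):
            au[ci] = 0.0
            never[ci] = True
        else:
            v, c = fit_multiscale(scales_arr, bp_c, n_boot)
            au[ci] = 100.0 * (1.0 - stats.norm.cdf(v - c))
    return ClusterTree(
        linkage_matrix=tree.linkage_matrix,
        leaves=tree.leaves,
        au=au,
        bp=bp_at_1,
        never_observed=never,
    )


def pca_scores(
    matrix: MFIMatrix, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples: centered (optionally unit-variance) SVD scores.

    Rows of the returned frame are samples, columns principal components;
    the second return value is the explained-variance fraction per
    component (summing to 1).
    """
    X = matrix.values.to_numpy(float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        keep = sd > 0
        if keep.sum() < 2:
            raise ValueError("fewer than 2 non-constant features")
        Xc = Xc[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    explained = s**2 / (s**2).sum() if (s**2).sum() > 0 else np.zeros_like(s)
    frame = pd.DataFrame(
        scores,
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return frame, explained


def heatmap_row_normalize(matrix: MFIMatrix) -> MFIMatrix:
    """Per-row z-score for heatmap display of analytes spanning a 3-log range.

    Constant rows map to zero with a warning.  Idempotent on already
    normalised rows.
    """
    X = matrix.values.to_numpy(float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        import warnings

        warnings.warn(f"{int(constant.sum())} constant rows mapped to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[constant] = 0.0
    values = pd.DataFrame(Z, index=matrix.values.index, columns=matrix.values.columns)
    return MFIMatrix(values, matrix.samples.copy(), log2_scale=matrix.log2_scale)


_SIF_RELATION = "interacts"


def export_network(diagram: NetworkDiagram, path: str | Path, format: str = "sif") -> Path:
    """Write a node-edge diagram for Cytoscape-style tools.

    ``sif`` writes "proteinA interacts proteinB" lines plus an attribute
    table next to it (``<stem>.attrs.csv``); ``graphml`` embeds the
    attributes; ``csv`` writes a single edge table.  All formats round-trip
    through :func:`read_network`.
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for e in diagram.edges:
                fh.write(f"{e.protein_a}\t{_SIF_RELATION}\t{e.protein_b}\n")
        _write_edge_csv(diagram, path.with_suffix(".attrs.csv"))
    elif format == "csv":
        _write_edge_csv(diagram, path)
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for e in diagram.edges:
            g.add_edge(
                e.protein_a,
                e.protein_b,
                log2_fc=e.log2_fc,
                direction=e.direction,
                significant=e.significant,
                measurement=e.measurement,
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _write_edge_csv(diagram: NetworkDiagram, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["protein_a", "protein_b", "log2_fc", "direction", "significant", "measurement"]
        )
        for e in diagram.edges:
            writer.writerow(
                [e.protein_a, e.protein_b, repr(e.log2_fc), e.direction,
                 int(e.significant), e.measurement]
            )


def read_network(path: str | Path, format: str = "sif") -> NetworkDiagram:
    """Read a diagram written by :func:`export_network`."""
    path = Path(path)
    if format == "sif":
        return _read_edge_csv(path.with_suffix(".attrs.csv"))
    if format == "csv":
        return _read_edge_csv(path)
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        edges = [
            Edge(
                protein_a=a,
                protein_b=b,
                log2_fc=float(d["log2_fc"]),
                significant=bool(d["significant"]),
                measurement=d.get("measurement", ""),
            )
            for a, b, d in g.edges(data=True)
        ]
        return NetworkDiagram(sorted(edges, key=lambda e: (e.protein_a, e.protein_b)))
    raise ValueError(f"unknown format {format!r}")


def _read_edge_csv(path: Path) -> NetworkDiagram:
    edges = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            edges.append(
                Edge(
                    protein_a=row["protein_a"],
                    protein_b=row["protein_b"],
                    log2_fc=float(row["log2_fc"]),
                    significant=bool(int(row["significant"])),
                    measurement=row["measurement"],
                )
            )
    return NetworkDiagram(edges)
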
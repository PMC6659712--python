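"""Correlation network analysis (CNA) of MFI matrices.

The network pipeline mirrors weighted correlation network analysis as used
on QMI data: remove weakly detected interactions (MFI below the assay
background in every sample), remove experiment-to-experiment batch effects
with a parametric empirical-Bayes location/scale model (ComBat), log2
transform, raise absolute Pearson correlations to a soft-threshold power
chosen for approximate scale-free topology, convert to topological overlap,
cluster interactions into colour-named modules, and summarise each module by
its eigengene (first principal component).  Modules whose eigengene
correlates with a binary experimental trait are trait-associated; their
members of interest are those with an FDR-adjusted probability of module
membership (p.MM) below 0.05.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import MFIMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkModel",
    "ModuleSet",
    "noise_filter",
    "combat_adjust",
    "log2_transform",
    "pick_soft_threshold",
    "adjacency_tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "module_membership",
    "run_cna",
]

#: Colour sequence for module naming, largest module first; "grey" is reserved
#: for unassigned interactions.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
]

UNASSIGNED = "grey"


@dataclass
class NetworkModel:
    """Soft-thresholded adjacency and topological overlap of a panel."""

    power: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    fit_table: pd.DataFrame | None = None  # per-candidate-power scale-free fit


@dataclass
class ModuleSet:
    """Module assignments, eigengenes, trait correlations and membership."""

    labels: pd.Series  # interaction -> colour
    eigengenes: pd.DataFrame | None = None  # module x sample
    module_trait: pd.DataFrame | None = None  # module, r, p, significant
    membership: pd.DataFrame | None = None  # interaction, module, kME, p_mm, p_mm_adj

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def noise_filter(matrix: MFIMatrix, floor: float = 100.0) -> MFIMatrix:
    """Drop interactions whose MFI is below ``floor`` in every sample.

    Interactions detected above background in at least one sample are kept
    unchanged.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    keep = (matrix.values >= floor).any(axis=1)
    if not keep.any():
        raise ValueError("noise filter removed every interaction")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("noise filter removed %d weakly detected interactions", n_removed)
    return MFIMatrix(
        matrix.values.loc[keep].copy(), matrix.samples.copy(), matrix.log2_scale
    )


def _combat_it_sol(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    t2: float,
    a_prior: float,
    b_prior: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB posterior solution for one batch (location and scale)."""
    n_b = z_batch.shape[1]
    gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n_b * gamma_hat + delta_star * gamma_bar) / (
            t2 * n_b + delta_star
        )
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - gamma_star).max(initial=0.0),
            np.abs(d_new - delta_star).max(initial=0.0),
        )
        gamma_star, delta_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star


def combat_adjust(matrix: MFIMatrix, batches: Sequence | None = None) -> MFIMatrix:
    """Remove batch effects with the parametric empirical-Bayes ComBat model.

    Each interaction is standardised against its grand mean and pooled
    variance; per-batch location and scale deviations are estimated and
    shrunk toward the across-interaction priors (normal prior on locations,
    inverse-gamma on scales, moment-matched), then divided out.  A single
    batch returns the input unchanged; a batch with one sample triggers a
    location-only fallback for that batch since its scale is inestimable.
    """
    if batches is None:
        batches = matrix.samples["experiment"]
    batch_arr = np.asarray(batches)
    if batch_arr.size != matrix.values.shape[1]:
        raise ValueError("batch labels must match the number of samples")
    levels = pd.unique(batch_arr)
    if len(levels) == 1:
        return matrix.copy()

    X = matrix.values.to_numpy(float)
    n_genes, n_array = X.shape
    idx_per_batch = [np.flatnonzero(batch_arr == lev) for lev in levels]
    sizes = np.array([len(ix) for ix in idx_per_batch])
    singleton = sizes == 1
    if singleton.any():
        warnings.warn(
            "batch with a single sample: location-only adjustment for it",
            stacklevel=2,
        )

    batch_means = np.stack([X[:, ix].mean(axis=1) for ix in idx_per_batch], axis=1)
    grand_mean = batch_means @ (sizes / n_array)
    batch_of_sample = np.empty(n_array, dtype=int)
    for b, ix in enumerate(idx_per_batch):
        batch_of_sample[ix] = b
    resid = X - batch_means[:, batch_of_sample]
    var_pooled = (resid**2).sum(axis=1) / n_array
    var_pooled = np.maximum(var_pooled, 1e-12)

    Z = (X - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    Z_adj = Z.copy()
    gamma_hat = np.stack([Z[:, ix].mean(axis=1) for ix in idx_per_batch], axis=1)
    delta_hat = np.stack(
        [
            Z[:, ix].var(axis=1, ddof=1) if len(ix) > 1 else np.ones(n_genes)
            for ix in idx_per_batch
        ],
        axis=1,
    )
    for b, ix in enumerate(idx_per_batch):
        g_hat, d_hat = gamma_hat[:, b], np.maximum(delta_hat[:, b], 1e-12)
        if singleton[b]:
            g_star, d_star = g_hat, np.ones(n_genes)
        else:
            gamma_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
            m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
            if t2 <= 1e-12 or s2 <= 1e-12 or n_genes < 3:
                # degenerate priors (e.g. noiseless constructions): no shrinkage
                g_star, d_star = g_hat, d_hat
            else:
                a_prior = (2.0 * s2 + m**2) / s2
                b_prior = (m * s2 + m**3) / s2
                g_star, d_star = _combat_it_sol(
                    Z[:, ix], g_hat, d_hat, gamma_bar, t2, a_prior, b_prior
                )
        Z_adj[:, ix] = (Z[:, ix] - g_star[:, None]) / np.sqrt(
            np.maximum(d_star, 1e-12)
        )[:, None]

    X_adj = Z_adj * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    values = pd.DataFrame(
        X_adj, index=matrix.values.index, columns=matrix.values.columns
    )
    return MFIMatrix(values, matrix.samples.copy(), matrix.log2_scale)


def log2_transform(matrix: MFIMatrix) -> MFIMatrix:
    """Elementwise log2; values below 1 a.u. are clipped to 1 with a warning."""
    X = matrix.values.to_numpy(float)
    n_clipped = int((X < 1.0).sum())
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} values below 1 a.u. before log2", stacklevel=2)
        X = np.maximum(X, 1.0)
    values = pd.DataFrame(
        np.log2(X), index=matrix.values.index, columns=matrix.values.columns
    )
    return MFIMatrix(values, matrix.samples.copy(), log2_scale=True)


def _drop_constant_rows(values: pd.DataFrame) -> pd.DataFrame:
    sd = values.std(axis=1, ddof=1)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"removed {int(constant.sum())} constant interactions before correlation",
            stacklevel=3,
        )
        values = values.loc[~constant]
    return values


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit of a connectivity vector.

    Connectivities are binned (equal-width), the log10 frequency is
    regressed on the log10 mean connectivity per occupied bin, and the R^2
    is negated when the slope is positive (a scale-free network requires a
    decreasing frequency in k).  Degenerate connectivity (fewer than two
    occupied bins) counts as a perfect fit.
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if k.size == 0 or np.ptp(k) <= 1e-12:
        return 1.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    occupied = np.flatnonzero(counts > 0)
    if occupied.size < 2:
        return 1.0
    mean_k = np.array([k[which == b].mean() for b in occupied])
    freq = counts[occupied] / k.size
    slope, _, r, _, _ = stats.linregress(np.log10(mean_k), np.log10(freq))
    return float(np.sign(-slope) * r**2)


def pick_soft_threshold(
    matrix: MFIMatrix,
    powers: Sequence[float] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    min_mean_k_frac: float = 0.01,
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power approximating scale-free topology.

    Returns the smallest candidate power whose signed scale-free fit R^2
    reaches ``r2_target``; if none does, the power with the largest R^2.
    Candidates whose mean connectivity falls below ``min_mean_k_frac`` of
    the maximum possible (n - 1) are excluded: past that density the
    network is so sparse that any connectivity histogram looks scale-free
    while the topological overlap degenerates (set the fraction to 0 to
    disable the guard).  Also returns the per-power fit table.
    """
    if len(powers) == 0:
        raise ValueError("no candidate powers")
    values = _drop_constant_rows(matrix.values)
    if matrix.values.shape[1] < 8:
        warnings.warn("fewer than 8 samples; correlations are unstable", stacklevel=2)
    cor = np.abs(np.corrcoef(values.to_numpy(float)))
    rows = []
    for beta in powers:
        a = cor**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"power": beta, "r2": scale_free_fit(k), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    k_floor = min_mean_k_frac * (len(values) - 1)
    admissible = table[table["mean_k"] >= k_floor]
    if admissible.empty:
        admissible = table.iloc[:1]  # densest candidate is the first power
    good = admissible[admissible["r2"] >= r2_target]
    if not good.empty:
        beta = float(good.iloc[0]["power"])
    else:
        # no candidate reaches the target: prefer the smallest power whose
        # fit is within 0.1 of the best admissible one (parsimony; higher
        # powers only sparsify the network without improving the fit)
        near = admissible[admissible["r2"] >= admissible["r2"].max() - 0.1]
        beta = float(near.iloc[0]["power"])
    return beta, table


def adjacency_tom(matrix: MFIMatrix, beta: float) -> NetworkModel:
    """Unsigned power adjacency and topological overlap matrix.

    ``a_ij = |cor(x_i, x_j)|^beta`` with unit diagonal;
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    connectivity ``k_i = sum_{u != i} a_iu`` and unit diagonal.
    """
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    values = _drop_constant_rows(matrix.values)
    names = values.index
    cor = np.corrcoef(values.to_numpy(float))
    if not np.all(np.isfinite(cor)):
        raise ValueError("non-finite correlations")
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)

    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    numer = a0 @ a0 + a0  # sum_{u != i,j} a_iu a_uj + a_ij (diag terms are zero)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    adj = pd.DataFrame(a, index=names, columns=names)
    return NetworkModel(
        power=beta, adjacency=adj, tom=pd.DataFrame(tom, index=names, columns=names)
    )


def detect_modules(
    net: NetworkModel, min_size: int = 6, cut_height: float | None = None
) -> ModuleSet:
    """Cluster interactions into modules on topological-overlap dissimilarity.

    Average-linkage hierarchical clustering of ``1 - TOM``; the tree is cut
    at ``cut_height`` (default 0.99 of the maximum merge height) and
    branches smaller than ``min_size`` fall into the unassigned "grey"
    class.  Modules are named by a fixed colour sequence, largest first.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    tom = net.tom.to_numpy(float)
    names = net.tom.index
    if len(names) < min_size:
        raise ValueError("fewer interactions than min_size")
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    height = (
        0.99 * Z[:, 2].max() if cut_height is None else cut_height
    )
    raw = fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=names, dtype=object)
    sizes = pd.Series(raw).value_counts()
    color_iter = iter(MODULE_COLORS)
    for cluster_id in sizes.index:  # value_counts sorts largest first
        if sizes[cluster_id] < min_size:
            continue
        labels.iloc[np.flatnonzero(raw == cluster_id)] = next(color_iter)
    return ModuleSet(labels=labels)


def module_eigengene(matrix: MFIMatrix, members: Sequence[str]) -> pd.Series:
    """First principal component of the row-standardised member submatrix.

    The eigengene is a unit-norm, sample-indexed vector, sign-oriented so
    its correlation with the members' average standardised profile is
    positive.  Zero-variance members are dropped.
    """
    members = [m for m in members if m in matrix.values.index]
    if len(members) < 2:
        raise ValueError("a module eigengene needs >= 2 members")
    sub = matrix.values.loc[members].to_numpy(float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} zero-variance members", stacklevel=2
        )
        sub, sd = sub[keep], sd[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    if np.corrcoef(eig, z.mean(axis=0))[0, 1] < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.values.columns, name="eigengene")


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: Sequence[float] | np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a binary trait.

    ``trait`` is the coded trait vector (e.g. stimulated 1 vs control 0)
    over the eigengene samples; p-values come from the t-distribution with
    n - 2 degrees of freedom.  Modules with p < 0.05 are flagged
    trait-associated.
    """
    t = np.asarray(trait, float)
    if np.ptp(t) == 0:
        raise ValueError("trait must have both classes")
    rows = []
    for module, eig in eigengenes.iterrows():
        r, p = stats.pearsonr(eig.to_numpy(float), t)
        rows.append({"module": module, "r": r, "p": p, "significant": p < 0.05})
    return pd.DataFrame(rows).set_index("module")


def module_membership(
    matrix: MFIMatrix, eigengene: pd.Series, fdr: float = 0.05
) -> pd.DataFrame:
    """kME and p.MM of every interaction against one module eigengene.

    kME is the Pearson correlation of the interaction's profile with the
    eigengene; p.MM its two-sided correlation-test p-value,
    Benjamini-Hochberg adjusted across interactions.  Members of interest
    are those with adjusted p.MM < ``fdr``.
    """
    eig = eigengene.to_numpy(float)
    kme, pmm = [], []
    for name, row in matrix.values.iterrows():
        x = row.to_numpy(float)
        if x.std(ddof=1) == 0:
            raise ValueError(f"zero-variance profile: {name}")
        r, p = stats.pearsonr(x, eig)
        kme.append(r)
        pmm.append(p)
    _, p_adj, _, _ = multipletests(pmm, alpha=fdr, method="fdr_bh")
    return pd.DataFrame(
        {
            "kME": kme,
            "p_mm": pmm,
            "p_mm_adj": p_adj,
            "member_of_interest": p_adj < fdr,
        },
        index=matrix.values.index,
    )


def run_cna(
    matrix: MFIMatrix,
    trait: Sequence[float] | np.ndarray,
    floor: float = 100.0,
    min_module_size: int = 6,
    powers: Sequence[float] = tuple(range(1, 21)),
    combat: bool = True,
    log2_before_combat: bool = False,
) -> tuple[ModuleSet, NetworkModel, MFIMatrix]:
    """End-to-end CNA: filter, batch-correct, transform, network, modules.

    Batch correction runs on raw MFIs with the log2 transform afterwards
    (the pipeline's stated order); set ``log2_before_combat`` for the more
    conventional order.  Returns the module set (with eigengenes, trait
    correlations and membership of trait-associated modules), the network
    model, and the processed expression matrix.
    """
    m = noise_filter(matrix, floor=floor)
    if log2_before_combat:
        m = log2_transform(m)
    if combat and m.samples["experiment"].nunique() > 1:
        m = combat_adjust(m)
    if not m.log2_scale:
        m = log2_transform(m)

    beta, fit_table = pick_soft_threshold(m, powers=powers)
    net = adjacency_tom(m, beta)
    net.fit_table = fit_table
    modules = detect_modules(net, min_size=min_module_size)

    eig_rows = {}
    for module in modules.modules:
        eig_rows[module] = module_eigengene(m, modules.members(module))
    if eig_rows:
        modules.eigengenes = pd.DataFrame(eig_rows).T
        modules.module_trait = module_trait_correlation(modules.eigengenes, trait)
        member_frames = []
        for module in modules.modules:
            mm = module_membership(m, modules.eigengenes.loc[module])
            mm.insert(0, "module", module)
            member_frames.append(mm.loc[modules.members(module)])
        modules.membership = pd.concat(member_frames) if member_frames else None
    return modules, net, m
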
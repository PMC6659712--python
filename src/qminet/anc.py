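"""Adaptive nonparametric hit calling (ANC) for QMI bead distributions.

Each interaction is tested per experiment by a two-sample distribution test
on bead-level reporter values (Kolmogorov-Smirnov by default; Mann-Whitney
available).  The per-experiment significance cutoff combines a Bonferroni
correction over the panel with an empirical calibration from technical-
replicate null comparisons, so the expected number of null calls across the
panel stays at the family alpha.  An interaction becomes a hit when it is
individually significant, with a consistent fold-change direction, in more
than 70 % of experiments (e.g. 3 of 4).

The module also provides the Bonferroni-adjusted Mann-Whitney family used
for small sets of single-plex MFI comparisons.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import BeadDistribution
from .preprocess import compute_mfi

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "AlphaCutoff",
    "ANCHit",
    "ANCResult",
    "distribution_test",
    "bonferroni_alpha",
    "empirical_alpha",
    "fold_change",
    "call_hits",
    "adjusted_mannwhitney_family",
    "run_anc",
]


@dataclass
class ComparisonResult:
    """One interaction's treated-vs-control test within one experiment."""

    interaction: str
    experiment: int | str
    p_value: float
    mfi_control: float
    mfi_treated: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def fold_change(self) -> float:
        return self.mfi_treated / self.mfi_control

    @property
    def log2_fc(self) -> float:
        return float(np.log2(self.fold_change))


@dataclass(frozen=True)
class AlphaCutoff:
    """Per-experiment significance cutoff: Bonferroni plus empirical calibration."""

    alpha_family: float
    n_comparisons: int
    alpha_bonferroni: float
    alpha_empirical: float

    @property
    def alpha_adj(self) -> float:
        return min(self.alpha_bonferroni, self.alpha_empirical)

    def __post_init__(self) -> None:
        if not 0 < self.alpha_adj <= self.alpha_bonferroni <= self.alpha_family:
            raise ValueError("require 0 < alpha_adj <= alpha_bonferroni <= alpha_family")


@dataclass
class ANCHit:
    """A replicated, direction-consistent significant interaction."""

    interaction: str
    experiments_significant: tuple
    replication_fraction: float
    direction: int  # +1 increase, -1 decrease
    mean_fold_change: float
    mean_log2_fc: float
    floor_limited: bool = False


@dataclass
class ANCResult:
    """Full output of an ANC run."""

    comparisons: pd.DataFrame
    alpha: AlphaCutoff
    hits: list[ANCHit]
    null_pvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def hit_interactions(self) -> set[str]:
        return {h.interaction for h in self.hits}


def distribution_test(
    a: BeadDistribution | np.ndarray,
    b: BeadDistribution | np.ndarray,
    method: str = "ks",
) -> float:
    """Two-sided two-sample test on bead-level reporter values.

    ``method="ks"`` runs the two-sample Kolmogorov-Smirnov test (exact for
    small samples, asymptotic otherwise); ``method="mann_whitney"`` the
    Mann-Whitney U test.
    """
    xa = a.reporters if isinstance(a, BeadDistribution) else np.asarray(a, float)
    xb = b.reporters if isinstance(b, BeadDistribution) else np.asarray(b, float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("distribution test requires non-empty samples")
    if min(xa.size, xb.size) < 5:
        warnings.warn("fewer than 5 beads per group; p-values are coarse", stacklevel=2)
    if method == "ks":
        return float(stats.ks_2samp(xa, xb).pvalue)
    if method == "mann_whitney":
        return float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    raise ValueError(f"unknown method {method!r}")


def _ks_many(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Asymptotic two-sample KS p-values for many pairs.

    Computes each D statistic with numpy and evaluates the Kolmogorov
    distribution with Stephens' small-sample correction,
    ``p = Q((sqrt(en) + 0.12 + 0.11/sqrt(en)) * D)``, vectorised over the
    panel.  Bead-level samples (hundreds of events) are deep in the
    asymptotic regime, and the empirical alpha calibration uses null
    p-values computed by this same path, so cutoffs are self-consistent.
    """
    d = np.empty(len(pairs))
    en = np.empty(len(pairs))
    for i, (xa, xb) in enumerate(pairs):
        na, nb = xa.size, xb.size
        sa, sb = np.sort(xa), np.sort(xb)
        # sup |F_a - F_b| over the jump points of both ECDFs; side="right"
        # evaluates each right-continuous ECDF after consuming ties
        fa_at_a = np.arange(1, na + 1) / na
        fb_at_a = np.searchsorted(sb, sa, side="right") / nb
        fa_at_b = np.searchsorted(sa, sb, side="right") / na
        fb_at_b = np.arange(1, nb + 1) / nb
        d[i] = max(
            np.abs(fa_at_a - fb_at_a).max(), np.abs(fa_at_b - fb_at_b).max()
        )
        en[i] = na * nb / (na + nb)
    root = np.sqrt(en)
    p = special.kolmogorov((root + 0.12 + 0.11 / root) * d)
    return np.clip(p, 0.0, 1.0)


def bonferroni_alpha(alpha_family: float, n: int) -> float:
    """Bonferroni-corrected per-comparison alpha."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return alpha_family / n


def empirical_alpha(
    null_pvalues: Sequence[float] | np.ndarray,
    alpha_bonferroni: float,
    n_comparisons: int,
    alpha_family: float = 0.05,
) -> float:
    """Calibrate the cutoff on technical-replicate null comparisons.

    Returns the largest alpha <= ``alpha_bonferroni`` at which the expected
    number of null calls across the panel — ``n_comparisons`` times the
    fraction of null p-values below alpha — stays at or below
    ``alpha_family``.  When no null comparison falls under the Bonferroni
    cutoff, no further adjustment is needed and the Bonferroni alpha is
    returned; otherwise the cutoff moves strictly below the first offending
    null p-value.
    """
    p = np.sort(np.asarray(null_pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("empirical calibration requires null p-values")
    if p.size < 20:
        warnings.warn(
            f"only {p.size} null comparisons; empirical alpha is unstable",
            stacklevel=2,
        )
    # largest tolerated count of null p-values below the cutoff
    k_max = int(np.floor(alpha_family / n_comparisons * p.size))
    n_below = int(np.searchsorted(p, alpha_bonferroni, side="left"))
    if n_below <= k_max:
        return alpha_bonferroni
    cutoff = np.nextafter(p[k_max], 0.0)  # strictly below the offending null
    return float(min(alpha_bonferroni, cutoff))


def fold_change(mfi_treated: float, mfi_control: float) -> tuple[float, float]:
    """Fold change and log2 fold change of treated vs control MFI."""
    if mfi_control <= 0:
        raise ValueError("control MFI must be > 0")
    fc = mfi_treated / mfi_control
    return fc, float(np.log2(fc))


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = [
        {
            "interaction": r.interaction,
            "experiment": r.experiment,
            "p_value": r.p_value,
            "mfi_control": r.mfi_control,
            "mfi_treated": r.mfi_treated,
            "fold_change": r.fold_change,
            "log2_fc": r.log2_fc,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def call_hits(
    results: pd.DataFrame | Sequence[ComparisonResult],
    alpha_adj: float,
    replication_threshold: float = 0.70,
    floor: float | None = None,
    floor_tolerance: float = 0.10,
) -> list[ANCHit]:
    """Call replicated hits from per-experiment comparison results.

    An interaction is a hit when the number of experiments in which it is
    individually significant (p < ``alpha_adj``) *and* shares the majority
    fold-change direction exceeds ``replication_threshold`` of all
    experiments (strict inequality: 3 of 4 qualifies at 0.70, 7 of 10 does
    not).  When ``floor`` is given, hits whose control MFI sits within
    ``floor_tolerance`` (relative) of the detection floor in every
    experiment are flagged ``floor_limited``: their fold changes are
    reported but not rankable.
    """
    frame = _as_frame(results)
    if frame.empty:
        return []
    per_exp = frame.groupby("experiment")["interaction"].apply(frozenset)
    if len(set(per_exp)) > 1:
        raise ValueError("experiments cover different interaction panels")
    n_experiments = frame["experiment"].nunique()
    if n_experiments < 2:
        raise ValueError("hit calling requires >= 2 experiments")

    hits: list[ANCHit] = []
    for interaction, sub in frame.groupby("interaction", sort=True):
        sig = sub[sub["p_value"] < alpha_adj]
        if sig.empty:
            continue
        signs = np.sign(sig["log2_fc"].to_numpy())
        n_pos, n_neg = int((signs > 0).sum()), int((signs < 0).sum())
        direction = 1 if n_pos >= n_neg else -1
        consistent = sig[np.sign(sig["log2_fc"]) == direction]
        frac = len(consistent) / n_experiments
        if frac > replication_threshold:
            floor_limited = False
            if floor is not None:
                floor_limited = bool(
                    (sub["mfi_control"] <= floor * (1 + floor_tolerance)).all()
                )
            hits.append(
                ANCHit(
                    interaction=interaction,
                    experiments_significant=tuple(consistent["experiment"]),
                    replication_fraction=frac,
                    direction=direction,
                    mean_fold_change=float(consistent["fold_change"].mean()),
                    mean_log2_fc=float(consistent["log2_fc"].mean()),
                    floor_limited=floor_limited,
                )
            )
    return hits


def adjusted_mannwhitney_family(
    mfi_groups: Sequence[tuple[Sequence[float], Sequence[float]]],
    alpha_family: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney U tests with a Bonferroni-adjusted per-comparison alpha.

    For a family of replicate-MFI comparisons, each two-sided U test is
    called significant at ``alpha_family / n_comparisons``, keeping the
    family-wise type-I error at or below ``alpha_family`` under the null.
    Returns one row per comparison with the p-value, cutoff and flag.
    """
    n = len(mfi_groups)
    if n == 0:
        raise ValueError("empty comparison family")
    alpha_per = bonferroni_alpha(alpha_family, n)
    rows = []
    for i, (a, b) in enumerate(mfi_groups):
        xa, xb = np.asarray(a, float), np.asarray(b, float)
        if min(xa.size, xb.size) < 2:
            raise ValueError("each group needs >= 2 values")
        p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append(
            {
                "comparison": i,
                "p_value": p,
                "alpha_per_comparison": alpha_per,
                "significant": p < alpha_per,
            }
        )
    return pd.DataFrame(rows)


def run_anc(
    dists: Sequence[BeadDistribution],
    control_condition: str,
    treated_condition: str,
    alpha_family: float = 0.05,
    method: str = "ks",
    replication_threshold: float = 0.70,
    floor: float | None = 100.0,
) -> ANCResult:
    """Full ANC pass over a set of bead distributions.

    Technical replicates are pooled at the event level per (interaction,
    experiment, condition); treated vs control distributions are tested per
    experiment.  Null p-values for the empirical calibration come from
    replicate-vs-replicate comparisons within the same condition.  The
    Bonferroni denominator is the number of interactions in the panel.
    """
    groups: dict[tuple[str, object, str], list[np.ndarray]] = {}
    for d in dists:
        groups.setdefault((d.interaction, d.experiment, d.condition), []).append(
            d.reporters
        )

    interactions = sorted({k[0] for k in groups})
    experiments = sorted({k[1] for k in groups})
    n_comparisons = len(interactions)

    test_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    test_meta: list[tuple[str, object, float, float]] = []
    null_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for interaction in interactions:
        for exp in experiments:
            ctrl = groups.get((interaction, exp, control_condition))
            trt = groups.get((interaction, exp, treated_condition))
            if ctrl is None or trt is None:
                raise ValueError(
                    f"missing condition for {interaction} in experiment {exp}"
                )
            for reps in (ctrl, trt):
                if len(reps) >= 2:
                    null_pairs.append((reps[0], reps[1]))
            pooled_c, pooled_t = np.concatenate(ctrl), np.concatenate(trt)
            test_pairs.append((pooled_c, pooled_t))
            test_meta.append(
                (interaction, exp, compute_mfi(pooled_c), compute_mfi(pooled_t))
            )

    if method == "ks":
        pvals = _ks_many(test_pairs)
        null_pvals = _ks_many(null_pairs) if null_pairs else np.array([])
    else:
        pvals = np.array([distribution_test(a, b, method) for a, b in test_pairs])
        null_pvals = np.array(
            [distribution_test(a, b, method) for a, b in null_pairs]
        )

    frame = pd.DataFrame(
        {
            "interaction": [m[0] for m in test_meta],
            "experiment": [m[1] for m in test_meta],
            "p_value": pvals,
            "mfi_control": [m[2] for m in test_meta],
            "mfi_treated": [m[3] for m in test_meta],
        }
    )
    frame["fold_change"] = frame["mfi_treated"] / frame["mfi_control"]
    frame["log2_fc"] = np.log2(frame["fold_change"])

    alpha_bonf = bonferroni_alpha(alpha_family, n_comparisons)
    if null_pvals.size:
        alpha_emp = empirical_alpha(null_pvals, alpha_bonf, n_comparisons, alpha_family)
    else:
        logger.warning("no technical-replicate null comparisons; skipping calibration")
        alpha_emp = alpha_bonf
    alpha = AlphaCutoff(alpha_family, n_comparisons, alpha_bonf, alpha_emp)

    hits = call_hits(
        frame, alpha.alpha_adj, replication_threshold=replication_threshold, floor=floor
    )
    return ANCResult(comparisons=frame, alpha=alpha, hits=hits, null_pvalues=null_pvals)
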
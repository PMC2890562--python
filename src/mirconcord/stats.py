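"""Agreement statistics: log ratios, Spearman, Lin's CCC, bootstrap, permutation.

The unit of all concordance analyses is the per-miRNA log2(Ref1/Ref2)
ratio.  Within a platform, ratios from all reference-replicate pairings
are cross-paired (independent hybridizations against independent
hybridizations) and the two Spearman correlations are averaged; between
platforms (and against qPCR) the mean log ratios are rank-correlated.
Uncertainty comes from a bootstrap over miRNAs — the only exchangeable
unit — and differences between platform-vs-qPCR correlations are tested
by permuting platform labels per miRNA, with Holm correction across the
family of contrasts.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mirconcord.types import (
    AgreementEstimate,
    CollapsedExpression,
    LogRatioSet,
    MatchedSet,
    PermutationTestResult,
    ValidationError,
)

logger = logging.getLogger(__name__)

PAIRING_LABELS = ("r11", "r12", "r21", "r22")


# ---------------------------------------------------------------------------
# log ratios

def build_log_ratios(
    expr: CollapsedExpression, values_are_log2: bool = True
) -> LogRatioSet:
    """All reference-pairing log2(Ref1/Ref2) ratios for one platform.

    One-color designs: with Ref1 replicates i and Ref2 replicates j the
    pairings are r_ij = log2(Ref1.i) − log2(Ref2.j) (2×2 design → columns
    r11, r12, r21, r22).  Two-color designs: the collapsed per-array
    swap-corrected M values already are log ratios; arrays are mapped to
    the same four labels by (replicate, dye-swap) order.  Non-positive raw
    intensities yield NaN ratios.  A miRNA is marked present when it is
    present in every column of ``expr``.
    """
    present = pd.Series(False, index=expr.values.index)
    present[sorted(expr.present_mirnas("all"))] = True

    if expr.color_mode == "two":
        pairings = _two_color_pairings(expr)
        return LogRatioSet(expr.platform_id, pairings, present)

    if values_are_log2:
        log_vals = expr.values
    else:
        v = expr.values.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_vals = pd.DataFrame(
                np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), np.nan),
                index=expr.values.index,
                columns=expr.values.columns,
            )
    cols_by_sample: dict[str, list[str]] = {"Ref1": [], "Ref2": []}
    for a in expr.arrays:
        for ch, s in a.channel_to_sample.items():
            cols_by_sample[s].append(f"{a.array_id}.{ch}")
    if not cols_by_sample["Ref1"] or not cols_by_sample["Ref2"]:
        raise ValidationError("need at least one replicate of each reference pool")
    pairings = {}
    for i, c1 in enumerate(cols_by_sample["Ref1"], start=1):
        for j, c2 in enumerate(cols_by_sample["Ref2"], start=1):
            pairings[f"r{i}{j}"] = log_vals[c1] - log_vals[c2]
    return LogRatioSet(expr.platform_id, pd.DataFrame(pairings), present)


def _two_color_pairings(expr: CollapsedExpression) -> pd.DataFrame:
    ordered = sorted(expr.arrays, key=lambda a: (a.replicate_index, a.is_dye_swap))
    if len(ordered) == 4 and sorted(
        (a.replicate_index, a.is_dye_swap) for a in ordered
    ) == [(1, False), (1, True), (2, False), (2, True)]:
        labels = dict(zip([a.array_id for a in ordered], PAIRING_LABELS))
    else:
        labels = {a.array_id: f"m{k + 1}" for k, a in enumerate(ordered)}
    return expr.values.rename(columns=labels)[list(labels.values())]


# ---------------------------------------------------------------------------
# correlation primitives

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson of mid-ranks, average ties).

    NaN pairs are removed pairwise; fewer than 3 complete pairs is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_rho needs two equal-length vectors")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValidationError("spearman_rho needs >= 3 complete pairs")
    return float(sps.spearmanr(x[mask], y[mask]).statistic)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValidationError("pearson needs >= 3 complete pairs")
    return float(np.corrcoef(x[mask], y[mask])[0, 1])


def lin_ccc(
    x: Sequence[float],
    y: Sequence[float],
    probe_set: str = "pairwise_present",
    label: str = "",
) -> AgreementEstimate:
    """Lin's concordance correlation coefficient with asymptotic 95% CI.

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population (1/n)
    moments; it penalizes both scatter around and displacement from the
    identity line, so |CCC| ≤ |Pearson r|.  The CI uses the Fisher
    z-transform with Lin's corrected asymptotic variance; the reported SE
    is back-transformed to the CCC scale by the delta method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValidationError("lin_ccc needs >= 3 complete pairs")
    mx, my = x.mean(), y.mean()
    s2x = float(np.var(x))
    s2y = float(np.var(y))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = s2x + s2y + (mx - my) ** 2
    if denom == 0:
        raise ValidationError("lin_ccc undefined: both vectors constant and equal")
    ccc = 2.0 * sxy / denom

    se = ci_low = ci_high = np.nan
    if s2x > 0 and s2y > 0:
        r = sxy / np.sqrt(s2x * s2y)
        one_minus_c2 = 1.0 - ccc**2
        if n > 2 and one_minus_c2 > 1e-15 and abs(r) > 1e-15:
            u = (mx - my) / (s2x * s2y) ** 0.25
            var_z = (
                (1 - r**2) * ccc**2 / (one_minus_c2 * r**2)
                + 4 * ccc**3 * (1 - ccc) * u**2 / (r * one_minus_c2**2)
                - 2 * ccc**4 * u**4 / (r**2 * one_minus_c2**2)
            ) / (n - 2)
            se_z = float(np.sqrt(max(var_z, 0.0)))
            z = np.arctanh(np.clip(ccc, -1 + 1e-15, 1 - 1e-15))
            ci_low = float(np.tanh(z - 1.959963984540054 * se_z))
            ci_high = float(np.tanh(z + 1.959963984540054 * se_z))
            se = se_z * one_minus_c2
        elif one_minus_c2 <= 1e-15:
            se, ci_low, ci_high = 0.0, ccc, ccc
    return AgreementEstimate(
        method="ccc",
        estimate=float(ccc),
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n=n,
        probe_set=probe_set,
        label=label,
    )


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    x: np.ndarray,
    y: np.ndarray,
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Bootstrap SE and percentile 95% CI of a paired statistic.

    Rows (miRNAs) of ``x`` and ``y`` are resampled jointly with
    replacement; 1-D vectors and n × k pairing matrices are both
    supported.  Degenerate resamples (the statistic raises or returns a
    non-finite value, e.g. a constant vector) are skipped and logged; more
    than 20% skips is an error.  Deterministic for a given seed.
    """
    if B < 200:
        raise ValidationError("bootstrap needs B >= 200")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValidationError("x and y must have the same number of rows")
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            s = statistic(x[idx], y[idx])
        except (ValidationError, FloatingPointError, ZeroDivisionError):
            s = np.nan
        if np.isfinite(s):
            vals.append(s)
        else:
            skipped += 1
    if skipped > 0.2 * B:
        raise ValidationError(
            f"bootstrap degenerate: {skipped}/{B} resamples skipped"
        )
    if skipped:
        logger.info("bootstrap skipped %d/%d degenerate resamples", skipped, B)
    vals = np.asarray(vals)
    se = float(np.std(vals, ddof=1))
    ci_low, ci_high = np.percentile(vals, [2.5, 97.5])
    return se, float(ci_low), float(ci_high)


def _finish_estimate(
    method: str,
    point: float,
    statistic,
    x,
    y,
    n: int,
    probe_set: str,
    label: str,
    B: int,
    seed: int,
) -> AgreementEstimate:
    if B:
        se, lo, hi = bootstrap_ci(statistic, x, y, B=B, seed=seed)
        lo = float(np.clip(min(lo, point), -1.0, 1.0))
        hi = float(np.clip(max(hi, point), -1.0, 1.0))
    else:
        se = lo = hi = np.nan
    return AgreementEstimate(
        method=method,
        estimate=float(point),
        se=se,
        ci_low=lo,
        ci_high=hi,
        n=n,
        probe_set=probe_set,
        label=label,
    )


# ---------------------------------------------------------------------------
# the paper-style agreement estimates

def _apply_filter(index: pd.Index, present: pd.Series, mirna_filter) -> pd.Index:
    keep = index[present.reindex(index, fill_value=False)]
    if mirna_filter is not None:
        keep = keep.intersection(pd.Index(sorted(mirna_filter)))
    return keep


def within_platform_correlation(
    lr: LogRatioSet,
    mirna_filter: Iterable[str] | None = None,
    probe_set: str = "pairwise_present",
    B: int = 2000,
    seed: int = 0,
) -> AgreementEstimate:
    """Cross-paired within-platform Spearman agreement (2×2 design only).

    estimate = ( ρ(r11, r22) + ρ(r12, r21) ) / 2 — each term correlates
    log ratios built from disjoint hybridizations, so replicate noise does
    not share between the two sides.  SE/CI by bootstrap over miRNAs
    (``B=0`` skips the bootstrap).
    """
    missing = [c for c in PAIRING_LABELS if c not in lr.pairings.columns]
    if missing:
        raise ValidationError(
            f"within-platform statistic needs the 2x2 pairings {PAIRING_LABELS}; "
            f"missing {missing}"
        )
    keep = _apply_filter(lr.mirnas, lr.present, mirna_filter)
    sub = lr.pairings.loc[keep, list(PAIRING_LABELS)].dropna()
    if len(sub) < 3:
        raise ValidationError("fewer than 3 usable miRNAs for within-platform estimate")
    x = sub[["r11", "r12"]].to_numpy()
    y = sub[["r22", "r21"]].to_numpy()

    def stat(xb: np.ndarray, yb: np.ndarray) -> float:
        return 0.5 * (spearman_rho(xb[:, 0], yb[:, 0]) + spearman_rho(xb[:, 1], yb[:, 1]))

    return _finish_estimate(
        "spearman", stat(x, y), stat, x, y, len(sub), probe_set,
        f"{lr.platform_id} within", B, seed,
    )


def between_platform_correlation(
    lr_a: LogRatioSet,
    lr_b: LogRatioSet,
    matched: MatchedSet | None = None,
    mirna_filter: Iterable[str] | None = None,
    probe_set: str = "pairwise_present",
    B: int = 2000,
    seed: int = 0,
) -> AgreementEstimate:
    """Between-platform Spearman of mean log ratios.

    miRNAs enter when present on both platforms (``pairwise_present``) or
    when restricted by ``mirna_filter`` to the common-all set; a
    :class:`MatchedSet` additionally restricts to sequence-verified
    matches.
    """
    common = lr_a.mirnas.intersection(lr_b.mirnas)
    if matched is not None:
        common = common.intersection(
            pd.Index(matched.keys_on([lr_a.platform_id, lr_b.platform_id]))
        )
    present_both = lr_a.present.reindex(common, fill_value=False) & lr_b.present.reindex(
        common, fill_value=False
    )
    keep = _apply_filter(common, present_both, mirna_filter)
    pair = pd.DataFrame(
        {"a": lr_a.mean_log_ratio.reindex(keep), "b": lr_b.mean_log_ratio.reindex(keep)}
    ).dropna()
    if len(pair) < 3:
        raise ValidationError(
            f"fewer than 3 matched present miRNAs between {lr_a.platform_id} "
            f"and {lr_b.platform_id}"
        )
    x = pair["a"].to_numpy()
    y = pair["b"].to_numpy()
    return _finish_estimate(
        "spearman", spearman_rho(x, y), lambda a, b: spearman_rho(a, b),
        x, y, len(pair), probe_set,
        f"{lr_a.platform_id} vs {lr_b.platform_id}", B, seed,
    )


def platform_vs_qpcr_correlation(
    lr: LogRatioSet,
    qpcr_ct_diff: pd.Series,
    qpcr_detected: pd.Series,
    mirna_filter: Iterable[str] | None = None,
    probe_set: str = "pairwise_present",
    B: int = 2000,
    seed: int = 0,
) -> AgreementEstimate:
    """Spearman of array mean log ratios against −1 × qPCR ΔCt differences.

    Low Ct means high expression, so the Ct-scale relative difference is
    sign-flipped to orient with the array log2(Ref1/Ref2) ratios.
    """
    common = lr.mirnas.intersection(qpcr_ct_diff.index)
    usable = lr.present.reindex(common, fill_value=False) & qpcr_detected.reindex(
        common, fill_value=False
    )
    keep = _apply_filter(common, usable, mirna_filter)
    pair = pd.DataFrame(
        {
            "array": lr.mean_log_ratio.reindex(keep),
            "qpcr": -1.0 * qpcr_ct_diff.reindex(keep),
        }
    ).dropna()
    if len(pair) < 3:
        raise ValidationError(
            f"fewer than 3 usable miRNAs between {lr.platform_id} and qPCR"
        )
    x = pair["array"].to_numpy()
    y = pair["qpcr"].to_numpy()
    return _finish_estimate(
        "spearman", spearman_rho(x, y), lambda a, b: spearman_rho(a, b),
        x, y, len(pair), probe_set, f"{lr.platform_id} vs qPCR", B, seed,
    )


# ---------------------------------------------------------------------------
# permutation inference

def _rank_rows(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=-1, method="average")


def permutation_diff_test(
    ref_vector: Sequence[float],
    platform1: Sequence[float],
    platform2: Sequence[float],
    n_perm: int = 5000,
    seed: int = 0,
    label: str = "",
) -> PermutationTestResult:
    """Permutation test for ρ(platform1, ref) − ρ(platform2, ref).

    Under the null the two platform labels are exchangeable per miRNA, so
    each permutation swaps the (platform1, platform2) values of every
    miRNA independently with probability ½ and recomputes the difference
    of Spearman correlations.  p = (1 + #{|diff*| ≥ |observed|}) /
    (n_perm + 1).
    """
    if n_perm < 100:
        raise ValidationError("permutation test needs n_perm >= 100")
    ref = np.asarray(ref_vector, dtype=float)
    p1 = np.asarray(platform1, dtype=float)
    p2 = np.asarray(platform2, dtype=float)
    if not (ref.shape == p1.shape == p2.shape):
        raise ValidationError("permutation test needs three aligned vectors")
    mask = np.isfinite(ref) & np.isfinite(p1) & np.isfinite(p2)
    ref, p1, p2 = ref[mask], p1[mask], p2[mask]
    n = ref.size
    if n < 3:
        raise ValidationError("permutation test needs >= 3 complete triples")

    observed = spearman_rho(p1, ref) - spearman_rho(p2, ref)

    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm, n)) < 0.5
    a = np.where(swap, p2[None, :], p1[None, :])
    b = np.where(swap, p1[None, :], p2[None, :])
    ranks_ref = _rank_rows(ref)
    rr = ranks_ref - ranks_ref.mean()
    rr_norm = np.sqrt((rr**2).sum())

    def _row_rhos(mat: np.ndarray) -> np.ndarray:
        r = _rank_rows(mat)
        rc = r - r.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc**2).sum(axis=1)) * rr_norm
        return (rc @ rr) / denom

    diffs = _row_rhos(a) - _row_rhos(b)
    n_extreme = int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
    p = (1 + n_extreme) / (n_perm + 1)
    return PermutationTestResult(
        observed_diff=float(observed),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        label=label,
    )


def familywise_correct(
    p_values: Sequence[float], method: str = "holm"
) -> np.ndarray:
    """Holm step-down family-wise adjustment (monotone, ≥ raw p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("familywise_correct needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if method != "holm":
        raise ValidationError(f"unsupported correction {method!r}")
    return multipletests(p, method="holm")[1]
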
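"""Intensity normalization: cyclic lowess, dye-swap + lowess, quantile.

One-color designs are normalized with cyclic lowess: for every unordered
pair of arrays a lowess curve of M = x_i − x_j on A = (x_i + x_j)/2 is
fitted, each array's per-pair adjustments (±fit/2) are averaged over its
pairs and subtracted, and the cycle repeats for a fixed number of passes.
This assumes roughly balanced up/down regulation between the samples being
normalized.  Two-color arrays are reduced to within-array log ratios
(oriented Ref1-over-Ref2 regardless of dye assignment, so dye-swap pairs
cancel dye bias when averaged) and lowess-normalized against A per array.
Quantile normalization is provided as the standard alternative.

All functions operate on log2-scale matrices, preserve shape and NaN
positions, and never impute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from mirconcord.types import IntensityDataset, ValidationError

logger = logging.getLogger(__name__)

_MIN_FINITE = 10


@dataclass(frozen=True)
class LowessParams:
    """Smoothing constants for (cyclic) lowess normalization.

    ``span`` is the fraction of points in each local window, ``iterations``
    the number of robustifying reweighting iterations per fit, and
    ``convergence_passes`` the number of full cyclic passes over all array
    pairs.
    """

    span: float = 0.4
    iterations: int = 3
    convergence_passes: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValidationError("span must be in (0, 1]")
        if self.iterations < 0 or self.convergence_passes < 1:
            raise ValidationError("iterations >= 0 and convergence_passes >= 1 required")


def _lowess_fit(m: np.ndarray, a: np.ndarray, params: LowessParams) -> np.ndarray:
    """Fitted lowess values of m on a, returned in input order."""
    fit = _sm_lowess(
        m, a, frac=params.span, it=params.iterations, return_sorted=True
    )
    return np.interp(a, fit[:, 0], fit[:, 1])


def _as_array(values) -> tuple[np.ndarray, object]:
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(dtype=float, copy=True), values
    return np.array(values, dtype=float, copy=True), None


def _like(arr: np.ndarray, template) -> np.ndarray | pd.DataFrame:
    if template is None:
        return arr
    return pd.DataFrame(arr, index=template.index, columns=template.columns)


def cyclic_lowess_normalize(values, params: LowessParams | None = None):
    """Cyclic lowess normalization of a log2 intensity matrix (≥2 columns).

    NaN entries are excluded pairwise and preserved in the output.  Raises
    :class:`ValidationError` when a column (or a pair's overlap) has fewer
    than 10 finite values.
    """
    params = params or LowessParams()
    x, template = _as_array(values)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("cyclic lowess needs a matrix with >= 2 columns")
    n_cols = x.shape[1]
    finite = np.isfinite(x)
    for j in range(n_cols):
        if finite[:, j].sum() < _MIN_FINITE:
            raise ValidationError(f"column {j} has < {_MIN_FINITE} finite values")
    for _ in range(params.convergence_passes):
        adj = np.zeros_like(x)
        cnt = np.zeros_like(x)
        for i in range(n_cols):
            for j in range(i + 1, n_cols):
                mask = finite[:, i] & finite[:, j]
                if mask.sum() < _MIN_FINITE:
                    raise ValidationError(
                        f"columns {i} and {j} share < {_MIN_FINITE} finite values"
                    )
                a = (x[mask, i] + x[mask, j]) / 2.0
                m = x[mask, i] - x[mask, j]
                f = _lowess_fit(m, a, params)
                adj[mask, i] += f / 2.0
                adj[mask, j] -= f / 2.0
                cnt[mask, i] += 1
                cnt[mask, j] += 1
        # scale the summed pairwise corrections by 2/(k+1), k = number of
        # partner columns: a constant array offset is then removed exactly
        # in a single pass (the usual cyclic-loess convention)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = x - np.where(cnt > 0, 2.0 * adj / (cnt + 1.0), 0.0)
    return _like(x, template)


def quantile_normalize(values):
    """Quantile normalization: columns share the mean order-statistic
    distribution; tied values receive the mean of the tied quantiles.

    NaN entries keep their positions; columns with missing values are
    mapped through their (scaled) mid-ranks onto the reference
    distribution.
    """
    x, template = _as_array(values)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 columns")
    n_rows, n_cols = x.shape
    finite = np.isfinite(x)
    for j in range(n_cols):
        if finite[:, j].sum() < _MIN_FINITE:
            raise ValidationError(f"column {j} has < {_MIN_FINITE} finite values")
    grid = np.linspace(0.0, 1.0, n_rows)
    stretched = np.empty((n_rows, n_cols))
    for j in range(n_cols):
        col = np.sort(x[finite[:, j], j])
        stretched[:, j] = np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    ref = stretched.mean(axis=1)
    out = np.full_like(x, np.nan)
    from scipy.stats import rankdata

    for j in range(n_cols):
        mask = finite[:, j]
        n_f = int(mask.sum())
        ranks = rankdata(x[mask, j], method="average")
        p = (ranks - 1.0) / (n_f - 1.0) if n_f > 1 else np.full(n_f, 0.5)
        out[mask, j] = np.interp(p, grid, ref)
    return _like(out, template)


def dyeswap_lowess_normalize(
    dataset: IntensityDataset,
    params: LowessParams | None = None,
    fit_lowess: bool = True,
) -> pd.DataFrame:
    """Within-array log-ratio extraction + lowess for a two-color dataset.

    For each array, M = log2(Ref1 channel) − log2(Ref2 channel) — the sign
    is fixed by sample, not dye, so dye-swap arrays are automatically
    orientation-corrected — and A is the mean of the log2 channels.  M is
    lowess-normalized on A per array.  Non-positive intensities become NaN.

    Returns a probe × array_id matrix of normalized M values; averaging a
    dye-swap pair of columns cancels residual dye bias.
    """
    params = params or LowessParams()
    if dataset.color_mode != "two":
        raise ValidationError("dyeswap_lowess_normalize requires a two-color dataset")
    if not any(a.is_dye_swap for a in dataset.arrays):
        logger.warning(
            "platform %s: no dye-swap arrays in the design; dye bias will not "
            "cancel, proceeding with per-array lowess only",
            dataset.platform_id,
        )
    out = {}
    for a in dataset.arrays:
        ch_of = {s: ch for ch, s in a.channel_to_sample.items()}
        v1 = dataset.values[f"{a.array_id}.{ch_of['Ref1']}"].to_numpy(dtype=float)
        v2 = dataset.values[f"{a.array_id}.{ch_of['Ref2']}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            l1 = np.where(v1 > 0, np.log2(np.where(v1 > 0, v1, 1.0)), np.nan)
            l2 = np.where(v2 > 0, np.log2(np.where(v2 > 0, v2, 1.0)), np.nan)
        m = l1 - l2
        av = (l1 + l2) / 2.0
        mask = np.isfinite(m) & np.isfinite(av)
        if mask.sum() < _MIN_FINITE:
            raise ValidationError(
                f"array {a.array_id}: < {_MIN_FINITE} finite log ratios"
            )
        m_norm = np.full_like(m, np.nan)
        if fit_lowess:
            m_norm[mask] = m[mask] - _lowess_fit(m[mask], av[mask], params)
        else:
            m_norm[mask] = m[mask]
        out[a.array_id] = m_norm
    return pd.DataFrame(out, index=dataset.values.index)
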
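"""Present/absent detection calls and qRT-PCR normalized expression.

Two array detection rules are implemented.  The negative-control rule
flags a spot absent when its raw median signal falls below the trimmed
mean plus ``sd_multiplier`` trimmed standard deviations of that array's
negative-control intensities (5% symmetric trim by default).  The
background-SD rule (used by μParaflo-style platforms) passes a spot when
its background-subtracted signal exceeds ``lc_bg_multiplier`` × the spot's
background SD and its replicate CV is below ``lc_cv_max``; a miRNA is then
present when at least half of its spots pass.

qRT-PCR Ct values are normalized to a reference gene (U6) as
ΔCt = Ct(miRNA) − Ct(U6), reported as log2 normalized expression −ΔCt so
that higher expression gives larger values; wells with Ct above the
detection threshold (35 cycles) or undetermined are flagged undetected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mirconcord.types import (
    CtTable,
    IntensityDataset,
    ProbeAnnotation,
    ValidationError,
)

_MIN_CONTROLS = 5


@dataclass(frozen=True)
class DetectionRuleParams:
    """Thresholds of the detection rules.

    trim_fraction
        symmetric tail fraction removed before computing the
        negative-control mean/SD (default 0.05 = 5%).
    sd_multiplier
        number of trimmed SDs above the trimmed mean (default 3).
    lc_bg_multiplier, lc_cv_max, lc_replicate_fraction
        background-SD rule: signal must exceed ``lc_bg_multiplier`` × the
        spot background SD, replicate CV must stay below ``lc_cv_max``,
        and at least ``lc_replicate_fraction`` of a miRNA's spots must
        pass for a present call.
    ct_detection_max
        qPCR detection limit in cycles (Ct above this = undetected).
    """

    trim_fraction: float = 0.05
    sd_multiplier: float = 3.0
    lc_bg_multiplier: float = 3.0
    lc_cv_max: float = 0.5
    lc_replicate_fraction: float = 0.5
    ct_detection_max: float = 35.0

    def __post_init__(self) -> None:
        if not (0 <= self.trim_fraction < 0.5):
            raise ValidationError("trim_fraction must be in [0, 0.5)")
        for name in ("sd_multiplier", "lc_bg_multiplier", "lc_cv_max",
                     "lc_replicate_fraction", "ct_detection_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


def trimmed_mean_sd(values: np.ndarray, trim_fraction: float) -> tuple[float, float]:
    """Mean and sample SD of the values surviving a symmetric trim.

    ``floor(n × trim_fraction)`` values are removed from each tail; the SD
    is the ddof=1 standard deviation of the survivors (0 when fewer than
    two survive).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    k = int(np.floor(n * trim_fraction))
    kept = v[k : n - k] if k > 0 else v
    if kept.size == 0:
        raise ValidationError("trim removed all values")
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    return mean, sd


def detect_present_negctrl(
    values: pd.DataFrame,
    negative_controls: Sequence[str],
    params: DetectionRuleParams | None = None,
) -> pd.DataFrame:
    """Negative-control detection call on a probe × column raw matrix.

    Per column the threshold is trimmed_mean + sd_multiplier × trimmed_SD
    of that column's negative-control intensities; a spot is absent iff
    its value is strictly below the threshold (NaN → absent).  Returns a
    boolean matrix, True = present, for all probes including controls.
    """
    params = params or DetectionRuleParams()
    ctrl_ids = [p for p in negative_controls if p in values.index]
    if not ctrl_ids:
        raise ValidationError("no negative-control probes found in the matrix")
    present = pd.DataFrame(False, index=values.index, columns=values.columns)
    for col in values.columns:
        ctrl = values.loc[ctrl_ids, col].to_numpy(dtype=float)
        ctrl = ctrl[np.isfinite(ctrl)]
        if ctrl.size < _MIN_CONTROLS:
            raise ValidationError(
                f"array column {col!r}: only {ctrl.size} finite negative-control "
                f"values (need >= {_MIN_CONTROLS})"
            )
        mean, sd = trimmed_mean_sd(ctrl, params.trim_fraction)
        threshold = mean + params.sd_multiplier * sd
        v = values[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            present[col] = np.isfinite(v) & ~(v < threshold)
    return present


def detect_present_lc(
    signal: float,
    background_sd: float,
    replicate_signals: Sequence[float],
    params: DetectionRuleParams | None = None,
) -> bool:
    """Single-spot pass under the background-SD + CV rule.

    The spot passes iff signal > lc_bg_multiplier × background_sd and
    SD(replicate_signals)/signal < lc_cv_max.  Non-positive or non-finite
    signal fails (the CV is undefined there).
    """
    params = params or DetectionRuleParams()
    if background_sd < 0 or not np.isfinite(background_sd):
        raise ValidationError("background_sd must be finite and >= 0")
    if not np.isfinite(signal) or signal <= 0:
        return False
    if signal <= params.lc_bg_multiplier * background_sd:
        return False
    reps = np.asarray(replicate_signals, dtype=float)
    reps = reps[np.isfinite(reps)]
    sd = float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0
    return (sd / signal) < params.lc_cv_max


def lc_mirna_present(
    spot_passes: Sequence[bool], params: DetectionRuleParams | None = None
) -> bool:
    """miRNA-level call: present iff ≥ lc_replicate_fraction of spots pass."""
    params = params or DetectionRuleParams()
    passes = list(spot_passes)
    if not passes:
        return False
    return (sum(passes) / len(passes)) >= params.lc_replicate_fraction


def detect_present_lc_dataset(
    dataset: IntensityDataset,
    annotations: Sequence[ProbeAnnotation],
    params: DetectionRuleParams | None = None,
) -> pd.DataFrame:
    """Spot-level pass matrix under the background-SD + CV rule.

    Requires ``dataset.background`` (per-spot background SDs).  Replicate
    SD is computed within each miRNA's technical-replicate spots per
    column.  Feed the result to
    :func:`mirconcord.matching.collapse_replicates` with
    ``consensus="majority"`` for the ≥50%-of-spots present call.
    """
    params = params or DetectionRuleParams()
    if dataset.background is None:
        raise ValidationError(
            f"platform {dataset.platform_id!r}: background matrix required "
            "for the background-SD detection rule"
        )
    probe_to_mirna = {
        p.probe_id: p.mirna_name for p in annotations if not p.is_negative_control
    }
    values, bg = dataset.values, dataset.background
    passes = pd.DataFrame(False, index=values.index, columns=values.columns)
    groups: dict[str, list[str]] = {}
    for pid in values.index:
        if pid in probe_to_mirna:
            groups.setdefault(probe_to_mirna[pid], []).append(pid)
    for col in values.columns:
        for _, pids in groups.items():
            sig = values.loc[pids, col].to_numpy(dtype=float)
            bsd = bg.loc[pids, col].to_numpy(dtype=float)
            finite = sig[np.isfinite(sig)]
            rep_sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
            for pid, s, b in zip(pids, sig, bsd):
                ok = (
                    np.isfinite(s)
                    and s > 0
                    and np.isfinite(b)
                    and s > params.lc_bg_multiplier * b
                    and (rep_sd / s) < params.lc_cv_max
                )
                passes.loc[pid, col] = bool(ok)
    return passes


def taqman_normalized_expression(
    ct: CtTable,
    params: DetectionRuleParams | None = None,
    sign: float = -1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔCt-normalized qPCR expression and detection flags.

    log2 NE = sign × (Ct(miRNA) − Ct(reference gene)) per sample; the
    default sign −1 orients the scale so higher expression → larger NE
    (low Ct means abundant template).  Detection is False where Ct exceeds
    the detection limit or is undetermined.  The reference-gene row is
    excluded from the output.

    Returns ``(log2_ne, detected)`` DataFrames, miRNA × sample.
    """
    params = params or DetectionRuleParams()
    ref = ct.ct.loc[ct.reference_gene]
    missing = [c for c in ct.ct.columns if not np.isfinite(ref[c])]
    if missing:
        raise ValidationError(
            f"reference gene {ct.reference_gene!r} undetermined for sample(s) {missing}"
        )
    dct = ct.ct.sub(ref, axis=1)
    log2_ne = sign * dct
    ctmax = min(params.ct_detection_max, ct.detection_ct)
    detected = ct.ct.notna() & (ct.ct <= ctmax)
    keep = ct.ct.index != ct.reference_gene
    return log2_ne.loc[keep], detected.loc[keep]


def qpcr_ct_difference(
    ct: CtTable, params: DetectionRuleParams | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-miRNA Ct-scale relative difference between the reference pools.

    Returns ``(ct_diff, detected)`` where ct_diff = mean Ct over Ref1
    wells − mean Ct over Ref2 wells (low Ct = abundant, so this runs
    opposite to array log ratios and is sign-flipped downstream), and
    detected is True only when every well of that miRNA is determined and
    at or below the detection limit.
    """
    params = params or DetectionRuleParams()
    _, det = taqman_normalized_expression(ct, params)
    keep = ct.ct.index != ct.reference_gene
    table = ct.ct.loc[keep]
    pools = {c: c.split(".", 1)[0] for c in table.columns}
    bad = {p for p in pools.values() if p not in ("Ref1", "Ref2")}
    if bad:
        raise ValidationError(f"unexpected sample pool label(s) {sorted(bad)}")
    ref1_cols = [c for c, p in pools.items() if p == "Ref1"]
    ref2_cols = [c for c, p in pools.items() if p == "Ref2"]
    if not ref1_cols or not ref2_cols:
        raise ValidationError("Ct table must contain both Ref1 and Ref2 wells")
    diff = table[ref1_cols].mean(axis=1) - table[ref2_cols].mean(axis=1)
    detected = det.all(axis=1)
    return diff, detected


def qpcr_log_ratio(
    ct: CtTable, params: DetectionRuleParams | None = None
) -> tuple[pd.Series, pd.Series]:
    """qPCR relative expression oriented like array log2(Ref1/Ref2).

    Convenience wrapper: −1 × :func:`qpcr_ct_difference`.
    """
    diff, detected = qpcr_ct_difference(ct, params)
    return -1.0 * diff, detected
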
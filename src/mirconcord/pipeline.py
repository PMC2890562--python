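"""End-to-end orchestration: read → match → normalize → detect → collapse →
log ratios → agreement statistics → reports.

The pipeline runs either in memory from a :class:`ScenarioBundle`
(:func:`analyze_bundle`) or from a YAML config + TSV files on disk
(:func:`run_pipeline`), and is deterministic for a fixed seed: every
bootstrap and permutation seed is derived from the run seed in a fixed
order, and report TSVs are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from mirconcord import io as mio
from mirconcord.detection import (
    DetectionRuleParams,
    detect_present_lc_dataset,
    detect_present_negctrl,
    qpcr_ct_difference,
)
from mirconcord.matching import (
    all_platform_intersection,
    collapse_replicates,
    match_across_platforms,
    present_intersections,
)
from mirconcord.normalization import (
    LowessParams,
    cyclic_lowess_normalize,
    dyeswap_lowess_normalize,
    quantile_normalize,
)
from mirconcord.simulate import ScenarioBundle
from mirconcord.stats import (
    between_platform_correlation,
    build_log_ratios,
    familywise_correct,
    lin_ccc,
    permutation_diff_test,
    platform_vs_qpcr_correlation,
    within_platform_correlation,
)
from mirconcord.types import (
    AgreementEstimate,
    ArrayDesign,
    CtTable,
    IntensityDataset,
    LogRatioSet,
    MatchedSet,
    PermutationTestResult,
    ProbeAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("cyclic_lowess", "quantile", "none")


@dataclass
class AnalysisOptions:
    """Tunable knobs of a pipeline run (all defaults are study-like)."""

    normalization: str = "cyclic_lowess"
    detection: DetectionRuleParams = field(default_factory=DetectionRuleParams)
    lowess: LowessParams = field(default_factory=LowessParams)
    bootstrap_B: int = 2000
    n_perm: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATION_METHODS:
            raise ValidationError(
                f"normalization must be one of {NORMALIZATION_METHODS}"
            )


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, ready for report writing."""

    matched: MatchedSet
    log_ratios: dict[str, LogRatioSet]
    present_sets: dict[str, set[str]]
    qpcr_ct_diff: pd.Series
    qpcr_detected: pd.Series
    common_all: set[str]
    venn: dict[frozenset, int]
    venn_qpcr: dict[frozenset, int]
    within: list[AgreementEstimate]
    between: list[AgreementEstimate]
    vs_qpcr: list[AgreementEstimate]
    ccc_vs_qpcr: list[AgreementEstimate]
    permutation: list[PermutationTestResult]
    scatter: dict[str, pd.DataFrame]
    options: AnalysisOptions


def _log2_matrix(values: pd.DataFrame) -> pd.DataFrame:
    v = values.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), np.nan)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def as_one_color(dataset: IntensityDataset, channel: str) -> IntensityDataset:
    """Reduce a two-color dataset to a single channel's one-color view.

    Mirrors analyzing a two-color platform in one-color format: only the
    named channel's columns are kept, each becoming a one-color array
    carrying whichever sample that channel held (dye-swap arrays thus
    supply the other pool's replicates).
    """
    if dataset.color_mode != "two":
        raise ValidationError("as_one_color expects a two-color dataset")
    arrays = []
    rep_counter = {"Ref1": 0, "Ref2": 0}
    cols = []
    for a in dataset.arrays:
        if channel not in a.channel_to_sample:
            raise ValidationError(f"array {a.array_id!r} has no channel {channel!r}")
        sample = a.channel_to_sample[channel]
        rep_counter[sample] += 1
        arrays.append(
            ArrayDesign(
                array_id=a.array_id,
                channel_to_sample={channel: sample},
                replicate_index=rep_counter[sample],
            )
        )
        cols.append(f"{a.array_id}.{channel}")
    return IntensityDataset(
        platform_id=dataset.platform_id,
        color_mode="one",
        arrays=arrays,
        values=dataset.values[cols],
        background=None if dataset.background is None else dataset.background[cols],
        negative_control_ids=dataset.negative_control_ids,
    )


def platform_log_ratios(
    dataset: IntensityDataset,
    annotations: list[ProbeAnnotation],
    detection_rule: str,
    options: AnalysisOptions,
) -> LogRatioSet:
    """Normalize, call detection, collapse and build log ratios for one platform."""
    if detection_rule not in ("negctrl", "lc"):
        raise ValidationError(f"unknown detection rule {detection_rule!r}")

    if detection_rule == "lc":
        detection = detect_present_lc_dataset(dataset, annotations, options.detection)
        consensus = "majority"
    else:
        detection = detect_present_negctrl(
            dataset.values, sorted(dataset.negative_control_ids), options.detection
        )
        consensus = "any_absent"

    if dataset.color_mode == "one":
        log_vals = _log2_matrix(dataset.values)
        if options.normalization == "cyclic_lowess":
            log_vals = cyclic_lowess_normalize(log_vals, options.lowess)
        elif options.normalization == "quantile":
            log_vals = quantile_normalize(log_vals)
        collapsed = collapse_replicates(
            log_vals,
            annotations,
            detection,
            platform_id=dataset.platform_id,
            color_mode="one",
            arrays=dataset.arrays,
            consensus=consensus,
            min_present_fraction=options.detection.lc_replicate_fraction,
        )
        return build_log_ratios(collapsed, values_are_log2=True)

    # two-color: within-array ratios, dye-swap orientation handled by sample
    m = dyeswap_lowess_normalize(
        dataset,
        options.lowess,
        fit_lowess=options.normalization != "none",
    )
    # a probe is present on an array when present in both channels
    per_array = {}
    for a in dataset.arrays:
        cols = a.columns()
        per_array[a.array_id] = detection[cols].all(axis=1)
    det_arrays = pd.DataFrame(per_array)
    collapsed = collapse_replicates(
        m,
        annotations,
        det_arrays,
        platform_id=dataset.platform_id,
        color_mode="two",
        arrays=dataset.arrays,
        consensus=consensus,
        min_present_fraction=options.detection.lc_replicate_fraction,
    )
    return build_log_ratios(collapsed)


def _name_to_key_maps(
    matched: MatchedSet, annotations: dict[str, list[ProbeAnnotation]]
) -> dict[str, dict[str, str]]:
    """Per platform: platform-local miRNA name → canonical matched key."""
    maps: dict[str, dict[str, str]] = {p: {} for p in matched.platforms}
    probe_name = {
        p: {a.probe_id: a.mirna_name for a in anns}
        for p, anns in annotations.items()
    }
    for key, per_platform in matched.entries.items():
        for pid, probe_ids in per_platform.items():
            for probe_id in probe_ids:
                maps[pid][probe_name[pid][probe_id]] = key
    return maps


def _canonicalize(lr: LogRatioSet, name_map: dict[str, str]) -> LogRatioSet:
    rename = {n: name_map.get(n, n) for n in lr.pairings.index}
    pairings = lr.pairings.rename(index=rename)
    present = lr.present.rename(index=rename)
    if pairings.index.has_duplicates:
        # two platform-local names collapsing onto one key: keep the
        # first in sorted order and log — should not occur with the
        # generator's catalogues
        logger.warning("platform %s: duplicate canonical keys after matching", lr.platform_id)
        keep = ~pairings.index.duplicated()
        pairings, present = pairings[keep], present[keep]
    order = pairings.index.sort_values()
    return LogRatioSet(lr.platform_id, pairings.loc[order], present.loc[order])


def analyze_bundle(
    bundle: ScenarioBundle, options: AnalysisOptions | None = None
) -> AnalysisResult:
    """Run the full concordance analysis on an in-memory bundle."""
    options = options or AnalysisOptions()
    rules = {pid: bundle.models[pid].detection_rule for pid in bundle.platform_ids}
    return analyze(
        datasets=bundle.datasets,
        annotations=bundle.annotations,
        detection_rules=rules,
        ct=bundle.ct,
        options=options,
    )


def analyze(
    datasets: dict[str, IntensityDataset],
    annotations: dict[str, list[ProbeAnnotation]],
    detection_rules: dict[str, str],
    ct: CtTable,
    options: AnalysisOptions | None = None,
) -> AnalysisResult:
    options = options or AnalysisOptions()
    platforms = sorted(datasets)
    if len(platforms) < 2:
        raise ValidationError("the concordance analysis needs >= 2 platforms")
    rng = np.random.default_rng(options.seed)

    def next_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    # stage: match
    matched = match_across_platforms(annotations)
    name_maps = _name_to_key_maps(matched, annotations)

    # stage: per-platform processing
    log_ratios: dict[str, LogRatioSet] = {}
    for pid in platforms:
        try:
            lr = platform_log_ratios(
                datasets[pid], annotations[pid], detection_rules[pid], options
            )
        except ValidationError as exc:
            raise ValidationError(f"platform stage failed for {pid!r}: {exc}") from exc
        log_ratios[pid] = _canonicalize(lr, name_maps[pid])

    present_sets = {
        pid: {m for m, ok in lr.present.items() if ok} for pid, lr in log_ratios.items()
    }

    # stage: qPCR
    ct_diff, ct_detected = qpcr_ct_difference(ct, options.detection)
    detected_names = set(ct_detected.index[ct_detected])

    # stage: intersections
    venn = present_intersections(present_sets)
    venn_qpcr = present_intersections(present_sets, qpcr_detected=detected_names)
    common_all = all_platform_intersection(present_sets, qpcr_detected=detected_names)

    b = options.bootstrap_B
    within: list[AgreementEstimate] = []
    for pid in platforms:
        lr = log_ratios[pid]
        within.append(
            within_platform_correlation(
                lr, None, "pairwise_present", B=b, seed=next_seed()
            )
        )
        try:
            within.append(
                within_platform_correlation(
                    lr, common_all, "common_all", B=b, seed=next_seed()
                )
            )
        except ValidationError as exc:
            logger.warning("within/common_all skipped for %s: %s", pid, exc)

    between: list[AgreementEstimate] = []
    scatter: dict[str, pd.DataFrame] = {}
    for pa, pb in itertools.combinations(platforms, 2):
        lra, lrb = log_ratios[pa], log_ratios[pb]
        between.append(
            between_platform_correlation(
                lra, lrb, matched, None, "pairwise_present", B=b, seed=next_seed()
            )
        )
        try:
            between.append(
                between_platform_correlation(
                    lra, lrb, matched, common_all, "common_all", B=b, seed=next_seed()
                )
            )
        except ValidationError as exc:
            logger.warning("between/common_all skipped for %s-%s: %s", pa, pb, exc)
        common = lra.mirnas.intersection(lrb.mirnas)
        scatter[f"{pa}_vs_{pb}"] = pd.DataFrame(
            {
                "mirna_name": common,
                pa: lra.mean_log_ratio.reindex(common).to_numpy(),
                pb: lrb.mean_log_ratio.reindex(common).to_numpy(),
                "present_both": (
                    lra.present.reindex(common, fill_value=False)
                    & lrb.present.reindex(common, fill_value=False)
                ).to_numpy(),
            }
        ).set_index("mirna_name")

    vs_qpcr: list[AgreementEstimate] = []
    ccc_vs_qpcr: list[AgreementEstimate] = []
    for pid in platforms:
        lr = log_ratios[pid]
        vs_qpcr.append(
            platform_vs_qpcr_correlation(
                lr, ct_diff, ct_detected, None, "pairwise_present", B=b, seed=next_seed()
            )
        )
        try:
            vs_qpcr.append(
                platform_vs_qpcr_correlation(
                    lr, ct_diff, ct_detected, common_all, "common_all",
                    B=b, seed=next_seed(),
                )
            )
        except ValidationError as exc:
            logger.warning("vs-qPCR/common_all skipped for %s: %s", pid, exc)
        for filt, tag in ((None, "pairwise_present"), (common_all, "common_all")):
            usable = lr.present & ct_detected.reindex(lr.mirnas, fill_value=False)
            keys = lr.mirnas[usable.to_numpy(dtype=bool)]
            if filt is not None:
                keys = keys.intersection(pd.Index(sorted(filt)))
            x = lr.mean_log_ratio.reindex(keys)
            y = -1.0 * ct_diff.reindex(keys)
            try:
                ccc_vs_qpcr.append(
                    lin_ccc(x, y, probe_set=tag, label=f"{pid} vs qPCR")
                )
            except ValidationError as exc:
                logger.warning("CCC skipped for %s (%s): %s", pid, tag, exc)

    # permutation tests: platform-vs-qPCR accuracy contrasts on the common set
    permutation: list[PermutationTestResult] = []
    perm_keys = sorted(common_all)
    if len(perm_keys) >= 3:
        ref = (-1.0 * ct_diff.reindex(perm_keys)).to_numpy()
        for pa, pb in itertools.combinations(platforms, 2):
            x1 = log_ratios[pa].mean_log_ratio.reindex(perm_keys).to_numpy()
            x2 = log_ratios[pb].mean_log_ratio.reindex(perm_keys).to_numpy()
            permutation.append(
                permutation_diff_test(
                    ref, x1, x2, n_perm=options.n_perm, seed=next_seed(),
                    label=f"{pa} vs {pb} (accuracy vs qPCR)",
                )
            )
        adjusted = familywise_correct([r.p_value for r in permutation])
        permutation = [
            replace(r, correction="holm", p_adjusted=float(p))
            for r, p in zip(permutation, adjusted)
        ]
    else:
        logger.warning("permutation tests skipped: common set too small")

    return AnalysisResult(
        matched=matched,
        log_ratios=log_ratios,
        present_sets=present_sets,
        qpcr_ct_diff=ct_diff,
        qpcr_detected=ct_detected,
        common_all=common_all,
        venn=venn,
        venn_qpcr=venn_qpcr,
        within=within,
        between=between,
        vs_qpcr=vs_qpcr,
        ccc_vs_qpcr=ccc_vs_qpcr,
        permutation=permutation,
        scatter=scatter,
        options=options,
    )


# ---------------------------------------------------------------------------
# report writing

REPORT_FILES = (
    "within_platform.tsv",
    "between_platform.tsv",
    "platform_vs_qpcr.tsv",
    "ccc_vs_qpcr.tsv",
    "permutation_tests.tsv",
    "venn_counts.tsv",
    "venn_counts_qpcr.tsv",
    "common_set.tsv",
    "manifest.json",
)


def write_reports(result: AnalysisResult, out_dir: str, config_hash: str = "") -> list[str]:
    """Write all report tables + a run manifest; returns the paths written."""
    from mirconcord import __version__

    mio.ensure_dir(out_dir)
    platforms = sorted(result.log_ratios)
    paths = []

    def p(name: str) -> str:
        paths.append(os.path.join(out_dir, name))
        return paths[-1]

    mio.write_agreement_report(result.within, p("within_platform.tsv"))
    mio.write_agreement_report(result.between, p("between_platform.tsv"))
    mio.write_agreement_report(result.vs_qpcr, p("platform_vs_qpcr.tsv"))
    mio.write_agreement_report(result.ccc_vs_qpcr, p("ccc_vs_qpcr.tsv"))
    if result.permutation:
        mio.write_permutation_report(result.permutation, p("permutation_tests.tsv"))
    mio.write_venn_counts(result.venn, platforms, p("venn_counts.tsv"))
    mio.write_venn_counts(result.venn_qpcr, platforms, p("venn_counts_qpcr.tsv"))
    pd.Series(sorted(result.common_all), name="mirna_name").to_csv(
        p("common_set.tsv"), sep="\t", index=False
    )
    for name, df in result.scatter.items():
        df.round(6).to_csv(p(f"scatter_{name}.tsv"), sep="\t", na_rep="NA")
    manifest = {
        "version": __version__,
        "seed": result.options.seed,
        "config_hash": config_hash,
        "options": {
            "normalization": result.options.normalization,
            "bootstrap_B": result.options.bootstrap_B,
            "n_perm": result.options.n_perm,
            "detection": dataclasses.asdict(result.options.detection),
            "lowess": dataclasses.asdict(result.options.lowess),
        },
        "platforms": platforms,
        "n_matched": len(result.matched),
        "n_common_all": len(result.common_all),
    }
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# config-driven entry point

def load_run_config(config_path: str) -> dict:
    """Load and validate a run config / design YAML."""
    cfg = mio.read_design(config_path)
    if "seed" not in cfg:
        raise ValidationError(f"{config_path}: config must declare a seed")
    if "platforms" not in cfg or len(cfg["platforms"]) < 2:
        raise ValidationError(f"{config_path}: need >= 2 platform entries")
    base = os.path.dirname(os.path.abspath(config_path))
    for pid, entry in cfg["platforms"].items():
        for key in ("intensities", "annotation"):
            if key not in entry:
                raise ValidationError(f"platform {pid!r}: missing {key!r} path")
            path = os.path.join(base, entry[key])
            if not os.path.exists(path):
                raise ValidationError(f"platform {pid!r}: path {path!r} does not exist")
    qpcr = cfg.get("qpcr", {})
    if "ct_table" not in qpcr:
        raise ValidationError(f"{config_path}: missing qpcr.ct_table")
    if not os.path.exists(os.path.join(base, qpcr["ct_table"])):
        raise ValidationError(f"qpcr.ct_table path does not exist")
    return cfg


def run_pipeline(
    config_path: str,
    out_dir: str,
    options: AnalysisOptions | None = None,
) -> AnalysisResult:
    """Run the full analysis from a config file and write all reports."""
    cfg = load_run_config(config_path)
    base = os.path.dirname(os.path.abspath(config_path))
    if options is None:
        stats_cfg = cfg.get("stats", {})
        options = AnalysisOptions(
            normalization=cfg.get("normalization", {}).get("method", "cyclic_lowess"),
            bootstrap_B=int(stats_cfg.get("bootstrap_B", 2000)),
            n_perm=int(stats_cfg.get("n_perm", 5000)),
            seed=int(cfg["seed"]),
        )

    datasets: dict[str, IntensityDataset] = {}
    annotations: dict[str, list[ProbeAnnotation]] = {}
    rules: dict[str, str] = {}
    for pid, entry in sorted(cfg["platforms"].items()):
        arrays = mio.design_from_config(entry)
        ds = mio.read_intensity_table(
            os.path.join(base, entry["intensities"]),
            arrays,
            platform_id=pid,
            color_mode=entry.get("color_mode", "one"),
            background_path=(
                os.path.join(base, entry["background"]) if "background" in entry else None
            ),
            negative_control_ids=entry.get("negative_controls", ()),
        )
        if entry.get("analyze_as", ds.color_mode) == "one" and ds.color_mode == "two":
            ds = as_one_color(ds, entry.get("one_color_channel", ds.arrays[0].channels[0]))
        datasets[pid] = ds
        annotations[pid] = mio.read_probe_annotation(
            os.path.join(base, entry["annotation"]),
            platform_id=pid,
            annotation_version=entry.get("annotation_version", ""),
        )
        rules[pid] = entry.get("detection_rule", "negctrl")
    qpcr_cfg = cfg["qpcr"]
    ct = mio.read_ct_table(
        os.path.join(base, qpcr_cfg["ct_table"]),
        reference_gene=qpcr_cfg.get("reference_gene", "U6"),
        detection_ct=float(qpcr_cfg.get("detection_ct", 35.0)),
    )

    result = analyze(datasets, annotations, rules, ct, options)
    config_hash = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    write_reports(result, out_dir, config_hash=config_hash)
    return result
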
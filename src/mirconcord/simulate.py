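"""Synthetic multi-platform miRNA microarray data with known ground truth.

The generator emulates a two-reference-pool concordance study: a shared
set of true per-miRNA log2 abundances for pools Ref1 and Ref2 (Ref1
enriched in some miRNAs, Ref2 in others, balanced up/down), measured by
several platforms that differ in probe chemistry (probe length —
creating substring-containment relations across platforms), catalogue
content (each platform omits a fraction of miRNAs, exercising Venn
logic), color mode (one-color 2+2 replicate designs; two-color designs
with dye-swap pairs), probe affinity, additive log-scale noise, dye bias
and a smooth intensity-dependent distortion for normalization to remove.
Matched TaqMan-style Ct values are generated with a configurable
efficiency slope and a constant reference (U6) row.

What it does not emulate: cross-hybridization between related miRNAs,
spatial/print-tip effects, or image-level artifacts.

All outputs are deterministic functions of an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mirconcord.types import (
    ArrayDesign,
    CtTable,
    IntensityDataset,
    ProbeAnnotation,
    ValidationError,
)

_BASES = np.array(list("ACGT"))
CORE_LENGTH = 22  # mature miRNAs are ~22 nt
CONTEXT_LENGTH = 60  # precursor-like context around the mature sequence


@dataclass
class SyntheticTruth:
    """Ground-truth abundances and sequences for the two reference pools."""

    mirna_names: list[str]
    core_sequences: list[str]
    context_sequences: list[str]  # core centered in precursor-like context
    abundance: pd.DataFrame  # miRNA × {Ref1, Ref2}, log2 units
    differential_fraction: float
    effect_size_sd: float
    is_differential: np.ndarray
    direction: np.ndarray  # +1 up in Ref1, -1 down, 0 non-differential

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_names)

    @property
    def log_ratio(self) -> pd.Series:
        """True per-miRNA log2(Ref1/Ref2)."""
        return self.abundance["Ref1"] - self.abundance["Ref2"]


@dataclass
class PlatformModel:
    """Measurement model of one synthetic platform.

    Log2 signal of a spot = platform_offset + probe affinity + true
    abundance + curvature distortion + dye bias (two-color) + N(0,
    noise_sd); intensities are 2**signal.  ``probe_length_range`` controls
    containment relations: probes longer than the 22-nt core embed it in
    random flanking sequence.  ``content_fraction`` of the truth catalogue
    is retained (platform-specific content).  ``name_suffix_fraction`` of
    retained miRNAs get an annotation-version-style name variant ("-5p")
    to exercise sequence-authoritative matching.
    """

    platform_id: str
    color_mode: str = "one"
    n_tech_reps: int = 3
    probe_affinity_sd: float = 0.25
    noise_sd: float = 0.25
    background_mean: float = 6.0  # log2 scale
    background_sd: float = 1.0  # log2 scale
    dye_bias: float = 0.3
    curvature: float = 0.0
    annotation_version: str = "synthetic-v1"
    probe_length_range: tuple[int, int] = (CORE_LENGTH, CORE_LENGTH)
    n_negative_controls: int = 20
    content_fraction: float = 1.0
    name_suffix_fraction: float = 0.0
    platform_offset: float = 0.0
    detection_rule: str = "negctrl"  # "negctrl" | "lc"

    def __post_init__(self) -> None:
        for name in ("probe_affinity_sd", "noise_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.probe_length_range
        if lo < CORE_LENGTH or hi < lo or hi > CONTEXT_LENGTH:
            raise ValidationError(
                f"probe_length_range must satisfy "
                f"{CORE_LENGTH} <= lo <= hi <= {CONTEXT_LENGTH}"
            )
        if not (0 < self.content_fraction <= 1):
            raise ValidationError("content_fraction must be in (0, 1]")


@dataclass
class QPCRModel:
    """TaqMan-style Ct model: Ct = ct_intercept + slope × log2 abundance + noise.

    The default slope of −1 per log2 unit corresponds to 100%
    amplification efficiency; the intercept is placed so that miRNAs
    abundant enough to be array-present yield Ct ≤ 25, well inside the
    detection range, while the detection limit sits at 35 cycles.
    """

    ct_intercept: float = 33.0
    slope: float = -1.0
    ct_noise_sd: float = 0.15
    u6_ct: float = 20.0
    undetected_above: float = 35.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError("slope must be negative (low Ct = abundant)")


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def generate_truth(
    n_mirna: int = 260,
    differential_fraction: float = 0.4,
    effect_size_sd: float = 2.0,
    seed: int = 0,
    baseline_mean: float = 9.0,
    baseline_sd: float = 2.5,
) -> SyntheticTruth:
    """Draw ground-truth abundances for the two reference pools.

    Baselines are broad on the log2 scale (default N(9, 2.5²), sitting
    clearly above the negative-control background for most miRNAs); a
    ``differential_fraction`` of miRNAs receive half-normal(effect_size_sd)
    log2 shifts in Ref1, split evenly up/down (when the count is odd the
    extra miRNA goes down).  Non-differential miRNAs are identical in both
    pools.  Deterministic per seed.
    """
    if n_mirna < 20:
        raise ValidationError("n_mirna must be >= 20")
    if not (0 <= differential_fraction <= 1):
        raise ValidationError("differential_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"syn-miR-{i:04d}" for i in range(n_mirna)]
    contexts = [
        "".join(rng.choice(_BASES, size=CONTEXT_LENGTH)) for _ in range(n_mirna)
    ]
    start = (CONTEXT_LENGTH - CORE_LENGTH) // 2
    cores = [c[start : start + CORE_LENGTH] for c in contexts]
    baseline = rng.normal(baseline_mean, baseline_sd, n_mirna)
    n_diff = int(round(differential_fraction * n_mirna))
    n_up = n_diff // 2
    diff_idx = rng.choice(n_mirna, size=n_diff, replace=False)
    direction = np.zeros(n_mirna)
    direction[diff_idx[:n_up]] = 1.0
    direction[diff_idx[n_up:]] = -1.0
    effects = np.abs(rng.normal(0.0, effect_size_sd, n_mirna)) * direction
    abundance = pd.DataFrame(
        {"Ref1": baseline + effects, "Ref2": baseline}, index=pd.Index(names, name="mirna")
    )
    return SyntheticTruth(
        mirna_names=names,
        core_sequences=cores,
        context_sequences=contexts,
        abundance=abundance,
        differential_fraction=differential_fraction,
        effect_size_sd=effect_size_sd,
        is_differential=direction != 0,
        direction=direction,
    )


def one_color_design(n_reps_per_pool: int = 2, channel: str = "Cy3") -> list[ArrayDesign]:
    """2+2 one-color design: one array per reference replicate."""
    arrays = []
    k = 0
    for sample in ("Ref1", "Ref2"):
        for rep in range(1, n_reps_per_pool + 1):
            k += 1
            arrays.append(
                ArrayDesign(
                    array_id=f"A{k}",
                    channel_to_sample={channel: sample},
                    replicate_index=rep,
                )
            )
    return arrays


def two_color_design(
    n_pairs: int = 2, channels: tuple[str, str] = ("Cy3", "Cy5")
) -> list[ArrayDesign]:
    """Two replicates + two dye swaps (4 arrays), both samples per array."""
    c1, c2 = channels
    arrays = []
    k = 0
    for rep in range(1, n_pairs + 1):
        for swap in (False, True):
            k += 1
            mapping = (
                {c1: "Ref2", c2: "Ref1"} if swap else {c1: "Ref1", c2: "Ref2"}
            )
            arrays.append(
                ArrayDesign(
                    array_id=f"A{k}",
                    channel_to_sample=mapping,
                    replicate_index=rep,
                    is_dye_swap=swap,
                )
            )
    return arrays


def _curvature_distortion(abundance: np.ndarray, scale_center: float, scale_sd: float) -> np.ndarray:
    # smooth, odd, bounded (±1): a saturating cubic in centered abundance
    z = (abundance - scale_center) / max(scale_sd, 1e-9)
    return np.tanh(z**3 / 3.0)


def simulate_platform(
    truth: SyntheticTruth,
    model: PlatformModel,
    design: list[ArrayDesign] | None = None,
    seed: int = 0,
) -> tuple[list[ProbeAnnotation], IntensityDataset]:
    """Simulate one platform's probe catalogue and intensity matrix.

    Each retained miRNA gets ``n_tech_reps`` technical-replicate spots of
    one probe whose sequence is a window of the miRNA's precursor-like
    context centered on the 22-nt core, so probes of different lengths
    nest and cross-platform containment holds by construction.  Negative-control spots draw
    log2-normal background intensities.  The curvature distortion varies
    linearly across columns from −curvature to +curvature so that it is
    removable by cross-array normalization.  When ``detection_rule`` is
    "lc" a same-shape background-SD matrix is attached.
    """
    if design is None:
        design = (
            one_color_design() if model.color_mode == "one" else two_color_design()
        )
    n_channels = {a.array_id: len(a.channel_to_sample) for a in design}
    want = 1 if model.color_mode == "one" else 2
    if any(n != want for n in n_channels.values()):
        raise ValidationError(
            f"design incompatible with color_mode={model.color_mode!r}"
        )
    rng = np.random.default_rng(seed)
    n = truth.n_mirna
    n_keep = int(round(model.content_fraction * n))
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))

    annotations: list[ProbeAnnotation] = []
    probe_rows: list[tuple[str, int]] = []  # (probe_id, truth index)
    lo, hi = model.probe_length_range
    for idx in keep:
        context = truth.context_sequences[idx]
        length = int(rng.integers(lo, hi + 1))
        # centered window: windows of different lengths nest, so the
        # containment rule holds pairwise across platforms
        start = (len(context) - length) // 2
        seq = context[start : start + length]
        name = truth.mirna_names[idx]
        if model.name_suffix_fraction > 0 and rng.random() < model.name_suffix_fraction:
            name = name + "-5p"
        for rep in range(1, model.n_tech_reps + 1):
            pid = f"{model.platform_id}:{truth.mirna_names[idx]}:s{rep}"
            annotations.append(
                ProbeAnnotation(
                    probe_id=pid,
                    mirna_name=name,
                    sequence=seq,
                    platform_id=model.platform_id,
                    annotation_version=model.annotation_version,
                    is_negative_control=False,
                )
            )
            probe_rows.append((pid, idx))
    neg_ids = [f"{model.platform_id}:neg:{k}" for k in range(model.n_negative_controls)]
    for pid in neg_ids:
        annotations.append(
            ProbeAnnotation(
                probe_id=pid,
                mirna_name="negative_control",
                sequence="",
                platform_id=model.platform_id,
                annotation_version=model.annotation_version,
                is_negative_control=True,
            )
        )

    probe_ids = [p for p, _ in probe_rows] + neg_ids
    truth_idx = np.array([i for _, i in probe_rows])
    n_signal = len(probe_rows)
    affinity = rng.normal(0.0, model.probe_affinity_sd, n_signal)

    columns = [c for a in design for c in a.columns()]
    n_cols = len(columns)
    center = float(truth.abundance.to_numpy().mean())
    spread = float(truth.abundance.to_numpy().std())
    values = np.empty((len(probe_ids), n_cols))
    col_scale = (
        np.linspace(-1.0, 1.0, n_cols) if n_cols > 1 else np.zeros(1)
    )
    for j, col in enumerate(columns):
        array_id, channel = col.rsplit(".", 1)
        a = next(a for a in design if a.array_id == array_id)
        sample = a.channel_to_sample[channel]
        ab = truth.abundance[sample].to_numpy()[truth_idx]
        sig = (
            model.platform_offset
            + affinity
            + ab
            + model.curvature * col_scale[j] * _curvature_distortion(ab, center, spread)
        )
        if model.color_mode == "two" and channel == a.channels[0]:
            sig = sig + model.dye_bias
        sig = sig + rng.normal(0.0, model.noise_sd, n_signal)
        bg = 2.0 ** rng.normal(
            model.background_mean, model.background_sd, model.n_negative_controls
        )
        values[:n_signal, j] = 2.0**sig
        values[n_signal:, j] = bg
    frame = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=columns)

    background = None
    if model.detection_rule == "lc":
        bg_sd = (
            2.0
            ** rng.normal(
                model.background_mean, model.background_sd / 2.0, frame.shape
            )
            / 3.0
        )
        background = pd.DataFrame(bg_sd, index=frame.index, columns=frame.columns)

    dataset = IntensityDataset(
        platform_id=model.platform_id,
        color_mode=model.color_mode,
        arrays=list(design),
        values=frame,
        background=background,
        negative_control_ids=frozenset(neg_ids),
    )
    return annotations, dataset


def simulate_qpcr(
    truth: SyntheticTruth,
    model: QPCRModel | None = None,
    n_replicates: int = 2,
    seed: int = 0,
) -> CtTable:
    """Simulate a TaqMan-style Ct table (all truth miRNAs + U6 row).

    Ct values above the detection limit are emitted as-is; flagging them
    undetected is the job of the detection rules downstream.
    """
    model = model or QPCRModel()
    rng = np.random.default_rng(seed)
    cols = [f"{s}.{r}" for s in ("Ref1", "Ref2") for r in range(1, n_replicates + 1)]
    rows = {}
    for name in truth.mirna_names:
        vals = []
        for col in cols:
            sample = col.split(".", 1)[0]
            ab = truth.abundance.loc[name, sample]
            vals.append(
                model.ct_intercept + model.slope * ab + rng.normal(0.0, model.ct_noise_sd)
            )
        rows[name] = vals
    rows["U6"] = [model.u6_ct + rng.normal(0.0, model.ct_noise_sd) for _ in cols]
    ct = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    ct.index.name = "mirna_name"
    return CtTable(ct=ct, reference_gene="U6", detection_ct=model.undetected_above)


@dataclass
class ScenarioBundle:
    """A full synthetic study: truth, four platforms, and a Ct table."""

    truth: SyntheticTruth
    models: dict[str, PlatformModel]
    annotations: dict[str, list[ProbeAnnotation]]
    datasets: dict[str, IntensityDataset]
    ct: CtTable
    qpcr_model: QPCRModel
    seed: int

    @property
    def platform_ids(self) -> list[str]:
        return sorted(self.datasets)


def default_platform_models(
    noise_sd: float = 0.25, zero_noise: bool = False
) -> dict[str, PlatformModel]:
    """The four study-like platforms: two one-color, two two-color.

    Probe lengths differ so the short-probe platform's sequences are
    contained in the longer-probe platforms'; catalogue content overlaps
    partially; one one-color platform uses the background-SD + CV
    detection rule.
    """
    models = {
        "agi1c": PlatformModel(
            platform_id="agi1c",
            color_mode="one",
            probe_length_range=(CORE_LENGTH, CORE_LENGTH),
            content_fraction=0.88,
            annotation_version="synthetic-v12",
            noise_sd=noise_sd,
            curvature=0.3,
            platform_offset=0.5,
        ),
        "lcs1c": PlatformModel(
            platform_id="lcs1c",
            color_mode="one",
            probe_length_range=(CORE_LENGTH, 28),
            content_fraction=0.9,
            annotation_version="synthetic-v14",
            noise_sd=noise_sd,
            detection_rule="lc",
            platform_offset=-0.3,
            name_suffix_fraction=0.05,
        ),
        "exi2c": PlatformModel(
            platform_id="exi2c",
            color_mode="two",
            probe_length_range=(CORE_LENGTH, 30),
            content_fraction=0.92,
            annotation_version="synthetic-v11",
            noise_sd=noise_sd,
            dye_bias=0.4,
            platform_offset=0.2,
        ),
        "nco2c": PlatformModel(
            platform_id="nco2c",
            color_mode="two",
            probe_length_range=(30, 40),
            content_fraction=0.85,
            annotation_version="synthetic-v9",
            noise_sd=noise_sd,
            dye_bias=-0.3,
            n_tech_reps=4,
            name_suffix_fraction=0.05,
        ),
    }
    if zero_noise:
        models = {
            pid: replace(
                m,
                noise_sd=0.0,
                probe_affinity_sd=0.0,
                dye_bias=0.0,
                curvature=0.0,
                background_sd=0.0,
                name_suffix_fraction=m.name_suffix_fraction,
            )
            for pid, m in models.items()
        }
    return models


def paper_like_scenario(
    seed: int = 0,
    n_mirna: int = 260,
    noise_sd: float = 0.25,
    differential_fraction: float = 0.8,
    effect_size_sd: float = 2.0,
    zero_noise: bool = False,
    qpcr_model: QPCRModel | None = None,
) -> ScenarioBundle:
    """Generate the full study-like bundle: 4 platforms + Ct table + truth.

    The high default differential fraction reflects reference pools chosen
    to maximize differences in miRNA content between them.
    """
    rng = np.random.default_rng(seed)
    truth = generate_truth(
        n_mirna=n_mirna,
        differential_fraction=differential_fraction,
        effect_size_sd=effect_size_sd,
        seed=_spawn_seed(rng),
    )
    models = default_platform_models(noise_sd=noise_sd, zero_noise=zero_noise)
    qpcr_model = qpcr_model or QPCRModel(
        ct_noise_sd=0.0 if zero_noise else QPCRModel.ct_noise_sd
    )
    annotations: dict[str, list[ProbeAnnotation]] = {}
    datasets: dict[str, IntensityDataset] = {}
    for pid in sorted(models):
        ann, ds = simulate_platform(truth, models[pid], seed=_spawn_seed(rng))
        annotations[pid] = ann
        datasets[pid] = ds
    ct = simulate_qpcr(truth, qpcr_model, seed=_spawn_seed(rng))
    return ScenarioBundle(
        truth=truth,
        models=models,
        annotations=annotations,
        datasets=datasets,
        ct=ct,
        qpcr_model=qpcr_model,
        seed=seed,
    )


def write_scenario(bundle: ScenarioBundle, out_dir: str) -> str:
    """Write a bundle to the TSV/YAML interchange formats + truth sidecar."""
    from mirconcord import io as mio

    mio.ensure_dir(out_dir)
    design_cfg: dict = {"seed": bundle.seed, "platforms": {}}
    for pid in bundle.platform_ids:
        ds = bundle.datasets[pid]
        mio.write_intensity_table(ds, f"{out_dir}/{pid}.intensities.tsv")
        mio.write_probe_annotation(
            bundle.annotations[pid], f"{out_dir}/{pid}.annotation.tsv"
        )
        entry = {
            "color_mode": ds.color_mode,
            "intensities": f"{pid}.intensities.tsv",
            "annotation": f"{pid}.annotation.tsv",
            "detection_rule": bundle.models[pid].detection_rule,
            "negative_controls": sorted(ds.negative_control_ids),
            "arrays": [
                {
                    "array_id": a.array_id,
                    "channels": dict(a.channel_to_sample),
                    "replicate_index": a.replicate_index,
                    "is_dye_swap": a.is_dye_swap,
                }
                for a in ds.arrays
            ],
        }
        if ds.background is not None:
            bg_path = f"{pid}.background.tsv"
            ds.background.rename_axis("probe_id").to_csv(
                f"{out_dir}/{bg_path}", sep="\t", na_rep="NA"
            )
            entry["background"] = bg_path
        design_cfg["platforms"][pid] = entry
    design_cfg["qpcr"] = {"ct_table": "qpcr.ct.tsv", "reference_gene": "U6"}
    mio.write_ct_table(bundle.ct, f"{out_dir}/qpcr.ct.tsv")
    bundle.truth.abundance.assign(
        log_ratio=bundle.truth.log_ratio,
        is_differential=bundle.truth.is_differential,
    ).rename_axis("mirna_name").to_csv(f"{out_dir}/truth.tsv", sep="\t")
    mio.write_design(design_cfg, f"{out_dir}/design.yaml")
    return out_dir
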
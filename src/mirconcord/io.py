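"""Plain-text interchange formats (TSV + YAML).

The analysis consumes per-array median foreground signal only, so the
intensity reader takes a TSV with a ``probe_id`` column plus one column
per (array, channel) pair named ``"<array_id>.<channel>"``, with the
array design described separately in YAML.  Annotation and Ct tables are
likewise one-line-header TSVs.  Values round-trip bit-for-bit through
:func:`pandas.read_csv` / ``to_csv`` with full float precision; derived
statistics are written to six decimals.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from mirconcord.matching import canonicalize_sequence
from mirconcord.types import (
    AgreementEstimate,
    ArrayDesign,
    CtTable,
    FormatError,
    IntensityDataset,
    PermutationTestResult,
    ProbeAnnotation,
    ValidationError,
)

_NA_VALUES = ["", "NA", "NaN", "nan", "Undetermined"]


def read_intensity_table(
    path: str,
    arrays: Sequence[ArrayDesign],
    platform_id: str = "",
    color_mode: str = "one",
    background_path: str | None = None,
    negative_control_ids: Sequence[str] = (),
) -> IntensityDataset:
    """Read a probe × (array, channel) intensity TSV against a design.

    Rows with missing signal are retained with NaN (never imputed).  A
    design column absent from the file header is a :class:`FormatError`;
    negative signal is a :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: missing 'probe_id' column")
    df = df.set_index("probe_id")
    expected = [c for a in arrays for c in a.columns()]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: header omits design column(s) {missing}")
    values = df[expected].astype(float)
    background = None
    if background_path is not None:
        bg = pd.read_csv(
            background_path, sep="\t", na_values=_NA_VALUES, keep_default_na=False
        ).set_index("probe_id")
        bg_missing = [c for c in expected if c not in bg.columns]
        if bg_missing:
            raise FormatError(f"{background_path}: header omits column(s) {bg_missing}")
        background = bg[expected].astype(float).reindex(values.index)
    return IntensityDataset(
        platform_id=platform_id,
        color_mode=color_mode,
        arrays=list(arrays),
        values=values,
        background=background,
        negative_control_ids=frozenset(negative_control_ids),
    )


def write_intensity_table(dataset: IntensityDataset, path: str) -> None:
    dataset.values.rename_axis("probe_id").to_csv(path, sep="\t", na_rep="NA")


def read_probe_annotation(
    path: str, platform_id: str = "", annotation_version: str = ""
) -> list[ProbeAnnotation]:
    """Read a probe annotation TSV, canonicalizing sequences.

    Columns: probe_id, mirna_name, sequence, is_negative_control.
    Duplicate probe_ids and illegal nucleotide characters are rejected
    (naming the offending row); negative-control rows may have an empty
    sequence.
    """
    df = pd.read_csv(
        path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype=str
    )
    required = ["probe_id", "mirna_name", "sequence", "is_negative_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    dup = df["probe_id"][df["probe_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate probe_id(s) {sorted(set(dup))}")
    out = []
    for row in df.itertuples(index=False):
        is_ctrl = str(row.is_negative_control).strip().lower() in ("true", "1", "yes")
        raw_seq = "" if pd.isna(row.sequence) else str(row.sequence)
        if raw_seq:
            try:
                seq = canonicalize_sequence(raw_seq)
            except ValidationError as exc:
                raise ValidationError(
                    f"{path}: probe {row.probe_id!r}: {exc}"
                ) from exc
        elif is_ctrl:
            seq = ""
        else:
            raise ValidationError(
                f"{path}: probe {row.probe_id!r}: empty sequence on a non-control probe"
            )
        out.append(
            ProbeAnnotation(
                probe_id=str(row.probe_id),
                mirna_name="" if pd.isna(row.mirna_name) else str(row.mirna_name),
                sequence=seq,
                platform_id=platform_id,
                annotation_version=annotation_version,
                is_negative_control=is_ctrl,
            )
        )
    return out


def write_probe_annotation(annotations: Sequence[ProbeAnnotation], path: str) -> None:
    pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in annotations],
            "mirna_name": [p.mirna_name for p in annotations],
            "sequence": [p.sequence for p in annotations],
            "is_negative_control": [
                str(p.is_negative_control).lower() for p in annotations
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(
    path: str, reference_gene: str = "U6", detection_ct: float = 35.0
) -> CtTable:
    """Read a miRNA × sample-replicate Ct TSV ("Undetermined" → NaN)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if "mirna_name" not in df.columns:
        raise FormatError(f"{path}: missing 'mirna_name' column")
    df = df.set_index("mirna_name").astype(float)
    return CtTable(ct=df, reference_gene=reference_gene, detection_ct=detection_ct)


def write_ct_table(ct: CtTable, path: str) -> None:
    ct.ct.rename_axis("mirna_name").to_csv(path, sep="\t", na_rep="Undetermined")


def write_agreement_report(
    estimates: Sequence[AgreementEstimate], path: str
) -> None:
    """Write agreement estimates to TSV (six-decimal statistics).

    Rows are ordered lexicographically by contrast label, then method,
    then probe set (``pairwise_present`` before ``common_all``).
    """
    if not estimates:
        raise ValidationError("no agreement estimates to write")
    order = {"pairwise_present": 0, "common_all": 1}
    rows = sorted(estimates, key=lambda e: (e.label, e.method, order[e.probe_set]))
    pd.DataFrame(
        {
            "label": [e.label for e in rows],
            "method": [e.method for e in rows],
            "probe_set": [e.probe_set for e in rows],
            "n": [e.n for e in rows],
            "estimate": [round(e.estimate, 6) for e in rows],
            "se": [_round6(e.se) for e in rows],
            "ci_low": [_round6(e.ci_low) for e in rows],
            "ci_high": [_round6(e.ci_high) for e in rows],
        }
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def _round6(v: float) -> float:
    return float("nan") if v is None or not np.isfinite(v) else round(v, 6)


def read_agreement_report(path: str) -> list[AgreementEstimate]:
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    return [
        AgreementEstimate(
            method=r.method,
            estimate=float(r.estimate),
            se=float(r.se),
            ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
            n=int(r.n),
            probe_set=r.probe_set,
            label=r.label,
        )
        for r in df.itertuples(index=False)
    ]


def write_permutation_report(
    results: Sequence[PermutationTestResult], path: str
) -> None:
    if not results:
        raise ValidationError("no permutation results to write")
    rows = sorted(results, key=lambda r: r.label)
    pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "observed_diff": [round(r.observed_diff, 6) for r in rows],
            "p_value": [round(r.p_value, 6) for r in rows],
            "p_adjusted": [
                _round6(getattr(r, "p_adjusted", float("nan"))) for r in rows
            ],
            "n_permutations": [r.n_permutations for r in rows],
            "seed": [r.seed for r in rows],
            "correction": [r.correction for r in rows],
        }
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_venn_counts(counts: dict[frozenset, int], platforms: Sequence[str], path: str) -> None:
    """Venn cells as TSV: a platform-membership bitmask, member list, count."""
    platforms = list(platforms)
    rows = []
    for subset, count in counts.items():
        mask = "".join("1" if p in subset else "0" for p in platforms)
        rows.append((mask, "+".join(sorted(subset)), count))
    rows.sort()
    pd.DataFrame(rows, columns=["bitmask", "platforms", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_design(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: design YAML must be a mapping")
    return cfg


def design_from_config(entry: dict) -> list[ArrayDesign]:
    try:
        return [
            ArrayDesign(
                array_id=str(a["array_id"]),
                channel_to_sample=dict(a["channels"]),
                replicate_index=int(a.get("replicate_index", 1)),
                is_dye_swap=bool(a.get("is_dye_swap", False)),
            )
            for a in entry["arrays"]
        ]
    except KeyError as exc:
        raise FormatError(f"design entry missing key {exc}") from exc


def write_design(platform_entries: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(platform_entries, fh, sort_keys=True)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
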
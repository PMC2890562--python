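"""Core data containers for the concordance pipeline.

Probe-level intensities live in pandas DataFrames indexed by ``probe_id``
with one column per hybridized (array, channel) pair, labelled
``"<array_id>.<channel>"``.  miRNA-level (collapsed) data are indexed by a
canonical miRNA key.  Samples are the two reference RNA pools, labelled
``"Ref1"`` and ``"Ref2"`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SAMPLES = ("Ref1", "Ref2")


class ValidationError(ValueError):
    """Raised when data violate a structural or value constraint."""


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe of a platform's catalogue.

    ``sequence`` is the canonical DNA-alphabet probe/target sequence
    (uppercase, U→T); negative-control probes may have an empty sequence.
    Several ``probe_id`` values may share a ``mirna_name`` — these are
    spot-level technical replicates.
    """

    probe_id: str
    mirna_name: str
    sequence: str
    platform_id: str = ""
    annotation_version: str = ""
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValidationError("probe_id must be non-empty")
        if not self.is_negative_control:
            if not self.sequence:
                raise ValidationError(
                    f"probe {self.probe_id!r}: non-control probes need a sequence"
                )
            bad = set(self.sequence) - set("ACGT")
            if bad:
                raise ValidationError(
                    f"probe {self.probe_id!r}: sequence not canonical "
                    f"(unexpected characters {sorted(bad)})"
                )


@dataclass(frozen=True)
class ArrayDesign:
    """Design metadata for one hybridized array.

    ``channel_to_sample`` maps channel names (e.g. ``"Cy3"``) to the sample
    hybridized on that channel; one entry for one-color arrays, exactly two
    for two-color arrays.
    """

    array_id: str
    channel_to_sample: Mapping[str, str]
    replicate_index: int = 1
    is_dye_swap: bool = False

    def __post_init__(self) -> None:
        if not self.channel_to_sample:
            raise ValidationError(f"array {self.array_id!r}: no channels")
        for ch, s in self.channel_to_sample.items():
            if s not in SAMPLES:
                raise ValidationError(
                    f"array {self.array_id!r}, channel {ch!r}: sample {s!r} "
                    f"not in {SAMPLES}"
                )
        if self.replicate_index < 1:
            raise ValidationError(
                f"array {self.array_id!r}: replicate_index must be >= 1"
            )

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_to_sample)

    def columns(self) -> list[str]:
        """Column labels this array contributes to the intensity matrix."""
        return [f"{self.array_id}.{ch}" for ch in self.channel_to_sample]


@dataclass
class IntensityDataset:
    """Probe × (array, channel) signal matrix plus design metadata.

    ``values`` holds raw (linear-scale, non-negative) intensities unless
    ``normalized`` is set.  ``background`` optionally carries a same-shape
    matrix of per-spot background standard deviations, consumed only by the
    background-SD + CV detection rule.
    """

    platform_id: str
    color_mode: str
    arrays: list[ArrayDesign]
    values: pd.DataFrame
    background: pd.DataFrame | None = None
    normalized: bool = False
    negative_control_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.color_mode not in ("one", "two"):
            raise ValidationError(f"color_mode must be 'one' or 'two', got {self.color_mode!r}")
        expected = [c for a in self.arrays for c in a.columns()]
        missing = [c for c in expected if c not in self.values.columns]
        if missing:
            raise FormatError(
                f"platform {self.platform_id!r}: intensity table lacks design "
                f"column(s) {missing}"
            )
        for a in self.arrays:
            n_ch = len(a.channel_to_sample)
            if self.color_mode == "one" and n_ch != 1:
                raise ValidationError(f"one-color array {a.array_id!r} has {n_ch} channels")
            if self.color_mode == "two":
                if n_ch != 2:
                    raise ValidationError(f"two-color array {a.array_id!r} has {n_ch} channels")
                if len(set(a.channel_to_sample.values())) != 2:
                    raise ValidationError(
                        f"two-color array {a.array_id!r} must carry both samples"
                    )
        vals = self.values[expected].to_numpy(dtype=float)
        if not self.normalized and np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError(
                f"platform {self.platform_id!r}: negative raw intensities"
            )
        if self.background is not None:
            if self.background.shape != self.values.shape:
                raise ValidationError("background matrix shape differs from values")

    def sample_of(self, column: str) -> str:
        """Sample (Ref1/Ref2) hybridized on an (array, channel) column."""
        array_id, channel = column.rsplit(".", 1)
        for a in self.arrays:
            if a.array_id == array_id:
                return a.channel_to_sample[channel]
        raise KeyError(column)

    def columns_for_sample(self, sample: str) -> list[str]:
        out = []
        for a in self.arrays:
            for ch, s in a.channel_to_sample.items():
                if s == sample:
                    out.append(f"{a.array_id}.{ch}")
        return out

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class CtTable:
    """qRT-PCR cycle-threshold values, miRNA × sample replicate.

    Columns are named ``"Ref1.1"``, ``"Ref1.2"``, ``"Ref2.1"``, ... ;
    NaN marks undetermined wells.  The reference (housekeeping) gene row is
    required and used for ΔCt normalization.
    """

    ct: pd.DataFrame
    reference_gene: str = "U6"
    detection_ct: float = 35.0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.index:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} not found in Ct table"
            )
        arr = self.ct.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(arr[np.isfinite(arr)] <= 0):
                raise ValidationError("Ct values must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)


@dataclass
class MatchedSet:
    """Cross-platform probe groups keyed by canonical miRNA.

    ``entries[key][platform_id]`` lists the probe_ids matched to that miRNA
    on that platform.  Only keys represented on at least two platforms are
    retained by cross-platform matching; ``dropped_ambiguous`` records keys
    discarded because a sequence matched probes of two distinct miRNAs.
    """

    entries: dict[str, dict[str, list[str]]]
    platforms: list[str]
    dropped_ambiguous: list[str] = field(default_factory=list)

    @property
    def n_platforms(self) -> int:
        return len(self.platforms)

    def keys_on(self, platform_ids: Iterable[str]) -> list[str]:
        """Matched keys represented on every listed platform (sorted)."""
        wanted = list(platform_ids)
        return sorted(
            k for k, m in self.entries.items() if all(p in m for p in wanted)
        )

    def keys_spanning_all(self) -> list[str]:
        return self.keys_on(self.platforms)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CollapsedExpression:
    """Per-miRNA expression after technical-replicate collapsing.

    ``values`` rows are canonical miRNA keys; each value is the median of
    the contributing technical-replicate spots (NaN excluded).  ``absent``
    is True wherever at least one contributing spot was flagged absent
    (or, under the majority rule, fewer than the required fraction passed).
    """

    platform_id: str
    color_mode: str
    values: pd.DataFrame
    absent: pd.DataFrame
    arrays: list[ArrayDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != self.absent.shape:
            raise ValidationError("values/absent shape mismatch")

    def present_mirnas(self, how: str = "all") -> set[str]:
        """miRNAs called present: 'all' = present in every column, 'any' = in at least one."""
        present = ~self.absent
        mask = present.all(axis=1) if how == "all" else present.any(axis=1)
        return set(self.values.index[mask])


@dataclass
class LogRatioSet:
    """Per-miRNA log2(Ref1/Ref2) ratios for every reference pairing.

    For a one-color 2+2 design the four pairings are
    ``R1.1/R2.1, R1.1/R2.2, R1.2/R2.1, R1.2/R2.2``; for a two-color design
    each array's dye-orientation-corrected M value is one pairing.
    ``mean_log_ratio`` is the NaN-aware mean over pairings.
    """

    platform_id: str
    pairings: pd.DataFrame
    present: pd.Series

    def __post_init__(self) -> None:
        if not self.pairings.index.equals(self.present.index):
            raise ValidationError("pairings/present index mismatch")

    @property
    def mean_log_ratio(self) -> pd.Series:
        return self.pairings.mean(axis=1, skipna=True)

    @property
    def mirnas(self) -> pd.Index:
        return self.pairings.index


@dataclass(frozen=True)
class AgreementEstimate:
    """A correlation-type agreement statistic with bootstrap uncertainty."""

    method: str  # "spearman" | "ccc"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    probe_set: str  # "pairwise_present" | "common_all"
    label: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "ccc"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.probe_set not in ("pairwise_present", "common_all"):
            raise ValidationError(f"unknown probe_set {self.probe_set!r}")
        if self.n < 3:
            raise ValidationError("agreement estimates require n >= 3 miRNAs")
        if not np.isnan(self.se) and self.se < 0:
            raise ValidationError("se must be >= 0")
        if not (
            np.isnan(self.ci_low)
            or self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12
        ):
            raise ValidationError("estimate outside its confidence interval")


@dataclass(frozen=True)
class PermutationTestResult:
    """Permutation test for a difference between two correlations."""

    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int
    correction: str = "none"
    label: str = ""
    p_adjusted: float = float("nan")

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        if not (lo - 1e-12 <= self.p_value <= 1.0 + 1e-12):
            raise ValidationError(
                f"p-value {self.p_value} outside [{lo}, 1] for "
                f"{self.n_permutations} permutations"
            )
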
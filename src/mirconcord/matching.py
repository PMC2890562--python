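"""Sequence-based probe matching across platforms and replicate collapsing.

Platforms are designed against different miRBase releases, so the same
mature miRNA can carry different names (or the same name different
sequences) on different arrays.  Probes are therefore merged by name first
and then verified by sequence, with sequence as the final authority: two
probes match when their canonical sequences are equal or the shorter is a
contiguous substring of the longer (shorter capture probes are embedded in
longer ones on other chemistries).
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mirconcord.types import (
    CollapsedExpression,
    IntensityDataset,
    MatchedSet,
    ProbeAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

_CANONICAL = set("ACGT")
_ALLOWED = set("ACGTUacgtu")


def canonicalize_sequence(seq: str) -> str:
    """Normalize a probe/miRNA sequence to the uppercase DNA alphabet.

    RNA bases are mapped U→T and case is folded; no reverse complementing
    is performed.  Raises :class:`ValidationError` on an empty sequence or
    characters outside {A, C, G, T, U}.
    """
    if not seq:
        raise ValidationError("empty sequence")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValidationError(f"illegal nucleotide character(s) {sorted(bad)} in {seq!r}")
    return seq.upper().replace("U", "T")


def sequences_match(a: str, b: str) -> bool:
    """True when two canonical sequences are equal or one contains the other.

    The containment rule reflects platforms whose capture probes embed a
    shorter probe's sequence; it is symmetric and reflexive.
    """
    for s in (a, b):
        if not s or set(s) - _CANONICAL:
            raise ValidationError(f"sequence {s!r} is not canonical; canonicalize first")
    if len(a) <= len(b):
        return a in b
    return b in a


def _group_probes(
    annotations: Mapping[str, Sequence[ProbeAnnotation]],
) -> dict[str, dict[str, list[ProbeAnnotation]]]:
    """name -> platform -> probes, excluding negative controls."""
    by_name: dict[str, dict[str, list[ProbeAnnotation]]] = {}
    for platform_id, probes in annotations.items():
        informative = [p for p in probes if not p.is_negative_control]
        if not informative:
            raise ValidationError(f"platform {platform_id!r} has no annotated probes")
        for p in informative:
            by_name.setdefault(p.mirna_name, {}).setdefault(platform_id, []).append(p)
    return by_name


def match_across_platforms(
    annotations: Mapping[str, Sequence[ProbeAnnotation]],
) -> MatchedSet:
    """Match probes across ≥2 platforms by name merge + sequence verification.

    Candidate groups are formed by exact miRNA-name equality; groups whose
    members fail the pairwise sequence-containment check are discarded.
    Name-discordant probes with identical sequences are additionally merged
    (sequence is authoritative).  Entries whose sequences ambiguously match
    two distinct miRNAs' probes on another platform are dropped and logged,
    so ambiguity cannot inflate downstream concordance.

    Returns a :class:`MatchedSet` whose entries all span ≥2 platforms, in
    lexicographic key order.
    """
    platforms = sorted(annotations)
    if len(platforms) < 2:
        raise ValidationError("cross-platform matching needs >= 2 platforms")
    by_name = _group_probes(annotations)

    # union-find over names: merge names that share an identical sequence
    parent: dict[str, str] = {n: n for n in by_name}

    def find(n: str) -> str:
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lexicographically smaller name as canonical key
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    seq_to_names: dict[str, set[str]] = {}
    for name, per_platform in by_name.items():
        for probes in per_platform.values():
            for p in probes:
                seq_to_names.setdefault(p.sequence, set()).add(name)
    for names in seq_to_names.values():
        names = sorted(names)
        for other in names[1:]:
            union(names[0], other)

    merged: dict[str, dict[str, list[ProbeAnnotation]]] = {}
    for name, per_platform in by_name.items():
        key = find(name)
        slot = merged.setdefault(key, {})
        for platform_id, probes in per_platform.items():
            slot.setdefault(platform_id, []).extend(probes)

    # retain groups spanning >=2 platforms whose members pairwise match
    entries: dict[str, dict[str, list[str]]] = {}
    key_of_probe: dict[tuple[str, str], str] = {}
    for key in sorted(merged):
        per_platform = merged[key]
        if len(per_platform) < 2:
            continue
        members = [
            (pl, p) for pl in sorted(per_platform) for p in per_platform[pl]
        ]
        ok = all(
            sequences_match(p.sequence, q.sequence)
            for (pla, p), (plb, q) in itertools.combinations(members, 2)
            if pla != plb
        )
        if not ok:
            logger.info("match group %r rejected: cross-platform sequences disagree", key)
            continue
        entries[key] = {
            pl: sorted(p.probe_id for p in per_platform[pl])
            for pl in sorted(per_platform)
        }
        for pl, p in members:
            key_of_probe[(pl, p.sequence)] = key

    # cross-entry containment: sequence is authoritative, so two entries
    # whose sequences match across platforms are candidates for merging
    # (e.g. the same miRNA under old and "-5p" style names with different
    # probe lengths); a merge that fails the pairwise check is a genuine
    # ambiguity and both entries are dropped
    seq_index: list[tuple[str, str, str]] = [
        (pl, seq, key) for (pl, seq), key in key_of_probe.items()
    ]
    link: dict[str, str] = {k: k for k in entries}

    def efind(k: str) -> str:
        while link[k] != k:
            link[k] = link[link[k]]
            k = link[k]
        return k

    for (pla, sa, ka), (plb, sb, kb) in itertools.combinations(seq_index, 2):
        if ka == kb or pla == plb or ka not in entries or kb not in entries:
            continue
        if sequences_match(sa, sb):
            ra, rb = sorted((efind(ka), efind(kb)))
            link[rb] = ra
    components: dict[str, list[str]] = {}
    for k in entries:
        components.setdefault(efind(k), []).append(k)

    dropped: set[str] = set()
    for root, keys in components.items():
        if len(keys) == 1:
            continue
        candidate: dict[str, list[ProbeAnnotation]] = {}
        for k in keys:
            for pl_id, probes in merged[k].items():
                candidate.setdefault(pl_id, []).extend(probes)
        members = [
            (pl_id, p) for pl_id in sorted(candidate) for p in candidate[pl_id]
        ]
        ok = all(
            sequences_match(p.sequence, q.sequence)
            for (pla, p), (plb, q) in itertools.combinations(members, 2)
            if pla != plb
        )
        if ok:
            key = min(keys)
            logger.info("merging sequence-linked entries %s under %r", keys, key)
            for k in keys:
                entries.pop(k, None)
            entries[key] = {
                pl_id: sorted(p.probe_id for p in candidate[pl_id])
                for pl_id in sorted(candidate)
            }
        else:
            logger.warning(
                "ambiguous cross-platform containment among %s; dropping all", keys
            )
            dropped.update(keys)
            for k in keys:
                entries.pop(k, None)

    return MatchedSet(
        entries=dict(sorted(entries.items())),
        platforms=platforms,
        dropped_ambiguous=sorted(dropped),
    )


def collapse_replicates(
    dataset_values: pd.DataFrame,
    annotations: Sequence[ProbeAnnotation],
    detection: pd.DataFrame,
    *,
    platform_id: str = "",
    color_mode: str = "one",
    arrays: list | None = None,
    consensus: str = "any_absent",
    min_present_fraction: float = 0.5,
) -> CollapsedExpression:
    """Collapse spot-level technical replicates to one value per miRNA.

    Per (miRNA, column) the collapsed value is the median of the
    contributing probes' values with NaN dropped; an even count takes the
    mean of the two central values.  Flag propagation follows ``consensus``:

    - ``"any_absent"``: the collapsed observation is absent if at least one
      contributing spot was flagged absent (the negative-control-rule
      convention);
    - ``"majority"``: present only if at least ``min_present_fraction`` of
      the spots passed (the background-SD + CV rule convention).

    ``detection`` is a probe × column boolean matrix, True = present.
    A miRNA whose contributors are all NaN gets value NaN and absent=True.
    """
    if isinstance(dataset_values, IntensityDataset):
        ds = dataset_values
        dataset_values = ds.values
        platform_id = platform_id or ds.platform_id
        color_mode = ds.color_mode
        arrays = arrays or ds.arrays
    if consensus not in ("any_absent", "majority"):
        raise ValidationError(f"unknown consensus {consensus!r}")
    if not detection.index.equals(dataset_values.index) or list(
        detection.columns
    ) != list(dataset_values.columns):
        raise ValidationError("detection matrix not aligned to dataset")

    probe_to_mirna = {
        p.probe_id: p.mirna_name for p in annotations if not p.is_negative_control
    }
    known = dataset_values.index.intersection(list(probe_to_mirna))
    vals = dataset_values.loc[known]
    det = detection.loc[known]
    groups = pd.Index([probe_to_mirna[p] for p in known], name="mirna")

    collapsed = vals.groupby(groups).median()
    if consensus == "any_absent":
        absent = (~det).groupby(groups).any()
    else:
        frac_present = det.astype(float).groupby(groups).mean()
        absent = frac_present < min_present_fraction
    all_nan = vals.isna().groupby(groups).all()
    absent = absent | all_nan
    collapsed = collapsed.sort_index()
    absent = absent.loc[collapsed.index]
    return CollapsedExpression(
        platform_id=platform_id,
        color_mode=color_mode,
        values=collapsed,
        absent=absent,
        arrays=arrays or [],
    )


def present_intersections(
    present_sets: Mapping[str, Iterable[str]],
    qpcr_detected: Iterable[str] | None = None,
) -> dict[frozenset[str], int]:
    """Venn-cell counts of present miRNAs over every platform subset.

    For each non-empty subset S of platforms, the count of miRNAs present
    on exactly the platforms in S (the exclusive Venn cell).  The special
    key ``frozenset(all platforms)`` is thus the all-platform intersection.
    If ``qpcr_detected`` is given, the universe is first restricted to
    miRNAs with valid qPCR detection.
    """
    platforms = sorted(present_sets)
    if len(platforms) < 2:
        raise ValidationError("need >= 2 platforms for intersections")
    sets = {p: set(present_sets[p]) for p in platforms}
    if qpcr_detected is not None:
        q = set(qpcr_detected)
        sets = {p: s & q for p, s in sets.items()}
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(platforms) + 1):
        for subset in itertools.combinations(platforms, r):
            inside = set.intersection(*(sets[p] for p in subset))
            outside = set().union(*(sets[p] for p in platforms if p not in subset)) if len(subset) < len(platforms) else set()
            counts[frozenset(subset)] = len(inside - outside)
    return counts


def all_platform_intersection(
    present_sets: Mapping[str, Iterable[str]],
    qpcr_detected: Iterable[str] | None = None,
) -> set[str]:
    """miRNAs present on every platform (optionally ∩ qPCR-detected)."""
    common = set.intersection(*(set(s) for s in present_sets.values()))
    if qpcr_detected is not None:
        common &= set(qpcr_detected)
    return common
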
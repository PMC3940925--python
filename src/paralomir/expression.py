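"""Arm assignment and expression quantification.

A hairpin precursor is processed into two mature strands.  The start
position with the highest read count summed across tissues defines the
major (guide) form and its arm; the highest-count start on the opposite arm
defines the minor (passenger) form.  Precursor expression sums all mapped
reads; per-tissue counts are normalized to reads per million (RPM) against
the tissue's library total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PrecursorAnnotation, ReadMappingTable

RPM_SCALE = 1_000_000.0


@dataclass
class ArmProfile:
    """Per-precursor guide/passenger assignment with per-tissue count vectors."""

    precursor_id: str
    major_position: int | None
    major_arm: str | None
    minor_position: int | None
    major_counts: pd.Series  # indexed by tissue
    minor_counts: pd.Series
    precursor_counts: pd.Series
    flags: list[str] = field(default_factory=list)

    @property
    def minor_arm(self) -> str | None:
        if self.major_arm is None:
            return None
        return "3p" if self.major_arm == "5p" else "5p"

    @property
    def major_total(self) -> int:
        return int(self.major_counts.sum())

    @property
    def minor_total(self) -> int:
        return int(self.minor_counts.sum())


@dataclass
class ExpressionMatrix:
    """Entity × tissue expression values, raw read counts or RPM."""

    values: pd.DataFrame  # index: entity ids, columns: tissues
    scale: str = "raw"  # "raw" | "rpm"

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def total(self) -> float:
        return float(self.values.to_numpy().sum())


def _argmax_start(by_start: pd.Series) -> int:
    """Start with the maximal summed count; ties resolved to the 5'-most start."""
    top = by_start[by_start == by_start.max()]
    return int(min(top.index))


def assign_arms(
    reads: ReadMappingTable,
    annotations: list[PrecursorAnnotation] | dict[str, PrecursorAnnotation],
) -> list[ArmProfile]:
    """Assign major/minor forms per precursor from read pile-ups.

    The major form is the start position with the highest count summed over
    all tissues; its arm (5p/3p) comes from the annotation (hairpin midpoint
    split when arms are not explicit).  The minor form is the highest-count
    start on the opposite arm.  Precursors with no reads, or reads on a
    single arm only, are returned flagged rather than dropped.
    """
    if not isinstance(annotations, dict):
        annotations = {a.precursor_id: a for a in annotations}
    tissues = reads.tissues
    zeros = pd.Series(0, index=tissues, dtype=np.int64)
    profiles: list[ArmProfile] = []
    grouped = dict(iter(reads.records.groupby("precursor_id"))) if len(reads.records) else {}
    for pid in sorted(annotations):
        ann = annotations[pid]
        sub = grouped.get(pid)
        if sub is None or not len(sub):
            profiles.append(
                ArmProfile(pid, None, None, None, zeros.copy(), zeros.copy(), zeros.copy(),
                           flags=["no_reads"])
            )
            continue
        per_tissue = sub.pivot_table(
            index="start", columns="tissue", values="count", aggfunc="sum", fill_value=0
        ).reindex(columns=tissues, fill_value=0)
        by_start = per_tissue.sum(axis=1)
        major_pos = _argmax_start(by_start)
        major_arm = ann.arm_of_position(major_pos)
        opposite = [p for p in by_start.index if ann.arm_of_position(p) != major_arm]
        flags: list[str] = []
        if opposite:
            minor_pos = _argmax_start(by_start.loc[opposite])
            minor_counts = per_tissue.loc[minor_pos].astype(np.int64)
        else:
            minor_pos = None
            minor_counts = zeros.copy()
            flags.append("single_arm")
        profiles.append(
            ArmProfile(
                precursor_id=pid,
                major_position=major_pos,
                major_arm=major_arm,
                minor_position=minor_pos,
                major_counts=per_tissue.loc[major_pos].astype(np.int64),
                minor_counts=minor_counts,
                precursor_counts=per_tissue.sum(axis=0).astype(np.int64),
                flags=flags,
            )
        )
    return profiles


def mature_name(profile: ArmProfile, annotation: PrecursorAnnotation | None, form: str) -> str:
    """Mature-form label: the annotated mature ID on that arm when available."""
    arm = profile.major_arm if form == "major" else profile.minor_arm
    if annotation is not None and arm is not None:
        rec = annotation.mature_on_arm(arm)
        if rec is not None:
            return rec[0]
    suffix = arm or form
    return f"{profile.precursor_id}-{suffix}"


def quantify(
    reads: ReadMappingTable,
    profiles: list[ArmProfile],
    level: str = "precursor",
    annotations: list[PrecursorAnnotation] | dict[str, PrecursorAnnotation] | None = None,
) -> ExpressionMatrix:
    """Build the entity × tissue raw count matrix at a given level.

    ``precursor`` sums reads over all start positions; ``major``/``minor``
    take the designated start's per-tissue counts.  At the mature levels the
    row label is the annotated mature ID when annotations are given, so that
    paralogous precursors sharing a major mature keep one row per precursor
    but a shared naming scheme is available through :func:`mature_name`.
    """
    if level not in {"precursor", "major", "minor"}:
        raise ValueError(f"unknown quantification level {level!r}")
    if annotations is not None and not isinstance(annotations, dict):
        annotations = {a.precursor_id: a for a in annotations}
    tissues = reads.tissues
    rows = {}
    for prof in profiles:
        if level == "precursor":
            vec = prof.precursor_counts
        elif level == "major":
            vec = prof.major_counts
        else:
            vec = prof.minor_counts
        rows[prof.precursor_id] = vec.reindex(tissues, fill_value=0)
    df = pd.DataFrame(rows).T
    df.columns = tissues
    return ExpressionMatrix(values=df.astype(float), scale="raw")


def normalize(
    matrix: ExpressionMatrix,
    tissue_totals: pd.Series | dict[str, float],
    scale: float = RPM_SCALE,
) -> ExpressionMatrix:
    """Normalize raw counts to reads per million of the tissue's library total.

    ``tissue_totals`` is the total number of mapped reads per tissue (the
    full library, not just the entities in ``matrix``).  A zero total with
    nonzero counts is an impossible state and raises.
    """
    totals = pd.Series(tissue_totals, dtype=float).reindex(matrix.tissues)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"no library total for tissue(s): {missing}")
    col_sums = matrix.values.sum(axis=0)
    bad = (totals == 0) & (col_sums > 0)
    if bad.any():
        raise ValueError(f"zero library total but nonzero counts in {list(totals.index[bad])}")
    safe = totals.replace(0, np.nan)
    out = matrix.values.div(safe, axis=1).mul(scale).fillna(0.0)
    return ExpressionMatrix(values=out, scale="rpm")


def arm_ratios(
    profiles: list[ArmProfile],
    min_total: int = 50,
    filter_on: str = "major",
) -> pd.DataFrame:
    """Major/minor expression ratios and arm-switch tissues.

    Pairs are retained when the major form's cross-tissue total (or, with
    ``filter_on="combined"``, major+minor) exceeds ``min_total`` strictly.
    ``ratio`` is major_total/minor_total (``inf`` when the minor has no
    reads); ``arm_switch_tissues`` lists tissues where the minor per-tissue
    count exceeds the major's.
    """
    if filter_on not in {"major", "combined"}:
        raise ValueError(f"filter_on must be 'major' or 'combined', got {filter_on!r}")
    rows = []
    for prof in profiles:
        basis = prof.major_total if filter_on == "major" else prof.major_total + prof.minor_total
        if basis <= min_total:
            continue
        ratio = prof.major_total / prof.minor_total if prof.minor_total else math.inf
        switches = [
            t for t in prof.major_counts.index
            if prof.minor_counts[t] > prof.major_counts[t]
        ]
        rows.append(
            {
                "precursor_id": prof.precursor_id,
                "major_total": prof.major_total,
                "minor_total": prof.minor_total,
                "ratio": ratio,
                "arm_switch_tissues": ",".join(switches),
            }
        )
    return pd.DataFrame(
        rows, columns=["precursor_id", "major_total", "minor_total", "ratio", "arm_switch_tissues"]
    )
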
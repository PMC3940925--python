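"""End-to-end convenience layer: reads + annotations → discrimination report.

Glue over the module surface: builds mature-level matrices (rows of
paralogous members sharing a major mature form are summed into one shared
major row), assembles the coexpression inputs with the precursor-level
matrix as the read universe, and runs the family discrimination screen.
"""

from __future__ import annotations

import pandas as pd

from . import association, coexpression, expression, families as families_mod
from .expression import ArmProfile, mature_name
from .io import PrecursorAnnotation, ReadMappingTable


def mature_level_matrices(
    reads: ReadMappingTable,
    annotations: list[PrecursorAnnotation],
    profiles: list[ArmProfile],
) -> dict:
    """Raw count matrices keyed by mature IDs plus the precursor universe.

    Returns dict with ``major`` (mature-ID rows; paralogous members summed),
    ``minor`` (one row per member minor), ``universe`` (precursor-level),
    and the maps ``major_of_precursor`` / ``minor_of_precursor``.
    """
    ann_by_id = {a.precursor_id: a for a in annotations}
    major_raw = expression.quantify(reads, profiles, level="major")
    minor_raw = expression.quantify(reads, profiles, level="minor")
    universe = expression.quantify(reads, profiles, level="precursor")

    major_of, minor_of = {}, {}
    for prof in profiles:
        ann = ann_by_id.get(prof.precursor_id)
        major_of[prof.precursor_id] = mature_name(prof, ann, "major")
        minor_of[prof.precursor_id] = mature_name(prof, ann, "minor")

    major = major_raw.values.groupby(
        major_raw.values.index.map(major_of)
    ).sum()
    minor = minor_raw.values.groupby(
        minor_raw.values.index.map(minor_of)
    ).sum()
    return {
        "major": major,
        "minor": minor,
        "universe": universe.values,
        "major_of_precursor": major_of,
        "minor_of_precursor": minor_of,
    }


def discriminate(
    reads: ReadMappingTable,
    annotations: list[PrecursorAnnotation],
    family_mode: str = "by_shared_mature_id",
    min_reads: int = 50,
    alpha: float = 0.05,
    top_fraction: float = 0.1,
    correlation_prefilter: bool = False,
    correlation_alpha: float = 0.01,
):
    """Run the full major/minor coexpression discrimination screen.

    Returns (families, CoexpressionReport, CoexpressionInputs).
    """
    profiles = expression.assign_arms(reads, annotations)
    fams = families_mod.find_families(annotations, profiles, mode=family_mode)
    mats = mature_level_matrices(reads, annotations, profiles)
    inputs = coexpression.build_inputs(
        mats["major"], mats["minor"], mats["universe"], min_reads=min_reads
    )
    major_of_family = {}
    minor_of_member = {}
    for fam in fams:
        for member in fam.members:
            minor_of_member[member] = mats["minor_of_precursor"][member]
        major_of_family[fam.family_id] = mats["major_of_precursor"][fam.members[0]]

    correlation_pass = None
    if correlation_prefilter:
        pairs = [
            (mats["major_of_precursor"][m], mats["minor_of_precursor"][m])
            for fam in fams for m in fam.members
        ]
        res = association.correlate_pairs(
            mats["major"], mats["minor"], pairs, alpha=correlation_alpha
        )
        members = [m for fam in fams for m in fam.members]
        correlation_pass = {
            m: (r.defined and r.significant and r.positive)
            for m, r in zip(members, res)
        }

    report = coexpression.discrimination_report(
        fams, inputs, major_of_family, minor_of_member,
        alpha=alpha, top_fraction=top_fraction, correlation_pass=correlation_pass,
    )
    return fams, report, inputs


def contributor_recovery(report, truth: dict) -> tuple[int, int]:
    """(correct calls, planted contributor slots) against a simulation truth."""
    calls = {
        (row.family_id, row.tissue): row.precursor_id
        for row in report.contributors().itertuples()
    }
    planted = truth["contributors"]
    correct = sum(1 for key, pid in planted.items() if calls.get(key) == pid)
    return correct, len(planted)
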
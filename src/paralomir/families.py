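"""Paralogous family grouping, genomic cluster detection and host-gene pairing.

A paralogous family is a set of ≥2 hairpin precursors at distinct genomic
loci whose major mature forms are identical; the distinct minor forms are
what make the members distinguishable.  A miRNA cluster is a run of
same-chromosome, same-strand precursors separated by less than a gap
threshold, typically co-transcribed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .expression import ArmProfile, mature_name
from .io import PrecursorAnnotation

logger = logging.getLogger("paralomir")


@dataclass
class ParalogFamily:
    family_id: str  # shared major mature ID or sequence
    members: list[str]  # precursor ids, ≥2
    minor_ids: dict[str, str]  # precursor -> minor mature id
    indistinguishable: bool = False  # identical minors across members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterPair:
    mirna_a: str
    mirna_b: str
    chromosome: str
    strand: str
    gap_bp: int


def _major_key(
    prof: ArmProfile, ann: PrecursorAnnotation, mode: str
) -> str | None:
    if prof.major_arm is None:
        return None
    rec = ann.mature_on_arm(prof.major_arm)
    if rec is None:
        return None
    mature_id, _arm, _start, _end, seq = rec
    return seq if mode == "by_sequence" else mature_id


def _minor_identity(prof: ArmProfile, ann: PrecursorAnnotation) -> tuple[str, str]:
    """(minor mature id, minor sequence) for distinguishability checks."""
    if prof.minor_arm is not None:
        rec = ann.mature_on_arm(prof.minor_arm)
        if rec is not None:
            return rec[0], rec[4]
    return mature_name(prof, ann, "minor"), ""


def find_families(
    annotations: list[PrecursorAnnotation] | dict[str, PrecursorAnnotation],
    profiles: list[ArmProfile],
    mode: str = "by_shared_mature_id",
) -> list[ParalogFamily]:
    """Group precursors whose major mature forms are identical.

    ``mode="by_shared_mature_id"`` groups on the annotated mature accession
    of the major arm (mirroring miRBase naming, where e.g. one miR-128-3p
    accession is produced by both hairpins); ``"by_sequence"`` groups on the
    mature sequence itself for annotation-free inputs.  Singletons are
    excluded.  Families whose members also share identical minor sequences
    are flagged indistinguishable.
    """
    if mode not in {"by_shared_mature_id", "by_sequence"}:
        raise ValueError(f"unknown family mode {mode!r}")
    if not isinstance(annotations, dict):
        annotations = {a.precursor_id: a for a in annotations}
    groups: dict[str, list[ArmProfile]] = {}
    for prof in profiles:
        ann = annotations.get(prof.precursor_id)
        if ann is None:
            continue
        key = _major_key(prof, ann, mode)
        if key is None:
            logger.warning("precursor %s lacks a major assignment; skipped", prof.precursor_id)
            continue
        groups.setdefault(key, []).append(prof)

    families = []
    for key in sorted(groups):
        profs = groups[key]
        if len(profs) < 2:
            continue
        minors = {
            p.precursor_id: _minor_identity(p, annotations[p.precursor_id]) for p in profs
        }
        minor_seqs = {seq for _id, seq in minors.values()}
        families.append(
            ParalogFamily(
                family_id=key,
                members=sorted(p.precursor_id for p in profs),
                minor_ids={pid: mid for pid, (mid, _seq) in minors.items()},
                indistinguishable=len(minor_seqs) == 1,
            )
        )
    return families


def find_cluster_pairs(
    annotations: list[PrecursorAnnotation] | dict[str, PrecursorAnnotation],
    max_gap: int = 5000,
) -> list[ClusterPair]:
    """Single-linkage clustering of genomic loci; emits within-cluster pairs.

    Two precursors chain into the same cluster when they lie on the same
    chromosome and strand with gap (next start − previous end) strictly
    below ``max_gap``.  Every unordered pair within a cluster is emitted,
    so a cluster of n precursors yields n·(n−1)/2 pairs.
    """
    if not isinstance(annotations, dict):
        annotations = {a.precursor_id: a for a in annotations}
    located = []
    for pid in sorted(annotations):
        ann = annotations[pid]
        if ann.genomic_locus is None:
            logger.warning("precursor %s has no genomic locus; excluded from clustering", pid)
            continue
        chrom, start, end, strand = ann.genomic_locus
        located.append((chrom, strand, start, end, pid))

    pairs: list[ClusterPair] = []
    frame = pd.DataFrame(located, columns=["chrom", "strand", "start", "end", "pid"])
    for (chrom, strand), sub in frame.groupby(["chrom", "strand"]):
        sub = sub.sort_values(["start", "end"])
        cluster: list[tuple[int, int, str]] = []
        clusters: list[list[tuple[int, int, str]]] = []
        for row in sub.itertuples():
            if cluster and row.start - cluster[-1][1] < max_gap:
                cluster.append((row.start, row.end, row.pid))
            else:
                if len(cluster) > 1:
                    clusters.append(cluster)
                cluster = [(row.start, row.end, row.pid)]
        if len(cluster) > 1:
            clusters.append(cluster)
        for cl in clusters:
            for (s1, e1, a), (s2, e2, b) in combinations(cl, 2):
                gap = max(s1, s2) - min(e1, e2) if max(s1, s2) > min(e1, e2) else 0
                pairs.append(ClusterPair(a, b, chrom, strand, gap))
    return pairs


def host_gene_pairs(
    annotations: list[PrecursorAnnotation] | dict[str, PrecursorAnnotation],
) -> list[tuple[str, str]]:
    """(precursor, host gene) pairs for the host-gene correlation screen.

    Host relationships are supplied by the input mapping (intronic/exonic
    residency asserted from genome annotation), not inferred here.
    """
    if not isinstance(annotations, dict):
        annotations = {a.precursor_id: a for a in annotations}
    return [
        (pid, annotations[pid].host_gene)
        for pid in sorted(annotations)
        if annotations[pid].host_gene
    ]
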
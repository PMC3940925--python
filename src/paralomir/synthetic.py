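"""Seed-reproducible synthetic miRBase-like data with planted ground truth.

The generator emulates the statistical structure the pipeline targets:
multi-tissue read-mapping tables where paralogous families share one major
mature sequence but carry member-specific minor sequences, with planted
tissue-restricted expression per member, genomic clusters, host genes, and
overdispersed (negative-binomial) count noise.  Defaults model a 15-tissue
mouse small-RNA compendium: major forms at ~2000 reads in their expressed
tissues, minor:major ratio 0.05 (within the broad range observed for real
arm-usage ratios), near-zero off-tissue background.  The default
dispersion (0.05) models single-library technical overdispersion — each
tissue is one pooled library, not a set of biological replicates.

Every downstream property is decidable from the returned truth record
alone; the same seed and config reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PrecursorAnnotation, ReadMappingTable
from .qpcr import CtTable

MOUSE_TISSUES = [
    "bone_marrow", "thymus", "spleen", "lymph_node", "brain",
    "heart", "lung", "liver", "kidney", "pancreas",
    "skin", "skeletal_muscle", "salivary_gland", "testis", "ovary",
]

HAIRPIN_LEN = 70
MATURE_LEN = 22
MAJOR_START_5P = 5  # within-hairpin 1-based starts of the planted mature forms
MINOR_START_3P = 45


class ConfigError(ValueError):
    """The simulation configuration is internally infeasible."""


@dataclass
class FamilySpec:
    """One paralogous family: members share the major mature sequence."""

    n_members: int = 2
    # contributor_tissues[m] = tissues in which member m is transcribed
    contributor_tissues: list[list[str]] = field(default_factory=list)
    major_level: float = 2000.0
    minor_ratio: float = 0.05
    major_arm: str = "5p"
    identical_minors: bool = False  # plant an indistinguishable family


@dataclass
class SingletonSpec:
    pattern: str = "none"  # "specific" | "selective" | "none"
    tissues: list[str] = field(default_factory=list)
    level: float = 2000.0
    minor_ratio: float = 0.05
    major_arm: str = "5p"


@dataclass
class SimulationConfig:
    n_tissues: int = 15
    tissues: list[str] = field(default_factory=lambda: list(MOUSE_TISSUES))
    families: list[FamilySpec] | None = None
    singletons: list[SingletonSpec] | None = None
    cluster_sizes: list[int] = field(default_factory=lambda: [2, 3])
    cluster_gap: int = 2000
    dispersion: float = 0.05  # negative-binomial: var = m + dispersion·m²
    # nominal total small-RNA reads per tissue library; the simulated
    # precursors are a small slice of it, so RPM normalization divides by
    # this, not by the slice's own sum (as with real miRBase report data)
    library_size: float = 1_000_000.0
    library_scale: dict[str, float] | None = None
    background_major: float = 2.0
    background_minor: float = 0.05
    isomir_fraction: float = 0.05  # stray reads one position 3' of the major start
    allow_arm_switch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.tissues = self.tissues[: self.n_tissues]
        if len(self.tissues) < self.n_tissues:
            self.tissues += [f"tissue_{i:02d}" for i in range(len(self.tissues), self.n_tissues)]
        if self.families is None:
            self.families = default_families(self.tissues)
        if self.singletons is None:
            self.singletons = default_singletons(self.tissues, self.cluster_sizes)
        for fam in self.families:
            if fam.minor_ratio > 1 and not self.allow_arm_switch:
                raise ConfigError(
                    "minor:major ratio above 1 plants an arm switch; "
                    "set allow_arm_switch=True if intended"
                )


def default_families(tissues: list[str], n_families: int = 8) -> list[FamilySpec]:
    """Two-member families; each member contributes in one distinct tissue."""
    fams = []
    for f in range(n_families):
        t_a = tissues[(2 * f) % len(tissues)]
        t_b = tissues[(2 * f + 1) % len(tissues)]
        fams.append(
            FamilySpec(
                n_members=2,
                contributor_tissues=[[t_a], [t_b]],
                major_arm="5p" if f % 2 == 0 else "3p",
            )
        )
    return fams


def default_singletons(
    tissues: list[str], cluster_sizes: list[int] | None = None
) -> list[SingletonSpec]:
    """8 tissue-specific, 6 two-tissue-selective and 6 unrestricted singletons.

    The leading singletons are placed into genomic clusters by the layout
    step; members of one cluster share their planted tissue, emulating
    co-transcription of clustered miRNAs from a common primary transcript.
    """
    cluster_of = {}
    offset = 0
    for ci, size in enumerate(cluster_sizes or []):
        for j in range(size):
            cluster_of[offset + j] = ci
        offset += size
    out = []
    for i in range(8):
        anchor = cluster_of[i] * 5 if i in cluster_of else 3 * i
        out.append(SingletonSpec("specific", [tissues[anchor % len(tissues)]]))
    for i in range(6):
        pair = [tissues[(2 * i + 1) % len(tissues)], tissues[(2 * i + 5) % len(tissues)]]
        out.append(SingletonSpec("selective", pair))
    for i in range(6):
        out.append(SingletonSpec("none", list(tissues), level=200.0))
    return out


@dataclass
class SimulationResult:
    reads: ReadMappingTable
    annotations: list[PrecursorAnnotation]
    truth: dict
    config: SimulationConfig


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Gamma–Poisson negative binomial with var = m + dispersion·m²."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam).astype(np.int64)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    """Change ``n_sites`` distinct positions to a different base."""
    seq = list(seq)
    for pos in rng.choice(len(seq), size=n_sites, replace=False):
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _build_hairpin(rng: np.random.Generator, seq_5p: str, seq_3p: str) -> str:
    """Random hairpin with the two mature sequences embedded at the planted starts."""
    hp = list(_random_seq(rng, HAIRPIN_LEN))
    hp[MAJOR_START_5P - 1 : MAJOR_START_5P - 1 + MATURE_LEN] = list(seq_5p)
    hp[MINOR_START_3P - 1 : MINOR_START_3P - 1 + MATURE_LEN] = list(seq_3p)
    return "".join(hp)


def _arm_starts(major_arm: str) -> tuple[int, int]:
    """(major start, minor start) given which arm carries the major form."""
    if major_arm == "5p":
        return MAJOR_START_5P, MINOR_START_3P
    return MINOR_START_3P, MAJOR_START_5P


def simulate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulationResult:
    """Generate a read table, annotations, loci and truth for one pseudo-genome."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tissues = config.tissues
    scale = {t: (config.library_scale or {}).get(t, 1.0) for t in tissues}

    annotations: list[PrecursorAnnotation] = []
    rows: list[tuple[str, int, int, str]] = []
    truth: dict = {
        "contributors": {},  # (family_id, tissue) -> precursor_id
        "families": [],
        "patterns": {},  # mature_id -> (call, tissues)
        "arms": {},  # precursor_id -> (major_start, major_arm, minor_start)
        "clusters": [],
        "host_genes": {},
        "expected_tissue_totals": {t: 0.0 for t in tissues},
        "library_totals": {t: config.library_size * scale[t] for t in tissues},
    }

    def emit(pid: str, start: int, mean_by_tissue: dict[str, float]) -> None:
        for t in tissues:
            mean = mean_by_tissue.get(t, 0.0) * scale[t]
            truth["expected_tissue_totals"][t] += mean
            count = int(_nb_counts(rng, mean, config.dispersion, 1)[0])
            if count > 0:
                rows.append((pid, start, count, t))

    def plant_precursor(
        pid: str,
        major_id: str,
        minor_id: str,
        major_seq: str,
        minor_seq: str,
        major_arm: str,
        expressed: list[str],
        level: float,
        minor_ratio: float,
    ) -> PrecursorAnnotation:
        major_start, minor_start = _arm_starts(major_arm)
        seq_5p = major_seq if major_arm == "5p" else minor_seq
        seq_3p = minor_seq if major_arm == "5p" else major_seq
        hairpin = _build_hairpin(rng, seq_5p, seq_3p)
        minor_arm = "3p" if major_arm == "5p" else "5p"
        ann = PrecursorAnnotation(
            precursor_id=pid,
            hairpin_sequence=hairpin,
            mature_records=[
                (major_id, major_arm, major_start, major_start + MATURE_LEN - 1, major_seq),
                (minor_id, minor_arm, minor_start, minor_start + MATURE_LEN - 1, minor_seq),
            ],
        )
        major_means = {
            t: (level if t in expressed else config.background_major) for t in tissues
        }
        minor_means = {
            t: (level * minor_ratio if t in expressed else config.background_minor)
            for t in tissues
        }
        emit(pid, major_start, major_means)
        if config.isomir_fraction > 0:
            emit(pid, major_start + 1, {t: m * config.isomir_fraction for t, m in major_means.items()})
        emit(pid, minor_start, minor_means)
        truth["arms"][pid] = (major_start, major_arm, minor_start)
        return ann

    # paralogous families ---------------------------------------------------
    for f, fam in enumerate(config.families):
        fam_name = f"sim-mir-{100 + f}"
        major_id = f"sim-miR-{100 + f}-{fam.major_arm}"
        major_seq = _random_seq(rng, MATURE_LEN)
        base_minor = _random_seq(rng, MATURE_LEN)
        members = []
        minor_ids = {}
        for m in range(fam.n_members):
            pid = f"{fam_name}-{m + 1}"
            minor_arm = "3p" if fam.major_arm == "5p" else "5p"
            minor_id = f"sim-miR-{100 + f}-{m + 1}-{minor_arm}"
            minor_seq = base_minor if fam.identical_minors else _mutate(rng, base_minor, m + 1)
            expressed = fam.contributor_tissues[m] if m < len(fam.contributor_tissues) else []
            ann = plant_precursor(
                pid, major_id, minor_id, major_seq, minor_seq, fam.major_arm,
                expressed, fam.major_level, fam.minor_ratio,
            )
            annotations.append(ann)
            members.append(pid)
            minor_ids[pid] = minor_id
            truth["host_genes"][pid] = f"HOST_{pid}"
            for t in expressed:
                truth["contributors"][(major_id, t)] = pid
        truth["families"].append(
            {
                "family_id": major_id,
                "members": members,
                "minor_ids": minor_ids,
                "indistinguishable": fam.identical_minors,
                "member_tissues": {
                    members[m]: list(fam.contributor_tissues[m])
                    if m < len(fam.contributor_tissues) else []
                    for m in range(fam.n_members)
                },
            }
        )
        all_t = sorted({t for ts in fam.contributor_tissues for t in ts})
        truth["patterns"][major_id] = (
            ("specific", all_t) if len(all_t) == 1 else ("selective", all_t)
        )

    # singletons ------------------------------------------------------------
    for s, single in enumerate(config.singletons):
        pid = f"sim-mir-{300 + s}"
        major_id = f"sim-miR-{300 + s}-{single.major_arm}"
        minor_arm = "3p" if single.major_arm == "5p" else "5p"
        minor_id = f"sim-miR-{300 + s}-{minor_arm}"
        expressed = single.tissues if single.pattern != "none" else list(tissues)
        ann = plant_precursor(
            pid, major_id, minor_id, _random_seq(rng, MATURE_LEN), _random_seq(rng, MATURE_LEN),
            single.major_arm, expressed, single.level, single.minor_ratio,
        )
        annotations.append(ann)
        truth["patterns"][major_id] = (
            (single.pattern, list(single.tissues)) if single.pattern != "none" else ("none", [])
        )

    # genomic layout: planted clusters use the leading singletons -----------
    isolated_gap = 50_000
    pids = [a.precursor_id for a in annotations]
    cluster_members: list[list[str]] = []
    cursor = 0
    singles = [a.precursor_id for a in annotations if a.precursor_id.startswith("sim-mir-3")]
    for size in config.cluster_sizes:
        cluster_members.append(singles[cursor : cursor + size])
        cursor += size
    clustered = {pid for cl in cluster_members for pid in cl}
    chrom_i = 1
    lookup = {a.precursor_id: a for a in annotations}
    for cl in cluster_members:
        pos = 10_000
        for pid in cl:
            lookup[pid].genomic_locus = (f"chr{chrom_i}", pos, pos + HAIRPIN_LEN - 1, "+")
            pos += HAIRPIN_LEN - 1 + config.cluster_gap
        chrom_i += 1
    for pid in pids:
        if pid not in clustered:
            lookup[pid].genomic_locus = (f"chr{chrom_i}", 10_000, 10_000 + HAIRPIN_LEN - 1, "+")
            chrom_i += 1
    truth["clusters"] = cluster_members
    for pid, host in truth["host_genes"].items():
        lookup[pid].host_gene = host

    frame = pd.DataFrame(rows, columns=["precursor_id", "start", "count", "tissue"])
    frame = frame.groupby(["precursor_id", "start", "tissue"], as_index=False, sort=True)[
        "count"
    ].sum()[["precursor_id", "start", "count", "tissue"]]
    reads = ReadMappingTable(records=frame, tissues=list(tissues))
    return SimulationResult(reads=reads, annotations=annotations, truth=truth, config=config)


def simulate_host_expression(
    sim: SimulationResult, noise_sd: float = 0.1, seed: int | None = None
) -> pd.DataFrame:
    """Host-gene expression matrix co-regulated with each member's activity.

    Each planted host gene tracks its miRNA member's per-tissue transcription
    (the member's planted mean profile) with multiplicative log-normal noise;
    used by the host-gene correlation screen.
    """
    rng = np.random.default_rng(sim.config.seed + 1 if seed is None else seed)
    tissues = sim.config.tissues
    rows = {}
    for fam_rec in sim.truth["families"]:
        member_tissues = fam_rec["member_tissues"]
        for pid, host in sorted(sim.truth["host_genes"].items()):
            if pid not in member_tissues:
                continue
            profile = np.array(
                [1000.0 if t in member_tissues[pid] else 5.0 for t in tissues]
            )
            noisy = profile * rng.lognormal(0.0, noise_sd, size=len(tissues))
            rows[host] = noisy
    return pd.DataFrame(rows, index=tissues).T


def simulate_ct(
    preferred: list[str],
    tissues: list[str] | None = None,
    fold: float = 16.0,
    n_replicates: int = 3,
    sigma: float = 0.25,
    reference: str = "U6",
    target: str = "target",
    baseline_ct: float = 25.0,
    reference_ct: float = 15.0,
    seed: int = 0,
) -> CtTable:
    """Ct table with the target preferentially expressed in ``preferred`` tissues.

    Preferred tissues get a target Ct lower by log2(fold) cycles; Gaussian
    replicate noise of ``sigma`` cycles applies to every well; the reference
    gene is flat across tissues.
    """
    rng = np.random.default_rng(seed)
    tissues = tissues or list(MOUSE_TISSUES)
    rows = []
    shift = np.log2(fold)
    for t in tissues:
        mu = baseline_ct - (shift if t in preferred else 0.0)
        for rep in range(1, n_replicates + 1):
            rows.append((t, rep, target, mu + rng.normal(0.0, sigma)))
            rows.append((t, rep, reference, reference_ct + rng.normal(0.0, sigma)))
    return CtTable(
        pd.DataFrame(rows, columns=["tissue", "replicate", "target", "ct"]),
        reference=reference,
    )
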
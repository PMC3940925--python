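"""Input/output layer: read-mapping tables, hairpin/mature annotations, GCT and TSV reports.

The canonical read-mapping input is a long-form TSV with one row per
(precursor, start position, tissue) combination and a read count.  miRBase's
web report is not machine-specified, so arbitrary column namings are
supported through a ``column_map``; coordinates are 1-based inclusive within
the hairpin, matching miRBase convention.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence


import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("paralomir")

READ_COLUMNS = ("precursor_id", "start", "count", "tissue")


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


class ValidationError(ValueError):
    """Row-level content violates an invariant (e.g. negative count)."""


@dataclass
class ReadMappingTable:
    """Long-form read-mapping records underlying all expression quantities.

    ``records`` holds one row per unique (precursor_id, start, tissue) with
    summed counts; ``tissues`` preserves first-appearance order from the
    input file and is the column order of every matrix derived from it.
    """

    records: pd.DataFrame
    tissues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tissues and len(self.records):
            self.tissues = list(pd.unique(self.records["tissue"]))

    def __len__(self) -> int:
        return len(self.records)

    def total_reads(self) -> int:
        return int(self.records["count"].sum())

    def tissue_totals(self) -> pd.Series:
        """Total mapped reads per tissue (the per-library normalizer)."""
        totals = self.records.groupby("tissue")["count"].sum()
        return totals.reindex(self.tissues, fill_value=0)


@dataclass
class PrecursorAnnotation:
    """Hairpin sequence plus mature-arm and genomic-locus annotation."""

    precursor_id: str
    hairpin_sequence: str
    mature_records: list[tuple[str, str, int, int, str]]  # (id, arm, start, end, seq)
    genomic_locus: tuple[str, int, int, str] | None = None  # (chrom, start, end, strand)
    host_gene: str | None = None

    @property
    def hairpin_length(self) -> int:
        return len(self.hairpin_sequence)

    def arm_of_position(self, pos: int) -> str:
        """5p/3p call for a within-hairpin start: the hairpin midpoint splits arms."""
        return "5p" if pos <= self.hairpin_length / 2 else "3p"

    def mature_on_arm(self, arm: str) -> tuple[str, str, int, int, str] | None:
        for rec in self.mature_records:
            if rec[1] == arm:
                return rec
        return None


def _canonical(label: str) -> str:
    return str(label).strip()


def load_read_mappings(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> ReadMappingTable:
    """Load and validate a long-form read-mapping TSV.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Optional mapping from canonical names (``precursor_id``, ``start``,
        ``count``, ``tissue``) to the column names used in the file, for
        foreign report dialects.

    Duplicate (precursor, start, tissue) rows are summed.  Negative counts
    raise :class:`ValidationError` naming the offending line.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype={"tissue": str})
    rename = {column_map.get(c, c): c for c in READ_COLUMNS}
    missing = [src for src, dst in rename.items() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=rename)[list(READ_COLUMNS)]
    if len(df):
        bad = df.index[df["count"] < 0]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValidationError(f"negative count at line {bad[0] + 2} of {path}")
        df["tissue"] = df["tissue"].map(_canonical)
        df["precursor_id"] = df["precursor_id"].map(_canonical)
    tissues = list(pd.unique(df["tissue"])) if len(df) else []
    df = (
        df.groupby(["precursor_id", "start", "tissue"], as_index=False, sort=True)["count"]
        .sum()[list(READ_COLUMNS)]
    )
    table = ReadMappingTable(records=df, tissues=tissues)
    logger.info("loaded %d read records over %d tissues from %s", len(df), len(tissues), path)
    return table


def _parse_gff3_features(path: str | Path) -> list[dict]:
    """Parse GFF3 features through gffutils into plain dicts."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        feats.append(
            {
                "seqid": f.seqid,
                "type": f.featuretype,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "attributes": {k: v[0] for k, v in f.attributes.items()},
            }
        )
    return feats


def load_annotations(
    hairpin_fasta: str | Path,
    mature_gff: str | Path,
    genomic_gff: str | Path | None = None,
    host_map: str | Path | None = None,
) -> list[PrecursorAnnotation]:
    """Assemble per-precursor annotations from FASTA + GFF3 (+ host-gene TSV).

    ``mature_gff`` features use the hairpin ID as seqid and within-hairpin
    1-based inclusive coordinates; the ``arm`` attribute is honoured when
    present, otherwise the arm is derived from the mature midpoint relative
    to the hairpin midpoint.  ``genomic_gff`` features carry the genomic
    locus (attribute ``ID`` = precursor).  Orphan mature features and
    out-of-hairpin coordinates raise.
    """
    hairpins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(hairpin_fasta), "fasta")}
    annotations = {
        pid: PrecursorAnnotation(pid, seq, mature_records=[]) for pid, seq in hairpins.items()
    }

    for f in _parse_gff3_features(mature_gff):
        pid = f["seqid"]
        if pid not in annotations:
            raise ValidationError(f"mature feature references unknown hairpin {pid!r}")
        ann = annotations[pid]
        if not (1 <= f["start"] <= f["end"] <= ann.hairpin_length):
            raise ValidationError(
                f"mature coordinates {f['start']}-{f['end']} outside hairpin {pid!r} "
                f"(length {ann.hairpin_length})"
            )
        mid = (f["start"] + f["end"]) / 2
        arm = f["attributes"].get("arm") or ("5p" if mid <= ann.hairpin_length / 2 else "3p")
        mature_id = f["attributes"].get("ID", f"{pid}-{arm}")
        seq = ann.hairpin_sequence[f["start"] - 1 : f["end"]]
        ann.mature_records.append((mature_id, arm, f["start"], f["end"], seq))

    if genomic_gff is not None:
        for f in _parse_gff3_features(genomic_gff):
            pid = f["attributes"].get("ID")
            if pid in annotations:
                annotations[pid].genomic_locus = (f["seqid"], f["start"], f["end"], f["strand"])

    if host_map is not None:
        hosts = pd.read_csv(host_map, sep="\t")
        for _, row in hosts.iterrows():
            pid = _canonical(row.iloc[0])
            if pid in annotations:
                annotations[pid].host_gene = _canonical(row.iloc[1])

    return list(annotations.values())


def write_annotations(
    annotations: Sequence[PrecursorAnnotation],
    hairpin_fasta: str | Path,
    mature_gff: str | Path,
    genomic_gff: str | Path | None = None,
    host_map: str | Path | None = None,
) -> None:
    """Write annotations back to the same FASTA/GFF3/TSV dialects."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(a.hairpin_sequence), id=a.precursor_id, description="") for a in annotations],
        str(hairpin_fasta),
        "fasta",
    )
    with open(mature_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            for mid, arm, start, end, _seq in a.mature_records:
                fh.write(
                    f"{a.precursor_id}\t.\tmiRNA\t{start}\t{end}\t.\t+\t.\t"
                    f"ID={mid};arm={arm}\n"
                )
    if genomic_gff is not None:
        with open(genomic_gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for a in annotations:
                if a.genomic_locus is None:
                    continue
                chrom, start, end, strand = a.genomic_locus
                fh.write(
                    f"{chrom}\t.\tmiRNA_primary_transcript\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={a.precursor_id}\n"
                )
    if host_map is not None:
        rows = [(a.precursor_id, a.host_gene) for a in annotations if a.host_gene]
        pd.DataFrame(rows, columns=["precursor_id", "host_gene"]).to_csv(
            host_map, sep="\t", index=False
        )


def write_reads(table: ReadMappingTable, path: str | Path) -> None:
    """Write a ReadMappingTable back to the canonical long-form TSV."""
    table.records.to_csv(path, sep="\t", index=False)


def write_gct(matrix, path: str | Path) -> None:
    """Serialize an expression matrix as GCT 1.2 (GenePattern heat-map input).

    Values are written with 6 significant digits; zero rows are preserved.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    if df.empty:
        raise ValueError("refusing to write an empty matrix as GCT")
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for name, row in df.iterrows():
            vals = "\t".join(f"{v:.6g}" for v in row.to_numpy())
            fh.write(f"{name}\tna\t{vals}\n")


def parse_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 file back into an entity × tissue DataFrame."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValidationError(f"unsupported GCT version line {version!r}")
        n_rows, n_cols = map(int, fh.readline().split("\t"))
        body = pd.read_csv(_io.StringIO(fh.read()), sep="\t")
    df = body.set_index("NAME").drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        raise ValidationError(
            f"GCT dimension line ({n_rows}, {n_cols}) disagrees with body {df.shape}"
        )
    return df


def write_report(report: pd.DataFrame, path: str | Path, sort_keys: Sequence[str] | None = None) -> None:
    """Write a tabular result as TSV with a deterministic row order.

    Rows are sorted on ``sort_keys`` (default: every column, left to right),
    so re-running on identical inputs is byte-identical.
    """
    df = report.copy()
    if len(df):
        keys = list(sort_keys) if sort_keys else list(df.columns)
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
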
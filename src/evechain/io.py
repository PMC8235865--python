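"""Readers and writers for the tabular formats the pipeline consumes.

All genomic inputs use 1-based inclusive coordinates (the BLAST tabular
convention); BED output is 0-based half-open. Strand is encoded implicitly
on the host side by coordinate order — ``start > end`` means minus — and is
normalised to an explicit flag plus min/max coordinates at parse time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "AlignmentHit",
    "EveRecord",
    "DepthTable",
    "VariantRecord",
    "SmallRnaAlignment",
    "read_blast_tab",
    "read_eve_table",
    "write_bed",
    "read_depth_table",
    "read_variants",
    "read_small_rna",
    "write_eve_table",
    "write_blast_tab",
    "write_depth_table",
    "write_variants",
    "write_small_rna",
    "write_fasta",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a viral query against a host subject.

    Mirrors the 12-column BLAST tabular (outfmt 6) dialect. Host strand is
    carried by the coordinate order of ``s_start``/``s_end``.
    """

    query_acc: str
    subject_id: str
    identity_pct: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise ValueError(f"identity_pct out of [0,100]: {self.identity_pct}")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def minus(self) -> bool:
        """True when the hit lies on the host minus strand."""
        return self.s_start > self.s_end

    @property
    def s_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)


@dataclass(frozen=True)
class EveRecord:
    """A curated endogenous viral element fragment.

    ``h_start``/``h_end`` keep the printed orientation-encoding order;
    ``length`` follows the difference convention ``|h_end - h_start|``
    (one less than the inclusive span).
    """

    identifier: str
    virus: str
    v_start: int
    v_end: int
    chrom: str
    h_start: int
    h_end: int
    length: int

    def __post_init__(self) -> None:
        if self.v_end < self.v_start:
            raise ValueError(f"{self.identifier}: v_end < v_start")
        if self.length < 0:
            raise ValueError(f"{self.identifier}: negative length")

    @property
    def strand(self) -> str:
        return "-" if self.h_start > self.h_end else "+"

    @property
    def h_lo(self) -> int:
        return min(self.h_start, self.h_end)

    @property
    def h_hi(self) -> int:
        return max(self.h_start, self.h_end)

    @property
    def event_label(self) -> str:
        """Event suffix of an ``AE<k>.<event>`` identifier, if present."""
        _, _, suffix = self.identifier.partition(".")
        return suffix


@dataclass
class DepthTable:
    """Per-base read depth for one sample, sparse over positions.

    Positions absent from a contig's array are depth 0; positions are
    strictly increasing per contig.
    """

    sample_id: str
    contigs: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_contig(self, contig: str, positions: np.ndarray, depths: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        depths = np.asarray(depths, dtype=np.int64)
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ParseError(f"{self.sample_id}/{contig}: positions not strictly increasing")
        if np.any(depths < 0):
            raise ParseError(f"{self.sample_id}/{contig}: negative depth")
        self.contigs[contig] = (positions, depths)

    def breadth(self, contig: str, start: int, end: int, min_depth: int = 1) -> float:
        """Fraction of bases in [start, end] (1-based inclusive) at >= min_depth."""
        if end < start:
            raise ValueError("inverted interval")
        span = end - start + 1
        if contig not in self.contigs:
            return 0.0
        pos, dep = self.contigs[contig]
        lo, hi = np.searchsorted(pos, [start, end + 1])
        covered = int(np.count_nonzero(dep[lo:hi] >= min_depth))
        return covered / span


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    type: str  # "SNP" or "InDel"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        expected = "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "InDel"
        if self.type != expected:
            raise ValueError(f"type {self.type} inconsistent with alleles {self.ref}>{self.alt}")


@dataclass(frozen=True)
class SmallRnaAlignment:
    chrom: str
    pos: int  # 1-based 5'-most coordinate
    strand: str
    read_length: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(f"unknown strand symbol: {self.strand!r}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Read a 12-column BLAST tabular (outfmt 6) file.

    Rows violating the hit invariants are rejected with their row number.
    An empty file yields an empty list.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: row {i}: expected >= 12 tab-separated fields, got {len(fields)}")
            try:
                hits.append(
                    AlignmentHit(
                        query_acc=fields[0],
                        subject_id=fields[1],
                        identity_pct=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    return hits


_EVE_REQUIRED = ["identifier", "virus", "virus_start", "virus_end", "chromosome", "host_start", "host_end"]


def read_eve_table(path: str | Path) -> list[EveRecord]:
    """Read a curated EVE table (TSV with a header).

    Required columns: identifier, virus, virus_start, virus_end, chromosome,
    host_start, host_end. A ``length`` column, if present, is kept verbatim
    (with a warning when inconsistent with ``|host_end - host_start|``);
    otherwise length is derived. Gap columns are ignored — gaps are
    recomputed downstream from coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in _EVE_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        h_start, h_end = int(row["host_start"]), int(row["host_end"])
        derived = abs(h_end - h_start)
        if "length" in df.columns and not pd.isna(row["length"]):
            length = int(row["length"])
            if length != derived:
                warnings.warn(
                    f"{row['identifier']}: printed length {length} != |host_end - host_start| = {derived}; "
                    "keeping printed value",
                    stacklevel=2,
                )
        else:
            length = derived
        records.append(
            EveRecord(
                identifier=str(row["identifier"]),
                virus=str(row["virus"]),
                v_start=int(row["virus_start"]),
                v_end=int(row["virus_end"]),
                chrom=str(row["chromosome"]),
                h_start=h_start,
                h_end=h_end,
                length=length,
            )
        )
    return records


def write_eve_table(records: Iterable[EveRecord], path: str | Path) -> None:
    """Write EVE records as TSV readable by :func:`read_eve_table`."""
    rows = [
        {
            "identifier": r.identifier,
            "virus": r.virus,
            "virus_start": r.v_start,
            "virus_end": r.v_end,
            "chromosome": r.chrom,
            "host_start": r.h_start,
            "host_end": r.h_end,
            "length": r.length,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["identifier", "virus", "virus_start", "virus_end",
                                "chromosome", "host_start", "host_end", "length"]).to_csv(
        path, sep="\t", index=False)


def write_bed(records: Iterable[EveRecord], path: str | Path) -> None:
    """Write records as BED6 (0-based half-open), name = identifier."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.h_lo - 1}\t{r.h_hi}\t{r.identifier}\t.\t{r.strand}\n")


def read_depth_table(path: str | Path, sample_id: str | None = None) -> DepthTable:
    """Read a 3-column depth TSV: contig, position (1-based), depth.

    Positions must be strictly increasing within each contig; omitted
    positions are depth 0.
    """
    sample = sample_id if sample_id is not None else Path(path).stem
    table = DepthTable(sample_id=sample)
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "pos", "depth"],
                     dtype={"contig": str, "pos": np.int64, "depth": np.int64})
    for contig, sub in df.groupby("contig", sort=False):
        table.add_contig(str(contig), sub["pos"].to_numpy(), sub["depth"].to_numpy())
    return table


def read_variants(path: str | Path, sample_id: str | None = None) -> list[VariantRecord]:
    """Read a VCF, keeping chrom/pos/ref/alt only.

    Multi-allelic records yield one VariantRecord per alternate allele.
    """
    sample = sample_id if sample_id is not None else Path(path).stem
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                vtype = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "InDel"
                out.append(VariantRecord(chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                                         alt=alt, type=vtype, sample_id=sample))
    return out


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect read by :func:`read_blast_tab`."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_acc, h.subject_id, f"{h.identity_pct:.2f}", h.aln_len,
                h.mismatches, h.gap_opens, h.q_start, h.q_end,
                h.s_start, h.s_end, f"{h.evalue:.3g}", f"{h.bitscore:.1f}")) + "\n")


def write_depth_table(table: DepthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, (pos, dep) in table.contigs.items():
            for p, d in zip(pos.tolist(), dep.tolist()):
                fh.write(f"{contig}\t{p}\t{d}\n")


def write_variants(variants: Iterable[VariantRecord], path: str | Path,
                   contigs: Mapping[str, int] | None = None) -> None:
    """Write variants as a minimal VCF readable by :func:`read_variants`."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def write_small_rna(alignments: Iterable[SmallRnaAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.pos}\t{a.strand}\t{a.read_length}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()],
                str(path), "fasta")


def read_small_rna(path: str | Path) -> list[SmallRnaAlignment]:
    """Read small-RNA alignment TSV: contig, pos (1-based 5'-most), strand, read length."""
    out: list[SmallRnaAlignment] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: row {i}: expected 4 fields")
            try:
                out.append(SmallRnaAlignment(chrom=fields[0], pos=int(fields[1]),
                                             strand=fields[2], read_length=int(fields[3])))
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    return out
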
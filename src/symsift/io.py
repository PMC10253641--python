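"""Readers and writers for the pipeline's on-disk formats.

Formats handled here: FASTA contigs (via Biopython), GFF3 CDS annotations
with a ``taxon`` attribute, the placement TSV (read intervals with mate
links, one table per library), BLAST tabular (outfmt-6) alignment hits,
and the truth table emitted by the simulator.  All in-memory coordinates
are 0-based half-open; GFF3 is converted to/from its 1-based inclusive
convention at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BLAST6_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "bitscore",
]

GFF_COLUMNS = ["contig", "start", "end", "strand", "cds_id", "taxon"]

PLACEMENT_TSV_COLUMNS = ["read_id", "mate_id", "library", "contig", "start", "end"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 (CDS features with ID and taxon attributes)
# ---------------------------------------------------------------------------

def write_gff3(cds: pd.DataFrame, path: str | Path) -> None:
    """Write a CDS table (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in cds.itertuples(index=False):
            attrs = f"ID={row.cds_id};taxon={row.taxon}"
            fh.write(
                f"{row.contig}\tsymsift\tCDS\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t0\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read CDS features from GFF3 into a 0-based half-open table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 row at line {lineno}")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "CDS":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            rows.append(
                {
                    "contig": contig,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "cds_id": attr_map.get("ID", f"cds{lineno}"),
                    "taxon": attr_map.get("taxon", "unannotated"),
                }
            )
    return pd.DataFrame(rows, columns=GFF_COLUMNS)


# ---------------------------------------------------------------------------
# BLAST outfmt-6
# ---------------------------------------------------------------------------

def read_blast6(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST outfmt-6 TSV.

    Query coordinates are normalized to 0-based half-open.  Malformed rows
    raise with the offending line number; an empty file yields an empty
    table.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: expected 12 tab-separated columns at line {lineno}, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(
                    {
                        "query_id": parts[0],
                        "subject_id": parts[1],
                        "percent_identity": float(parts[2]),
                        "length": int(parts[3]),
                        "mismatches": int(parts[4]),
                        "gap_opens": int(parts[5]),
                        "query_start": int(parts[6]) - 1,
                        "query_end": int(parts[7]),
                        "subject_start": int(parts[8]) - 1,
                        "subject_end": int(parts[9]),
                        "evalue": float(parts[10]),
                        "bitscore": float(parts[11]),
                    }
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed hit row at line {lineno}: {exc}")
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def write_blast6(hits: pd.DataFrame, path: str | Path) -> None:
    out = hits.copy()
    out["query_start"] = out["query_start"] + 1
    out["subject_start"] = out["subject_start"] + 1
    out[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Placement tables
# ---------------------------------------------------------------------------

@dataclass
class PlacementTable:
    """Read placements for one library, as flat arrays.

    Each row is a single placed read interval on a contig (0-based
    half-open).  ``mate`` holds the row index of a paired mate, or -1 for
    unpaired (long) reads.  Contigs are stored as integer codes into
    ``contig_ids`` to keep multi-million-row tables compact.
    """

    library: str
    contig_ids: list[str]
    contig: np.ndarray  # int32 codes
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    mate: np.ndarray  # int64 row index, -1 if unpaired
    _order: np.ndarray | None = field(default=None, repr=False)
    _bounds: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return int(self.contig.shape[0])

    @property
    def is_paired(self) -> np.ndarray:
        return self.mate >= 0

    def _index(self) -> tuple[np.ndarray, np.ndarray]:
        if self._order is None:
            self._order = np.argsort(self.contig, kind="stable")
            self._bounds = np.searchsorted(
                self.contig[self._order], np.arange(len(self.contig_ids) + 1)
            )
        return self._order, self._bounds

    def rows_for_contig(self, contig_id: str) -> np.ndarray:
        """Row indices of all placements on a contig."""
        try:
            code = self.contig_ids.index(contig_id)
        except ValueError:
            return np.empty(0, dtype=np.int64)
        order, bounds = self._index()
        return order[bounds[code] : bounds[code + 1]]

    def intervals_for_contig(self, contig_id: str) -> tuple[np.ndarray, np.ndarray]:
        rows = self.rows_for_contig(contig_id)
        return self.start[rows], self.end[rows]

    def pairs_for_contig(
        self, contig_id: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(left_start, left_end, right_start, right_end) for intra-contig pairs."""
        rows = self.rows_for_contig(contig_id)
        rows = rows[self.mate[rows] >= 0]
        if rows.size == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z, z
        mates = self.mate[rows]
        keep = (rows < mates) & (self.contig[mates] == self.contig[rows])
        a, b = rows[keep], mates[keep]
        ls = np.minimum(self.start[a], self.start[b])
        le = np.where(self.start[a] <= self.start[b], self.end[a], self.end[b])
        rs = np.maximum(self.start[a], self.start[b])
        re = np.where(self.start[a] <= self.start[b], self.end[b], self.end[a])
        return ls, le, rs, re

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        read_ids = np.array([f"{self.library}_r{i:08d}" for i in range(n)])
        mate_ids = np.where(self.mate >= 0, read_ids[np.maximum(self.mate, 0)], ".")
        return pd.DataFrame(
            {
                "read_id": read_ids,
                "mate_id": mate_ids,
                "library": self.library,
                "contig": np.asarray(self.contig_ids, dtype=object)[self.contig],
                "start": self.start,
                "end": self.end,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, library: str | None = None) -> "PlacementTable":
        if library is None:
            libs = df["library"].unique()
            if len(libs) != 1:
                raise ValueError(
                    "placement frame holds multiple libraries; pass `library`"
                )
            library = str(libs[0])
        df = df[df["library"] == library].reset_index(drop=True)
        contig_ids = list(dict.fromkeys(df["contig"]))
        code_of = {c: i for i, c in enumerate(contig_ids)}
        contig = df["contig"].map(code_of).to_numpy(dtype=np.int32)
        row_of = {rid: i for i, rid in enumerate(df["read_id"])}
        mate = np.full(len(df), -1, dtype=np.int64)
        for i, mid in enumerate(df["mate_id"]):
            if isinstance(mid, str) and mid != ".":
                mate[i] = row_of.get(mid, -1)
        return cls(
            library=library,
            contig_ids=contig_ids,
            contig=contig,
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
            mate=mate,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, library: str | None = None) -> "PlacementTable":
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "mate_id": str})
        return cls.from_frame(df, library=library)


def read_placement_libraries(path: str | Path) -> dict[str, PlacementTable]:
    """Read a placement TSV that may mix libraries; one table per library."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "mate_id": str})
    return {
        str(lib): PlacementTable.from_frame(df, library=str(lib))
        for lib in df["library"].unique()
    }
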
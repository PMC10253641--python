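"""Configuration and ground-truth record types for the synthetic metagenome.

The defaults encode the structure the parsing pipeline exploits in a real
holobiont assembly: a host genome at modest, even read depth (~16x) with
slightly higher GC, and an intracellular symbiont at much higher depth
(~128x short-read, ~189x long-read) with lower GC and distinct codon usage.
Chimeric contigs (a mis-joined host+symbiont fragment) and host contigs
carrying symbiont-derived HGT inserts are planted with recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

TAXON_SYMBIONT = "alphaproteobacteria"
TAXON_HOST = "eukaryota"

CLASS_HOST = "host"
CLASS_SYMBIONT = "symbiont"
CLASS_CHIMERA = "chimera"
CLASS_HGT = "hgt_host"

SHORT_LIBRARIES = ("short_a", "short_b", "short_c")
LONG_LIBRARY = "long"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic holobiont metagenome.

    GC and depth defaults mirror the contrast measured in the motivating
    system: host GC 37.8% vs symbiont GC 35.3%; host short-read depth 16x
    (observed range 12-20x) vs symbiont 128x short-read / 189x long-read.
    """

    seed: int = 0
    host_gc: float = 0.378
    symbiont_gc: float = 0.353
    host_cov_short: float = 16.0
    symbiont_cov_short: float = 128.0
    host_cov_long: float = 16.0
    symbiont_cov_long: float = 189.0
    n_host_contigs: int = 500
    n_symbiont_contigs: int = 150
    n_chimeras: int = 15
    n_hgt_contigs: int = 20
    contig_len_range: tuple[int, int] = (5_000, 60_000)
    insert_cds_range: tuple[int, int] = (1, 19)
    read_len: int = 150
    insert_size: tuple[float, float] = (900.0, 100.0)  # mean, sd of pair outer span
    long_read_len: float = 5_000.0
    host_genome_len: int = 4_000_000
    symbiont_genome_len: int = 1_600_000
    host_coding_density: float = 0.30
    symbiont_coding_density: float = 0.70
    # extra symbiont depth stacked on HGT insert intervals (off: inserts are
    # ordinary single-copy chromosome regions of the host)
    hgt_insert_extra_cov: bool = False

    def __post_init__(self) -> None:
        for name in ("host_gc", "symbiont_gc"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        for name in (
            "host_cov_short",
            "symbiont_cov_short",
            "host_cov_long",
            "symbiont_cov_long",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_host_contigs", "n_symbiont_contigs", "n_chimeras", "n_hgt_contigs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.contig_len_range
        if lo > hi or lo < 2 * self.read_len:
            raise ValueError(
                "contig_len_range must be (lo, hi) with lo <= hi and lo >= 2 * read_len"
            )
        lo, hi = self.insert_cds_range
        if lo < 1 or lo > hi:
            raise ValueError("insert_cds_range must be (lo, hi) with 1 <= lo <= hi")
        for name in ("host_coding_density", "symbiont_coding_density"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1)")


@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic contig."""

    contig_id: str
    true_class: str  # host | symbiont | chimera | hgt_host
    junction_pos: Optional[int] = None  # chimera only, 0-based offset
    insert_intervals: list[tuple[int, int]] = field(default_factory=list)  # hgt only
    insert_cds_count: int = 0

    def __post_init__(self) -> None:
        if (self.true_class == CLASS_CHIMERA) != (self.junction_pos is not None):
            raise ValueError("junction_pos present iff true_class == chimera")
        if (self.true_class == CLASS_HGT) != bool(self.insert_intervals):
            raise ValueError("insert_intervals present iff true_class == hgt_host")
        ivs = sorted(self.insert_intervals)
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if c < b:
                raise ValueError("insert intervals must be non-overlapping")


def truth_to_frame(records: list[TruthRecord]) -> pd.DataFrame:
    """Tabulate truth records (intervals serialized as 'a-b;c-d')."""
    rows = []
    for r in records:
        rows.append(
            {
                "contig_id": r.contig_id,
                "true_class": r.true_class,
                "junction_pos": -1 if r.junction_pos is None else r.junction_pos,
                "insert_intervals": ";".join(f"{a}-{b}" for a, b in r.insert_intervals),
                "insert_cds_count": r.insert_cds_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "true_class",
            "junction_pos",
            "insert_intervals",
            "insert_cds_count",
        ],
    )


def truth_from_frame(df: pd.DataFrame) -> list[TruthRecord]:
    records = []
    for row in df.itertuples(index=False):
        intervals = []
        if isinstance(row.insert_intervals, str) and row.insert_intervals:
            for part in row.insert_intervals.split(";"):
                a, b = part.split("-")
                intervals.append((int(a), int(b)))
        records.append(
            TruthRecord(
                contig_id=row.contig_id,
                true_class=row.true_class,
                junction_pos=None if row.junction_pos < 0 else int(row.junction_pos),
                insert_intervals=intervals,
                insert_cds_count=int(row.insert_cds_count),
            )
        )
    return records
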
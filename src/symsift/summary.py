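"""Assembly statistics, three-strain pangenome partition, feature census.

N50 is the length of the contig at which the descending cumulative length
first reaches half the assembly (inclusive at an exact half), and L50 the
number of contigs needed to do so.  The pangenome partition places each
ortholog cluster into one of the seven regions of a three-set Venn
diagram from its presence pattern.  The feature census classifies protein
descriptions by keyword with a fixed precedence (mobile-element >
ankyrin > multispecies-hypothetical > hypothetical > unknown > assigned).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int
    l50: int
    gc_percent: float | None = None


def assembly_stats(
    lengths: Sequence[int], sequences: Iterable[str] | None = None
) -> AssemblyStats:
    """N50/L50/total from contig lengths; GC when sequences are given."""
    lengths = [int(x) for x in lengths]
    if not lengths:
        raise ValueError("need at least one contig length")
    arr = np.sort(np.asarray(lengths))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, total / 2.0))  # first cum >= total/2
    gc = None
    if sequences is not None:
        g = c = n = 0
        for seq in sequences:
            s = seq.upper()
            g += s.count("G")
            c += s.count("C")
            n += len(s)
        gc = 100.0 * (g + c) / n if n else 0.0
    return AssemblyStats(
        n_contigs=len(lengths),
        total_length=total,
        n50=int(arr[idx]),
        l50=idx + 1,
        gc_percent=gc,
    )


@dataclass
class PangenomePartition:
    """Cluster counts for the 7 regions of a 3-strain Venn diagram."""

    strains: tuple[str, str, str]
    core: int
    pairwise: dict[frozenset, int]  # {a,b} -> count present in exactly a and b
    unique: dict[str, int]

    @property
    def total(self) -> int:
        return self.core + sum(self.pairwise.values()) + sum(self.unique.values())

    def strain_total(self, strain: str) -> int:
        """Clusters containing the strain (its region of the Venn)."""
        if strain not in self.strains:
            raise KeyError(strain)
        return (
            self.core
            + sum(c for pair, c in self.pairwise.items() if strain in pair)
            + self.unique[strain]
        )

    def core_share_percent(self, strain: str) -> float:
        """Core clusters as a percentage of one strain's cluster total."""
        return 100.0 * self.core / self.strain_total(strain)

    def unique_share_percent(self, strain: str) -> float:
        return 100.0 * self.unique[strain] / self.strain_total(strain)


def pangenome_partition(
    membership: pd.DataFrame, strains: Sequence[str] | None = None
) -> PangenomePartition:
    """Partition ortholog clusters by their 3-strain presence pattern.

    ``membership`` holds one row per cluster with boolean presence columns
    (``strains`` names them; defaults to all non-cluster-id columns, which
    must number exactly three).  A cluster present in no strain is an
    error.
    """
    if strains is None:
        strains = [c for c in membership.columns if c != "cluster_id"]
    if len(strains) != 3:
        raise ValueError(f"exactly 3 strains required, got {len(strains)}")
    a, b, c = strains
    pres = membership[list(strains)].astype(bool)
    none = ~pres.any(axis=1)
    if none.any():
        bad = membership.index[none][0]
        raise ValueError(f"cluster at row {bad} present in zero strains")
    pa, pb, pc = (pres[s].to_numpy() for s in strains)
    core = int((pa & pb & pc).sum())
    pairwise = {
        frozenset((a, b)): int((pa & pb & ~pc).sum()),
        frozenset((a, c)): int((pa & ~pb & pc).sum()),
        frozenset((b, c)): int((~pa & pb & pc).sum()),
    }
    unique = {
        a: int((pa & ~pb & ~pc).sum()),
        b: int((~pa & pb & ~pc).sum()),
        c: int((~pa & ~pb & pc).sum()),
    }
    return PangenomePartition(tuple(strains), core, pairwise, unique)


_MOBILE_RE = re.compile(r"transposase|recombinase|integrase", re.IGNORECASE)
_ANKYRIN_RE = re.compile(r"ankyrin", re.IGNORECASE)
_HYPOTHETICAL_RE = re.compile(r"hypothetical protein|uncharacterized", re.IGNORECASE)
_UNKNOWN_RE = re.compile(r"^\s*$|^unknown", re.IGNORECASE)

CENSUS_CATEGORIES = (
    "mobile_element",
    "ankyrin",
    "multispecies_hypothetical",
    "hypothetical",
    "unknown",
    "assigned",
)


@dataclass
class FeatureCensus:
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CENSUS_CATEGORIES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def functional_count(self) -> int:
        """Proteins with an assigned function (incl. mobile-element and
        ankyrin proteins, which are functionally annotated)."""
        return (
            self.counts["assigned"]
            + self.counts["mobile_element"]
            + self.counts["ankyrin"]
        )

    def functional_share_percent(self) -> float:
        return 100.0 * self.functional_count / self.total if self.total else 0.0


def classify_description(description: str) -> str:
    """Category of one protein description under the census precedence."""
    d = description or ""
    if _MOBILE_RE.search(d):
        return "mobile_element"
    if _ANKYRIN_RE.search(d):
        return "ankyrin"
    if d.startswith("MULTISPECIES:") and _HYPOTHETICAL_RE.search(d):
        return "multispecies_hypothetical"
    if _HYPOTHETICAL_RE.search(d):
        return "hypothetical"
    if _UNKNOWN_RE.match(d):
        return "unknown"
    return "assigned"


def feature_census(annotations: pd.DataFrame) -> FeatureCensus:
    """Count proteins per category from an id + description table."""
    census = FeatureCensus()
    if annotations.empty:
        return census
    for desc in annotations["description"].fillna(""):
        census.counts[classify_description(str(desc))] += 1
    return census
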
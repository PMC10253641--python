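"""Alignment screening and composition covariates.

Candidate symbiont contigs are selected from BLAST tabular hits by joint
bitscore / e-value / alignment-length thresholds, and two composition
covariates used downstream are computed per contig: the Codon Adaptation
Index (CAI) against a reference weight table built from trusted symbiont
genes, and sliding-window GC content.

CAI follows the classical relative-adaptiveness formulation: within each
synonymous codon family, a codon's weight is its count in the reference
gene set divided by the count of the family's most frequent codon; a
gene's CAI is the geometric mean of the weights of its codons, excluding
single-codon families (Met, Trp) and stop codons.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import STOP_CODONS, codon_to_aa, synonymous_families


@dataclass
class ScreenThresholds:
    """Joint hit-retention thresholds (all comparisons inclusive)."""

    min_bitscore: float = 60.0
    max_evalue: float = 1e-5
    min_length: int = 55

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(x) for x in (self.min_bitscore, self.max_evalue, self.min_length)
        ):
            raise ValueError("thresholds must be finite")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def filter_hits(
    hits: pd.DataFrame, thresholds: ScreenThresholds | None = None
) -> set[str]:
    """Query ids with at least one hit passing all three thresholds.

    A query qualifies iff a *single* hit satisfies bitscore >= min_bitscore,
    e-value <= max_evalue and alignment length >= min_length simultaneously
    (any-hit rule); the returned set is deduplicated.
    """
    thresholds = thresholds or ScreenThresholds()
    if hits.empty:
        return set()
    ok = (
        (hits["bitscore"] >= thresholds.min_bitscore)
        & (hits["evalue"] <= thresholds.max_evalue)
        & (hits["length"] >= thresholds.min_length)
    )
    return set(hits.loc[ok, "query_id"].unique())


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

#: families excluded from the geometric mean (no synonymous choice)
_SINGLE_CODON_AAS = frozenset(
    aa for aa, codons in synonymous_families().items() if len(codons) == 1
)


@dataclass
class CodonWeightTable:
    """Relative-adaptiveness weights per sense codon, max 1 per family."""

    weights: dict[str, float]
    reference_set_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if not (0.0 < w <= 1.0):
                raise ValueError(f"weight for {codon} must lie in (0, 1], got {w}")


def _codon_iter(cds: str):
    for i in range(0, len(cds) - 2, 3):
        yield cds[i : i + 3]


def build_weight_table(
    reference_cds: dict[str, str] | list[str], floor_scale: float = 0.5
) -> CodonWeightTable:
    """Build a CAI weight table from reference coding sequences.

    weight(codon) = count(codon) / count(most frequent synonymous codon).
    Codons unobserved in an observed family receive a small positive floor
    (``floor_scale`` / max family count); families absent altogether get
    the floor relative to a pseudo-count of 1.  Internal stop codons are
    excluded from counting with a warning.
    """
    if isinstance(reference_cds, dict):
        ids, seqs = list(reference_cds), list(reference_cds.values())
    else:
        ids, seqs = [], list(reference_cds)
    if not seqs:
        raise ValueError("need at least one reference CDS")
    counts: Counter[str] = Counter()
    for sid, seq in zip(ids or [f"seq{i}" for i in range(len(seqs))], seqs):
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"reference CDS {sid} length not divisible by 3")
        n_codons = len(seq) // 3
        for j, codon in enumerate(_codon_iter(seq)):
            if codon in STOP_CODONS:
                if j < n_codons - 1:
                    warnings.warn(
                        f"internal stop codon in reference CDS {sid}; excluded",
                        stacklevel=2,
                    )
                continue
            if codon_to_aa(codon) is not None:
                counts[codon] += 1

    weights: dict[str, float] = {}
    for codons in synonymous_families().values():
        fam_counts = {c: counts.get(c, 0) for c in codons}
        top = max(fam_counts.values())
        if top == 0:
            # amino acid absent from the reference: all codons at the floor
            for c in codons:
                weights[c] = min(1.0, floor_scale)
            continue
        floor = floor_scale / top
        for c in codons:
            weights[c] = fam_counts[c] / top if fam_counts[c] > 0 else min(1.0, floor)
    return CodonWeightTable(weights=weights, reference_set_ids=ids)


def cai(cds: str, table: CodonWeightTable) -> float:
    """Codon Adaptation Index of one coding sequence.

    Geometric mean of codon weights, skipping Met/Trp and stop codons;
    codons with non-ACGT symbols are skipped with a warning.
    """
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    log_sum, n = 0.0, 0
    for codon in _codon_iter(seq):
        if any(b not in "ACGT" for b in codon):
            warnings.warn(f"non-ACGT codon {codon!r} skipped in CAI", stacklevel=2)
            continue
        if codon in STOP_CODONS:
            continue
        aa = codon_to_aa(codon)
        if aa is None or aa in _SINGLE_CODON_AAS:
            continue
        log_sum += math.log(table.weights[codon])
        n += 1
    if n == 0:
        raise ValueError("CDS contains no scorable codons")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# GC profiling
# ---------------------------------------------------------------------------

@dataclass
class GcProfile:
    values: list[float]
    window_starts: list[int]
    overall: float
    trailing_partial: bool  # last window shorter than `window`


def gc_profile(sequence: str, window: int = 1000, step: int | None = None) -> GcProfile:
    """Sliding-window GC fractions plus overall GC.

    Each value is (G+C) over the bases actually covered by the window; a
    trailing partial window is included and flagged.  A window longer than
    the sequence degenerates to a single whole-sequence window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or window
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    is_gc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    overall = float(is_gc.mean())
    if window >= n:
        return GcProfile([overall], [0], overall, trailing_partial=window > n)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    starts = list(range(0, n, step))
    values, partial = [], False
    for s in starts:
        e = min(s + window, n)
        values.append(float((cum[e] - cum[s]) / (e - s)))
        if e - s < window:
            partial = True
    return GcProfile(values, starts, overall, trailing_partial=partial)


# ---------------------------------------------------------------------------
# per-contig covariates
# ---------------------------------------------------------------------------

def cds_sequences(contigs: dict[str, str], cds: pd.DataFrame) -> dict[str, str]:
    """Extract CDS sequences (forward strand) keyed by cds_id."""
    out = {}
    for row in cds.itertuples(index=False):
        seq = contigs[row.contig][row.start : row.end]
        out[row.cds_id] = seq
    return out


def contig_covariates(
    contigs: dict[str, str],
    cds: pd.DataFrame,
    table: CodonWeightTable,
) -> pd.DataFrame:
    """Per-contig length, overall GC, and CAI of the concatenated CDSs."""
    by_contig = cds.groupby("contig") if not cds.empty else None
    rows = []
    for cid, seq in contigs.items():
        gc = gc_profile(seq, window=len(seq)).overall
        cai_val = float("nan")
        if by_contig is not None and cid in by_contig.groups:
            sub = by_contig.get_group(cid)
            concat = "".join(seq[r.start : r.end] for r in sub.itertuples(index=False))
            trimmed = concat[: 3 * (len(concat) // 3)]
            if trimmed:
                try:
                    cai_val = cai(trimmed, table)
                except ValueError:
                    pass
        rows.append({"contig": cid, "length": len(seq), "gc": gc, "cai": cai_val})
    return pd.DataFrame(rows, columns=["contig", "length", "gc", "cai"])
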
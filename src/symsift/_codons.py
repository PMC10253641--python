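"""Fixed codon-usage tables for the two synthetic source genomes.

Each table assigns every sense codon a sampling frequency within its
synonymous family.  The two tables prefer *different* codons in every
family of size >= 2 (the symbiont prefers the most AT-rich codon, the host
the runner-up), so a codon-adaptation index built from one genome's genes
separates the two sources -- the signal the CAI screening stage relies on.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: preference weight of the favoured codon relative to the others in its family
_BOOST = 6.0


@lru_cache(maxsize=None)
def synonymous_families() -> dict[str, tuple[str, ...]]:
    """Amino acid -> sorted tuple of its sense codons (standard code)."""
    fams: dict[str, list[str]] = {}
    for codon, aa in _STANDARD.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in fams.items()}


def codon_to_aa(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    return _STANDARD.forward_table.get(codon)


def _at_rank(codons: tuple[str, ...]) -> list[str]:
    # most AT-rich first; ties broken alphabetically for determinism
    return sorted(codons, key=lambda c: (-(c.count("A") + c.count("T")), c))


def _biased_frequencies(rank: int) -> dict[str, float]:
    freqs: dict[str, float] = {}
    for codons in synonymous_families().values():
        order = _at_rank(codons)
        preferred = order[min(rank, len(order) - 1)]
        weights = {c: (_BOOST if c == preferred else 1.0) for c in codons}
        total = sum(weights.values())
        for c in codons:
            freqs[c] = weights[c] / total
    return freqs


#: codon frequencies used to synthesize symbiont CDSs
SYMBIONT_CODON_FREQS: dict[str, float] = _biased_frequencies(0)

#: codon frequencies used to synthesize host CDSs (distinct preferred codons)
HOST_CODON_FREQS: dict[str, float] = _biased_frequencies(1)
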
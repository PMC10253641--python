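"""Contig adjudication: spanning evidence, decision table, splitting, HGT."""

import numpy as np
import pytest

from symsift.adjudicate import (
    AdjudicationThresholds,
    ContigVerdict,
    TaxonSegment,
    resolve_contig,
    spanning_support,
    split_chimeras,
    summarize_hgt,
    taxon_segments,
)
from symsift.config import (
    CLASS_CHIMERA,
    CLASS_HGT,
    CLASS_SYMBIONT,
    TAXON_HOST,
    TAXON_SYMBIONT,
)
from symsift.coverage import CoverageShift
from symsift.io import PlacementTable


def table_from_pairs(pairs, library="short_a", contig="c1"):
    """Build a PlacementTable from [(l_start, l_end, r_start, r_end), ...]."""
    starts, ends, mates = [], [], []
    for i, (ls, le, rs, re) in enumerate(pairs):
        starts += [ls, rs]
        ends += [le, re]
        mates += [2 * i + 1, 2 * i]
    n = 2 * len(pairs)
    return PlacementTable(
        library=library,
        contig_ids=[contig],
        contig=np.zeros(n, dtype=np.int32),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        mate=np.array(mates, dtype=np.int64),
    )


def table_from_reads(reads, library="long", contig="c1"):
    n = len(reads)
    return PlacementTable(
        library=library,
        contig_ids=[contig],
        contig=np.zeros(n, dtype=np.int32),
        start=np.array([r[0] for r in reads], dtype=np.int64),
        end=np.array([r[1] for r in reads], dtype=np.int64),
        mate=np.full(n, -1, dtype=np.int64),
    )


EMPTY = {
    "short_a": table_from_pairs([]),
    "long": table_from_reads([]),
}


class TestSpanningSupport:
    def test_pair_bracketing_the_region_counts(self):
        placements = {"short_a": table_from_pairs([(100, 250, 900, 1050)])}
        ev = spanning_support(placements, "c1", (300, 800), pad=0)
        assert ev.n_pair_spans == 1 and ev.n_long_spans == 0

    def test_padding_excludes_tight_pairs(self):
        placements = {"short_a": table_from_pairs([(100, 250, 900, 1050)])}
        ev = spanning_support(placements, "c1", (300, 800), pad=200)
        assert ev.n_pair_spans == 0

    def test_long_read_must_cover_padded_region(self):
        placements = {"long": table_from_reads([(50, 1200), (400, 1200)])}
        ev = spanning_support(placements, "c1", (300, 800), pad=200)
        assert ev.n_long_spans == 1

    def test_chimera_junctions_have_no_spanning_reads(self, small_sim):
        for rec in small_sim.truth:
            if rec.true_class != CLASS_CHIMERA:
                continue
            j = rec.junction_pos
            ev = spanning_support(
                small_sim.placements, rec.contig_id, (j - 100, j + 100), pad=0
            )
            assert ev.n_pair_spans == 0 and ev.n_long_spans == 0

    def test_hgt_boundaries_are_spanned(self, small_sim):
        for rec in small_sim.truth:
            if rec.true_class != CLASS_HGT:
                continue
            for edge in rec.insert_intervals[0]:
                ev = spanning_support(
                    small_sim.placements, rec.contig_id, (edge, edge), pad=200
                )
                assert ev.n_pair_spans >= 1 and ev.n_long_spans >= 1


class TestTaxonSegments:
    def test_adjacent_same_taxon_cds_merge(self, small_sim):
        rec = next(r for r in small_sim.truth if r.true_class == CLASS_HGT)
        segs = taxon_segments(small_sim.cds, rec.contig_id)
        taxa = [s.taxon for s in segs]
        assert taxa.count(TAXON_SYMBIONT) == 1
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start
            assert a.taxon != b.taxon


class TestResolveContig:
    def _mixed_segments(self):
        return [
            TaxonSegment("c1", 100, 4800, TAXON_HOST, ["h1", "h2"]),
            TaxonSegment("c1", 5200, 9800, TAXON_SYMBIONT, ["s1", "s2"]),
        ]

    def test_shift_plus_no_spans_is_a_chimera_split_at_midpoint(self):
        placements = {
            "short_a": table_from_pairs([]),
            "long": table_from_reads([(4000, 9500), (4100, 9700)]),  # 2 long spans
        }
        v = resolve_contig(
            "c1",
            10_000,
            self._mixed_segments(),
            [CoverageShift("c1", 5000, 16.0, 128.0)],
            placements,
            "ambiguous",
        )
        assert v.verdict == "chimera"
        assert v.split_pos == 5000
        assert v.evidence["left_taxon"] == TAXON_HOST

    def test_three_long_spans_block_the_chimera_call(self):
        placements = {
            "long": table_from_reads([(4000, 9500)] * 3),
        }
        v = resolve_contig(
            "c1",
            10_000,
            self._mixed_segments(),
            [CoverageShift("c1", 5000, 16.0, 128.0)],
            placements,
            "ambiguous",
        )
        assert v.verdict == "unresolved"

    def test_flat_coverage_with_spans_is_hgt(self):
        pairs = [(4500, 4650, 5400, 5550)]  # brackets the insert edge at 5200
        placements = {
            "short_a": table_from_pairs(pairs),
            "long": table_from_reads([(4000, 9900)]),
        }
        v = resolve_contig(
            "c1", 10_000, self._mixed_segments(), [], placements, "host"
        )
        assert v.verdict == "hgt_host"
        assert v.insert_intervals == [(5200, 9800)]
        assert v.insert_cds_counts == [2]

    def test_pair_spans_alone_fail_the_conjunctive_rule(self):
        placements = {
            "short_a": table_from_pairs([(4500, 4650, 5400, 5550)]),
            "long": table_from_reads([]),
        }
        v = resolve_contig(
            "c1", 10_000, self._mixed_segments(), [], placements, "host"
        )
        assert v.verdict == "unresolved"
        v2 = resolve_contig(
            "c1",
            10_000,
            self._mixed_segments(),
            [],
            placements,
            "host",
            AdjudicationThresholds(require_both_span_types=False),
        )
        assert v2.verdict == "hgt_host"

    def test_uniform_symbiont_annotation_and_coverage(self):
        segs = [TaxonSegment("c1", 0, 9000, TAXON_SYMBIONT, ["s1"])]
        v = resolve_contig("c1", 10_000, segs, [], EMPTY, "symbiont")
        assert v.verdict == "symbiont"

    def test_unannotated_contig_follows_coverage(self):
        assert resolve_contig("c1", 10_000, [], [], EMPTY, "symbiont").verdict == "symbiont"
        assert resolve_contig("c1", 10_000, [], [], EMPTY, "host").verdict == "host"
        assert (
            resolve_contig("c1", 10_000, [], [], EMPTY, "ambiguous").verdict
            == "unresolved"
        )

    def test_verdict_invariants_enforced(self):
        with pytest.raises(ValueError):
            ContigVerdict("c1", "chimera")
        with pytest.raises(ValueError):
            ContigVerdict("c1", "host", split_pos=5)


class TestSplitChimeras:
    def test_split_produces_suffixed_parts_of_correct_size(self):
        contigs = {"c1": "A" * 4000 + "G" * 6000}
        v = ContigVerdict(
            "c1",
            "chimera",
            split_pos=4000,
            contig_length=10_000,
            evidence={"left_taxon": TAXON_HOST, "right_taxon": TAXON_SYMBIONT},
        )
        sym, host = split_chimeras(contigs, [v])
        assert host == {"c1.1": "A" * 4000}
        assert sym == {"c1.2": "G" * 6000}

    def test_no_chimeras_passes_through_by_verdict(self):
        contigs = {"a": "ACGT", "b": "GGCC", "u": "ATAT"}
        verdicts = [
            ContigVerdict("a", "symbiont"),
            ContigVerdict("b", "host"),
            ContigVerdict("u", "unresolved"),
        ]
        sym, host = split_chimeras(contigs, verdicts)
        assert sym == {"a": "ACGT"} and host == {"b": "GGCC"}

    def test_degenerate_split_position_rejected(self):
        contigs = {"c1": "ACGT" * 10}
        v = ContigVerdict("c1", "chimera", split_pos=0)
        with pytest.raises(ValueError):
            split_chimeras(contigs, [v])

    def test_sequence_conservation(self):
        contigs = {"c1": "A" * 3000 + "G" * 3000, "c2": "ACGT" * 500}
        verdicts = [
            ContigVerdict(
                "c1", "chimera", split_pos=3000, evidence={"left_taxon": TAXON_SYMBIONT}
            ),
            ContigVerdict("c2", "host"),
        ]
        sym, host = split_chimeras(contigs, verdicts)
        total = sum(len(s) for s in sym.values()) + sum(len(s) for s in host.values())
        assert total == sum(len(s) for s in contigs.values())


class TestSummarizeHgt:
    def _verdicts(self, cds_counts, lengths=None, ins_lens=None):
        out = []
        for i, k in enumerate(cds_counts):
            out.append(
                ContigVerdict(
                    f"c{i}",
                    "hgt_host",
                    insert_intervals=[(0, 100)],
                    insert_cds_counts=[k],
                    insert_lengths=[ins_lens[i] if ins_lens else 100],
                    contig_length=lengths[i] if lengths else 1000,
                )
            )
        return out

    def test_worked_example_mean_and_se(self):
        s = summarize_hgt(self._verdicts([1, 2, 4, 19]))
        assert s.mean_cds_per_insert == pytest.approx(6.5)
        assert s.se_cds_per_insert == pytest.approx(4.213, abs=5e-4)
        assert s.frac_le4_cds == pytest.approx(0.75)

    def test_empty_input_reports_absent_fields(self):
        s = summarize_hgt([])
        assert s.n_contigs == 0
        assert s.mean_cds_per_insert is None
        assert s.max_insert_len is None

    def test_agrees_with_brute_force_recomputation(self, small_sim):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, 12).tolist()
        ins = rng.integers(300, 9000, 12).tolist()
        lens = rng.integers(10_000, 60_000, 12).tolist()
        s = summarize_hgt(self._verdicts(counts, lens, ins))
        arr = np.array(counts, float)
        assert s.mean_cds_per_insert == pytest.approx(arr.mean())
        assert s.se_cds_per_insert == pytest.approx(arr.std(ddof=1) / np.sqrt(len(arr)))
        assert s.max_insert_len == max(ins)
        li = np.array(lens, float)
        assert s.se_contig_len == pytest.approx(li.std(ddof=1) / np.sqrt(len(li)))
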
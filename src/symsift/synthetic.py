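"""Synthetic holobiont metagenome with planted ground truth.

Two source genomes are synthesized -- a "host" (insect-like: higher GC,
sparse coding) and a "symbiont" (intracellular-bacterium-like: lower GC,
dense coding, distinct codon usage) -- and contigs are cut from them:

* pure host and pure symbiont fragments,
* chimeras: a host fragment concatenated to a symbiont fragment at a
  recorded junction, emulating assembly mis-joins,
* HGT contigs: host fragments with a block of consecutive symbiont CDSs
  spliced into an intergenic gap, emulating symbiont-to-host horizontal
  gene transfer.

Read placements (three short-insert paired libraries plus one long-read
library) are simulated per contig at class-appropriate depths.  Reads and
pairs never cross a chimera junction but freely span HGT insert
boundaries, because the insert is genuinely part of the host chromosome.
A BLAST-style hit table against a notional symbiont reference database is
also simulated so the screening stage can run end to end.

Coordinates are 0-based half-open throughout; GFF3 output is converted at
the file boundary (see :mod:`symsift.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import HOST_CODON_FREQS, SYMBIONT_CODON_FREQS
from .config import (
    CLASS_CHIMERA,
    CLASS_HGT,
    CLASS_HOST,
    CLASS_SYMBIONT,
    LONG_LIBRARY,
    SHORT_LIBRARIES,
    TAXON_HOST,
    TAXON_SYMBIONT,
    SimulationConfig,
    TruthRecord,
    truth_to_frame,
)
from .io import PlacementTable, write_blast6, write_fasta, write_gff3

# clearance (bp) kept between a chimera junction and the nearest CDS
# boundary; > read length so junction evidence channels stay independent
_JUNCTION_CLEARANCE = 260
_JUNCTION_JITTER = 40

# geometric parameter for HGT insert CDS counts: P(k<=4) ~ 0.83, mean ~ 2.8
_INSERT_CDS_GEOM_P = 0.36

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Genome:
    """A synthetic source genome: sequence plus its planted CDS coordinates."""

    sequence: str
    cds: list[tuple[int, int]]  # 0-based half-open, forward strand
    gc_target: float

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


def _sample_cds_seqs(
    rng: np.random.Generator, n_codons: np.ndarray, freqs: dict[str, float]
) -> list[str]:
    codons = np.array(sorted(freqs))
    p = np.array([freqs[c] for c in codons])
    p = p / p.sum()
    idx = rng.choice(len(codons), size=int(n_codons.sum()), p=p)
    flat = codons[idx]
    seqs, off = [], 0
    for n in n_codons:
        seqs.append("ATG" + "".join(flat[off : off + n]) + "TAA")
        off += n
    return seqs


def _bernoulli_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """Uniform-within-pair Bernoulli(gc) DNA: G/C with prob gc, A/T otherwise."""
    is_gc = rng.random(length) < gc
    alt = rng.random(length) < 0.5
    # codes into "ACGT": A=0 C=1 G=2 T=3
    codes = np.where(is_gc, np.where(alt, 2, 1), np.where(alt, 0, 3)).astype(np.uint8)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _synth_genome(
    rng: np.random.Generator,
    length: int,
    gc_target: float,
    coding_density: float,
    codon_freqs: dict[str, float],
) -> Genome:
    mean_cds = 250 * 3 + 6  # mean CDS length in bp
    mean_gap = mean_cds * (1.0 - coding_density) / coding_density
    gap_lo, gap_hi = max(30, int(0.5 * mean_gap)), int(1.5 * mean_gap) + 1

    # lay out alternating gap / CDS blocks until the target length is reached
    gaps: list[int] = []
    cds_codons: list[int] = []
    pos = 0
    while True:
        gap = int(rng.integers(gap_lo, gap_hi))
        ncod = int(rng.integers(100, 401))
        if pos + gap + 3 * ncod + 6 > length:
            gaps.append(length - pos)  # trailing intergenic remainder
            break
        gaps.append(gap)
        cds_codons.append(ncod)
        pos += gap + 3 * ncod + 6

    cds_seqs = _sample_cds_seqs(rng, np.asarray(cds_codons, dtype=np.int64), codon_freqs)
    cds_bases = sum(len(s) for s in cds_seqs)
    cds_gc = sum(s.count("G") + s.count("C") for s in cds_seqs)
    inter_bases = length - cds_bases
    # choose the intergenic GC so the whole genome hits gc_target in expectation
    p_inter = (gc_target * length - cds_gc) / max(inter_bases, 1)
    p_inter = float(np.clip(p_inter, 0.01, 0.99))

    pieces: list[str] = []
    cds_coords: list[tuple[int, int]] = []
    pos = 0
    for i, gap in enumerate(gaps):
        pieces.append(_bernoulli_dna(rng, gap, p_inter))
        pos += gap
        if i < len(cds_seqs):
            s = cds_seqs[i]
            pieces.append(s)
            cds_coords.append((pos, pos + len(s)))
            pos += len(s)
    return Genome(sequence="".join(pieces), cds=cds_coords, gc_target=gc_target)


def make_source_genomes(config: SimulationConfig) -> tuple[Genome, Genome]:
    """Synthesize the (host, symbiont) source genomes.

    Each genome's overall GC lands within +-0.005 of its configured target;
    the same seed reproduces byte-identical sequences.
    """
    rng = np.random.default_rng([config.seed, 0])
    host = _synth_genome(
        rng,
        config.host_genome_len,
        config.host_gc,
        config.host_coding_density,
        HOST_CODON_FREQS,
    )
    symbiont = _synth_genome(
        rng,
        config.symbiont_genome_len,
        config.symbiont_gc,
        config.symbiont_coding_density,
        SYMBIONT_CODON_FREQS,
    )
    return host, symbiont


# ---------------------------------------------------------------------------
# contig planting
# ---------------------------------------------------------------------------

def _gaps(genome: Genome) -> list[tuple[int, int]]:
    """Intergenic intervals of a genome (between consecutive CDSs)."""
    out = []
    prev = 0
    for s, e in genome.cds:
        if s > prev:
            out.append((prev, s))
        prev = e
    if len(genome) > prev:
        out.append((prev, len(genome)))
    return out


def _lift_cds(
    genome: Genome, frag_start: int, frag_end: int, offset: int
) -> list[tuple[int, int]]:
    """CDSs fully inside [frag_start, frag_end), shifted to contig coords."""
    return [
        (s - frag_start + offset, e - frag_start + offset)
        for s, e in genome.cds
        if s >= frag_start and e <= frag_end
    ]


def _trunc_geometric(rng: np.random.Generator, lo: int, hi: int) -> int:
    for _ in range(1000):
        k = int(rng.geometric(_INSERT_CDS_GEOM_P))
        if lo <= k <= hi:
            return k
    return lo


def plant_contigs(
    config: SimulationConfig, host_genome: Genome, symbiont_genome: Genome
) -> tuple[dict[str, str], pd.DataFrame, list[TruthRecord]]:
    """Cut contigs from the source genomes and record planted truth.

    Returns ``(contigs, cds_table, truth_records)`` where ``cds_table`` has
    columns contig/start/end/strand/cds_id/taxon (0-based half-open) and
    every CDS carries the taxon of its true origin.
    """
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.contig_len_range
    if hi > min(len(host_genome), len(symbiont_genome)):
        raise ValueError("contig_len_range exceeds source genome length")

    contigs: dict[str, str] = {}
    cds_rows: list[dict] = []
    truth: list[TruthRecord] = []
    counter = 0

    cds_counts: dict[str, int] = {}

    def add_cds(contig_id: str, coords: list[tuple[int, int]], taxon: str) -> None:
        for s, e in coords:
            i = cds_counts.get(contig_id, 0)
            cds_counts[contig_id] = i + 1
            cds_rows.append(
                {
                    "contig": contig_id,
                    "start": s,
                    "end": e,
                    "strand": "+",
                    "cds_id": f"{contig_id}_cds{i:04d}",
                    "taxon": taxon,
                }
            )

    def pure_contig(genome: Genome, taxon: str, true_class: str) -> None:
        nonlocal counter
        L = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(0, len(genome) - L + 1))
        cid = f"ctg{counter:05d}"
        counter += 1
        contigs[cid] = genome.sequence[s : s + L]
        add_cds(cid, _lift_cds(genome, s, s + L, 0), taxon)
        truth.append(TruthRecord(contig_id=cid, true_class=true_class))

    for _ in range(config.n_host_contigs):
        pure_contig(host_genome, TAXON_HOST, CLASS_HOST)
    for _ in range(config.n_symbiont_contigs):
        pure_contig(symbiont_genome, TAXON_SYMBIONT, CLASS_SYMBIONT)

    host_gaps = _gaps(host_genome)
    sym_gaps = _gaps(symbiont_genome)
    clearance = max(_JUNCTION_CLEARANCE, config.read_len + 60)

    # genome cut positions with `clearance` bp of intergenic DNA on the
    # junction-facing side; (cut, distance-to-CDS) pairs
    host_cut_gaps = [g for g in host_gaps if g[1] - g[0] >= clearance + _JUNCTION_JITTER]
    sym_cut_gaps = [g for g in sym_gaps if g[1] - g[0] >= clearance + _JUNCTION_JITTER]
    if (config.n_chimeras > 0) and (not host_cut_gaps or not sym_cut_gaps):
        raise ValueError("source genomes have no intergenic gaps wide enough for chimera junctions")

    def make_chimera() -> None:
        nonlocal counter
        for _ in range(200):
            L = int(rng.integers(max(20_000, lo), hi + 1))
            frac = rng.uniform(0.35, 0.65)
            len_host = int(L * frac)
            len_sym = L - len_host
            # host side ends `clearance+u1` bp after its last CDS
            gs, ge = host_cut_gaps[int(rng.integers(len(host_cut_gaps)))]
            u1 = int(rng.integers(0, _JUNCTION_JITTER + 1))
            cut_h = gs + clearance + u1
            if cut_h > ge or cut_h - len_host < 0:
                continue
            # symbiont side starts `clearance+u2` bp before its first CDS
            gs2, ge2 = sym_cut_gaps[int(rng.integers(len(sym_cut_gaps)))]
            u2 = int(rng.integers(0, _JUNCTION_JITTER + 1))
            cut_s = ge2 - clearance - u2
            if cut_s < gs2 or cut_s + len_sym > len(symbiont_genome):
                continue
            host_cds = _lift_cds(host_genome, cut_h - len_host, cut_h, 0)
            sym_cds = _lift_cds(symbiont_genome, cut_s, cut_s + len_sym, len_host)
            if not host_cds or not sym_cds:
                continue
            cid = f"ctg{counter:05d}"
            counter += 1
            contigs[cid] = (
                host_genome.sequence[cut_h - len_host : cut_h]
                + symbiont_genome.sequence[cut_s : cut_s + len_sym]
            )
            add_cds(cid, host_cds, TAXON_HOST)
            add_cds(cid, sym_cds, TAXON_SYMBIONT)
            truth.append(
                TruthRecord(contig_id=cid, true_class=CLASS_CHIMERA, junction_pos=len_host)
            )
            return
        raise RuntimeError("failed to place a chimera junction; genomes too gene-dense")

    for _ in range(config.n_chimeras):
        make_chimera()

    k_lo, k_hi = config.insert_cds_range
    sym_cds_arr = symbiont_genome.cds

    def pick_insert(k: int) -> tuple[int, int, list[tuple[int, int]]] | None:
        """Slice of the symbiont genome holding k consecutive CDSs + margins."""
        for _ in range(200):
            i = int(rng.integers(0, len(sym_cds_arr) - k + 1))
            m1 = int(rng.integers(20, 61))
            m2 = int(rng.integers(20, 61))
            a = sym_cds_arr[i][0] - m1
            b = sym_cds_arr[i + k - 1][1] + m2
            if a < 0 or b > len(symbiont_genome):
                continue
            # margins must be intergenic: neighbours stay outside the slice
            if i > 0 and sym_cds_arr[i - 1][1] > a:
                continue
            if i + k < len(sym_cds_arr) and sym_cds_arr[i + k][0] < b:
                continue
            rel = [(s - a, e - a) for s, e in sym_cds_arr[i : i + k]]
            return a, b, rel
        return None

    def make_hgt() -> None:
        nonlocal counter
        for _ in range(200):
            k = _trunc_geometric(rng, k_lo, k_hi)
            ins = pick_insert(k)
            if ins is None:
                continue
            a, b, rel_cds = ins
            insert_seq = symbiont_genome.sequence[a:b]
            L_host = int(rng.integers(max(30_000, lo), hi + 1))
            s = int(rng.integers(0, len(host_genome) - L_host + 1))
            host_cds = _lift_cds(host_genome, s, s + L_host, 0)
            if len(host_cds) < 3:
                continue
            # splice right after a non-terminal host CDS, a short gap away,
            # so both HGT boundary regions stay small enough for read pairs
            # to span them
            j = int(rng.integers(1, len(host_cds) - 1))
            g1 = int(rng.integers(40, 121))
            q = host_cds[j][1] + g1
            if j + 1 < len(host_cds) and q >= host_cds[j + 1][0] - 40:
                continue
            cid = f"ctg{counter:05d}"
            counter += 1
            frag = host_genome.sequence[s : s + L_host]
            contigs[cid] = frag[:q] + insert_seq + frag[q:]
            before = [c for c in host_cds if c[1] <= q]
            after = [(cs + len(insert_seq), ce + len(insert_seq)) for cs, ce in host_cds if cs >= q]
            add_cds(cid, before, TAXON_HOST)
            add_cds(cid, [(q + cs, q + ce) for cs, ce in rel_cds], TAXON_SYMBIONT)
            add_cds(cid, after, TAXON_HOST)
            truth.append(
                TruthRecord(
                    contig_id=cid,
                    true_class=CLASS_HGT,
                    insert_intervals=[(q, q + len(insert_seq))],
                    insert_cds_count=k,
                )
            )
            return
        raise RuntimeError("failed to place an HGT insert")

    for _ in range(config.n_hgt_contigs):
        make_hgt()

    cds_df = pd.DataFrame(
        cds_rows, columns=["contig", "start", "end", "strand", "cds_id", "taxon"]
    )
    return contigs, cds_df, truth


# ---------------------------------------------------------------------------
# read placements
# ---------------------------------------------------------------------------

def _class_segments(
    contig_len: int, rec: TruthRecord
) -> list[tuple[int, int, str]]:
    """(start, end, source_class) segments of a contig for depth purposes."""
    if rec.true_class == CLASS_CHIMERA:
        j = int(rec.junction_pos)
        return [(0, j, CLASS_HOST), (j, contig_len, CLASS_SYMBIONT)]
    if rec.true_class == CLASS_SYMBIONT:
        return [(0, contig_len, CLASS_SYMBIONT)]
    # host and hgt_host contigs are host chromosome throughout
    return [(0, contig_len, CLASS_HOST)]


def simulate_placements(
    config: SimulationConfig,
    contigs: dict[str, str],
    truth: list[TruthRecord],
) -> dict[str, PlacementTable]:
    """Simulate read placements for three short-insert libraries and one
    long-read library.

    Read counts are Poisson at the class-appropriate mean depth with
    uniform start positions inside each source segment, so chimera halves
    show their source depths and no read or pair crosses a chimera
    junction.  HGT contigs are covered uniformly end to end (the insert is
    host chromosome), so pairs and long reads span insert boundaries.
    """
    if not contigs:
        raise ValueError("no contigs to place reads on")
    truth_by_id = {r.contig_id: r for r in truth}
    contig_ids = list(contigs)
    rl = config.read_len
    ins_mean, ins_sd = config.insert_size
    tables: dict[str, PlacementTable] = {}

    lib_rngs = {
        lib: np.random.default_rng([config.seed, 2, i])
        for i, lib in enumerate([*SHORT_LIBRARIES, LONG_LIBRARY])
    }

    for lib in SHORT_LIBRARIES:
        rng = lib_rngs[lib]
        codes, starts, ends, mates = [], [], [], []
        offset = 0
        for code, cid in enumerate(contig_ids):
            L = len(contigs[cid])
            rec = truth_by_id[cid]
            for a, b, cls in _class_segments(L, rec):
                depth = (
                    config.symbiont_cov_short
                    if cls == CLASS_SYMBIONT
                    else config.host_cov_short
                )
                seg = b - a
                if seg < 2 * rl + 20 or depth <= 0:
                    continue
                n = int(rng.poisson(depth * seg / (2 * rl)))
                if n == 0:
                    continue
                o = np.clip(
                    np.round(rng.normal(ins_mean, ins_sd, n)), 2 * rl + 20, seg
                ).astype(np.int64)
                s1 = a + np.floor(rng.random(n) * (seg - o + 1)).astype(np.int64)
                left_s, left_e = s1, s1 + rl
                right_s, right_e = s1 + o - rl, s1 + o
                codes.append(np.full(2 * n, code, dtype=np.int32))
                starts.append(np.concatenate([left_s, right_s]))
                ends.append(np.concatenate([left_e, right_e]))
                m = np.empty(2 * n, dtype=np.int64)
                m[:n] = offset + n + np.arange(n)
                m[n:] = offset + np.arange(n)
                mates.append(m)
                offset += 2 * n
        tables[lib] = _assemble(lib, contig_ids, codes, starts, ends, mates)

    rng = lib_rngs[LONG_LIBRARY]
    codes, starts, ends, mates = [], [], [], []
    lrl = config.long_read_len
    for code, cid in enumerate(contig_ids):
        L = len(contigs[cid])
        rec = truth_by_id[cid]
        for a, b, cls in _class_segments(L, rec):
            depth = (
                config.symbiont_cov_long if cls == CLASS_SYMBIONT else config.host_cov_long
            )
            seg = b - a
            if seg < 600 or depth <= 0:
                continue
            n = int(rng.poisson(depth * seg / lrl))
            if n == 0:
                continue
            lens = np.clip(
                np.round(rng.normal(lrl, 0.1 * lrl, n)), 500, seg
            ).astype(np.int64)
            s = a + np.floor(rng.random(n) * (seg - lens + 1)).astype(np.int64)
            codes.append(np.full(n, code, dtype=np.int32))
            starts.append(s)
            ends.append(s + lens)
            mates.append(np.full(n, -1, dtype=np.int64))
    tables[LONG_LIBRARY] = _assemble(LONG_LIBRARY, contig_ids, codes, starts, ends, mates)
    return tables


def _assemble(lib, contig_ids, codes, starts, ends, mates) -> PlacementTable:
    if not codes:
        z = np.empty(0, dtype=np.int64)
        return PlacementTable(lib, contig_ids, z.astype(np.int32), z, z, z)
    return PlacementTable(
        library=lib,
        contig_ids=contig_ids,
        contig=np.concatenate(codes),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        mate=np.concatenate(mates),
    )


# ---------------------------------------------------------------------------
# alignment hits
# ---------------------------------------------------------------------------

def simulate_alignment_hits(
    config: SimulationConfig,
    contigs: dict[str, str],
    truth: list[TruthRecord],
    cds: pd.DataFrame | None = None,
    p_host_passing: float = 0.4,
    p_host_weak: float = 0.35,
) -> pd.DataFrame:
    """Simulate BLASTn-style hits of contigs against a symbiont reference set.

    Contigs with genuine symbiont content (pure symbiont, chimera halves,
    HGT inserts) receive strong hits inside their symbiont-derived region.
    A fraction of host contigs receive borderline passing hits and another
    fraction short, weak hits, reproducing the structure of a real screen
    where the alignment filter keeps far more candidates than are truly
    symbiont.
    """
    rng = np.random.default_rng([config.seed, 3])
    rows = []

    def region_of(rec: TruthRecord, L: int) -> tuple[int, int]:
        if rec.true_class == CLASS_SYMBIONT:
            return 0, L
        if rec.true_class == CLASS_CHIMERA:
            return int(rec.junction_pos), L
        a, b = rec.insert_intervals[0]
        return a, b

    def add_hit(cid, qs, qe, ident, bits, ev):
        length = qe - qs
        rows.append(
            {
                "query_id": cid,
                "subject_id": "symbiont_ref_001",
                "percent_identity": round(float(ident), 2),
                "length": int(length),
                "mismatches": int(round(length * (100 - ident) / 100)),
                "gap_opens": 0,
                "query_start": int(qs),
                "query_end": int(qe),
                "subject_start": 0,
                "subject_end": int(length),
                "evalue": float(ev),
                "bitscore": round(float(bits), 1),
            }
        )

    for rec in truth:
        L = len(contigs[rec.contig_id])
        if rec.true_class in (CLASS_SYMBIONT, CLASS_CHIMERA, CLASS_HGT):
            a, b = region_of(rec, L)
            n = 1 + int(rng.poisson(1.5))
            for _ in range(n):
                hlen = int(rng.integers(150, max(151, min(1500, b - a))))
                qs = int(rng.integers(a, max(a + 1, b - hlen + 1)))
                ident = rng.uniform(88.0, 99.5)
                add_hit(
                    rec.contig_id,
                    qs,
                    qs + hlen,
                    ident,
                    1.8 * hlen,
                    10.0 ** -rng.uniform(20, 80),
                )
        else:
            u = rng.random()
            if u < p_host_passing:
                hlen = int(rng.integers(55, 201))
                qs = int(rng.integers(0, max(1, L - hlen)))
                add_hit(
                    rec.contig_id,
                    qs,
                    qs + hlen,
                    rng.uniform(70, 85),
                    rng.uniform(60, 110),
                    10.0 ** -rng.uniform(5, 12),
                )
            elif u < p_host_passing + p_host_weak:
                hlen = int(rng.integers(30, 91))
                qs = int(rng.integers(0, max(1, L - hlen)))
                add_hit(
                    rec.contig_id,
                    qs,
                    qs + hlen,
                    rng.uniform(65, 75),
                    rng.uniform(25, 59.9),
                    10.0 ** -rng.uniform(0, 5),
                )
    from .io import BLAST6_COLUMNS

    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMetagenome:
    config: SimulationConfig
    host_genome: Genome
    symbiont_genome: Genome
    contigs: dict[str, str]
    cds: pd.DataFrame
    truth: list[TruthRecord]
    placements: dict[str, PlacementTable] = field(default_factory=dict)
    hits: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "contigs.fasta")
        write_gff3(self.cds, outdir / "cds.gff3")
        truth_to_frame(self.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.hits is not None:
            write_blast6(self.hits, outdir / "hits.tsv")
        if self.placements:
            frames = [t.to_frame() for t in self.placements.values()]
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "placements.tsv", sep="\t", index=False
            )


def simulate(config: SimulationConfig, with_placements: bool = True) -> SyntheticMetagenome:
    """Generate the full synthetic metagenome bundle for a config."""
    host, sym = make_source_genomes(config)
    contigs, cds, truth = plant_contigs(config, host, sym)
    placements = simulate_placements(config, contigs, truth) if with_placements else {}
    hits = simulate_alignment_hits(config, contigs, truth, cds)
    return SyntheticMetagenome(
        config=config,
        host_genome=host,
        symbiont_genome=sym,
        contigs=contigs,
        cds=cds,
        truth=truth,
        placements=placements,
        hits=hits,
    )
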
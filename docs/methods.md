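# Methods

This note documents the models, rules, and numerical choices behind
`symsift`: what each stage assumes, which parameters matter, and what
the synthetic benchmark does and does not establish about real data.

## The parsing problem

A holobiont assembly mixes contigs from a host animal and an
intracellular bacterial symbiont. Three signals separate them:

1. **Sequence composition.** The two genomes differ in GC content and in
   codon usage, so penta-nucleotide frequency vectors and the Codon
   Adaptation Index (CAI) carry source information.
2. **Read depth.** The symbiont is present at many copies per host cell;
   its contigs sit at roughly an order of magnitude higher coverage
   (defaults here: 128× vs 16× short-read; 189× vs 16× long-read),
   consistently across libraries.
3. **Read continuity.** An assembly mis-join (chimera) is a coverage
   step that no read pair and at most a stray long read or two crosses;
   a genuine horizontally transferred insert is ordinary host chromosome
   and is bridged freely.

The pipeline applies these in order: alignment screen → composition
binning → coverage classification and shift detection → per-contig
adjudication → assembly summaries.

## Alignment screen

Candidates are query contigs with at least one tabular hit passing all
three thresholds jointly (any-hit rule): bitscore ≥ 60, e-value ≤ 1e-5,
length ≥ 55 bp, all comparisons inclusive. The joint per-hit rule (rather
than best-of-each-marginal) is deliberate: a contig qualifying on three
different weak hits is weaker evidence than one hit that is long, strong,
and significant at once.

**CAI.** Weights are the classical relative-adaptiveness form: within a
synonymous family, w(c) = count(c) / count(most frequent codon). Codons
unobserved within an observed family get a floor of 0.5/(max family
count), a standard pseudo-count convention that keeps the geometric mean
finite; families absent from the reference altogether get a flat 0.5.
Met, Trp, and stop codons are excluded from the geometric mean (no
synonymous choice, hence no information). The reference gene set is
drawn from candidates that look unambiguously symbiont: ≥ 5 kbp, best
hit identity ≥ 95%, and exclusively symbiont-taxon CDS annotations.

## Composition binning

Profiles are forward-strand 5-mer frequencies (windows with non-ACGT
symbols skipped; a `--canonical` flag pools reverse complements).
Clustering is a bootstrap k-medoids consensus:

* PCA to 10 components (the 1024-dim frequency simplex is highly
  collinear; 10 components retain the composition contrast),
* 100 bootstrap resamples of the contig set; each resample is clustered
  with Voronoi-iteration k-medoids and *every* contig is assigned to its
  nearest medoid, so co-assignment is defined for all pairs in every
  replicate,
* the co-assignment matrix is cut by average linkage into the final
  bins; a contig's confidence is its mean co-assignment with its own
  bin, and contigs below 0.8 are flagged unbinned.

k-medoids is written in-house (no installed implementation); it operates
on a precomputed Euclidean distance matrix, with distances below 1e-12
snapped to zero so duplicate profiles are tie-broken identically.
Contigs are canonicalized by id before resampling, which makes bin
composition exactly invariant to input order. `n_clusters="auto"`
maximizes mean silhouette over k ∈ 2..6; the pipeline default is k = 2
(host vs symbiont).

## Coverage

Depth profiles are per-base interval coverage averaged in 100 bp bins
(the trailing partial bin averages over its real width). Classification
uses the median bin depth per library against a host depth prior:
symbiont iff median ≥ 6 × prior in **all** libraries, host iff median
≤ 2 × prior in all, else ambiguous. The 6× cut is inclusive and
configurable; it sits well inside the ~8× class gap of the default
conditions. Medians, not means, because chimeric halves and edge
effects otherwise leak across the contig.

**Shift detection.** At every interior bin boundary with `flank`
(default 1000 bp) of profile on both sides, the median depth of the left
and right flanks is compared; boundaries with ratio ≥ 3 (max/min, the
smaller median floored at 0.5 to tolerate zero-coverage flanks) are
candidates, and runs of adjacent candidates are merged. Within a merged
run the reported position is the one maximizing the *mean*-based
contrast: the median ratio plateaus over several bins around a clean
step (robustness is its job), while the mean contrast peaks exactly at
the step. Under flat Poisson noise at ~20× the false-positive rate is
below 1% per contig (verified by simulation in the tests).

## Adjudication

CDSs carry a taxon attribute (`alphaproteobacteria` / `eukaryota`);
consecutive same-taxon CDSs collapse into segments, and the gap between
adjacent different-taxon segments is the boundary region. The decision
table:

| evidence | verdict |
|---|---|
| mixed taxa, shift co-located (± flank) with a boundary, 0 pair spans and ≤ 2 long spans | chimera; split at the midpoint of the boundary region ∩ shift ± flank |
| mixed taxa, no shift at any boundary, ≥ 1 pair span **and** ≥ 1 long span at every boundary | hgt_host; inserts = symbiont-taxon segments |
| all symbiont-taxon (or unannotated) and symbiont coverage | symbiont |
| all host-taxon, or host coverage | host |
| otherwise | unresolved (evidence attached) |

Two operationalizations deserve note:

* **Spanning regions.** For the chimera test, spanning is counted across
  the whole padded boundary region — bridging the entire gap is what
  would prove the join real, and a mis-join has no such reads by
  construction. For the HGT test, continuity is judged across a padded
  window at the symbiont-segment *edge* (insert boundary): host
  intergenic gaps flanking an insert can span kilobases that no read
  pair could bridge even on a perfectly intact chromosome, so demanding
  a full-gap span would make the rule unsatisfiable on real geometry.
  The pad is 200 bp on each side.
* **Conjunctive HGT rule.** Both a pair span and a long-read span are
  required (the strict reading); `require_both_span_types=False` relaxes
  it to either.

A shift that does not co-locate with a taxon boundary never triggers a
split — repeats and copy-number features produce shifts on single-taxon
contigs, and the chimera rule deliberately ignores them.

HGT summaries report per-contig totals (CDSs per insert, insert length
as the total symbiont-segment length) with SE = sample sd/√n, the
longest single insert, and the fraction of carriers with ≤ 4 CDSs.

## Pathway audit

A pathway is an ordered list of steps, each a disjunction of enzymes
(keys match by EC number first, gene symbol as fallback); the pathway is
the conjunction of its steps. A step is satisfied iff some alternative
is `present`; `pseudogene` (e.g. a frameshifted gene) is equivalent to
`absent` everywhere. Verdicts: **capable** (all steps), **conditional**
(every unsatisfied step lies strictly upstream of some entry substrate's
entry point — the earliest such substrate(s) are reported as the minimal
supplement), **incapable** otherwise. This gives the intended
asymmetry: losing only *dxs* is rescued by host-supplied DXP, but a
broken *ispG* sits downstream of that entry and cannot be.

Branched routes are encoded as entry substrates on one linear
definition (SAM from aspartate vs homoserine vs methionine), and the
multi-route IAA map pools each route's enzymes as per-step alternatives
— a simplification that suits presence/absence capability questions,
not flux. The "LASS" gene of the methionine route is carried as a gene
symbol only (no EC), at the homoserine-acylation step. Definitions ship
as a documented JSON schema (`symsift/data/pathways.json`) and
round-trip through `save_pathway_defs`/`load_pathway_defs`.

## Synthetic metagenome

The generator emulates the features the pipeline exploits, with defaults
set to the motivating study system:

| parameter | default | meaning |
|---|---|---|
| host_gc / symbiont_gc | 0.378 / 0.353 | overall GC targets, hit to ± 0.005 |
| host_cov_short / long | 16× / 16× | host depth per library |
| symbiont_cov_short / long | 128× / 189× | symbiont depth |
| contigs | 500 host, 150 symbiont, 15 chimeras, 20 HGT (~20 Mbp) | default census |
| contig_len_range | 5–60 kbp | chimeras ≥ 20 kbp, HGT carriers ≥ 30 kbp, so every artifact has room for flanks and junction clearance |
| insert_cds_range | (1, 19) | CDSs per HGT insert; counts drawn from a geometric distribution (p = 0.36, truncated to the range), giving mean ≈ 2.8 and ~83% of inserts with ≤ 4 CDSs |
| read_len / insert_size | 150 bp / 900 ± 100 bp | short-read geometry; the insert size is a free parameter and is set long enough that pairs can bracket a padded insert-edge window (a 350 bp insert geometrically cannot) |
| long_read_len | 5000 bp mean | long-read length (± 10%) |

Source genomes alternate intergenic DNA with in-frame ORFs (`ATG` +
codons + `TAA`). Intergenic bases are per-base Bernoulli(gc) over
{G,C} vs {A,T}; CDS codons are drawn from two fixed codon-frequency
tables that prefer *different* codons in every synonymous family
(symbiont: most AT-rich codon at 6:1; host: the runner-up), so CAI
built from symbiont genes separates the sources by construction. The
intergenic GC is solved analytically from the realized CDS GC so the
whole genome hits its target. Coding density is 0.70 for the symbiont
(gene-dense bacterium) and 0.30 for the host.

Chimeras concatenate a host and a symbiont fragment cut inside
intergenic gaps, keeping ≥ 260 bp (more than a read length) between the
junction and the nearest CDS so the annotation and coverage evidence
channels stay independent; HGT inserts are k consecutive symbiont CDSs
with 20–60 bp intergenic margins spliced a short (40–120 bp) gap after a
host CDS. Read counts are Poisson at the class depth with uniform
starts inside each source segment: chimera halves get their own depths
and nothing crosses the junction; HGT carriers are covered uniformly end
to end. There is no sequencing-error model and no real alignment — the
placements are truth-level, which is exactly what makes the benchmark a
test of the *parsing logic* rather than of a mapper.

**What passing does not show.** Real data add mapping ambiguity,
GC-coverage bias, repeat-induced coverage shifts within one genome,
partially degraded inserts without intact CDSs, and annotation error.
The synthetic benchmark demonstrates that the decision logic recovers
planted structure under the stated depth/composition contrasts; it does
not calibrate false-discovery rates on real assemblies.

## Problem sizes and determinism

The default end-to-end benchmark (~20 Mbp, ~18 M read placements, 100
bootstrap replicates) runs in well under a minute on one CPU; unit and
property tests use smaller configurations of the same generator. All
randomness flows from a single integer seed through per-stage
`SeedSequence` children, so every artifact (FASTA/GFF/TSV and the final
report) is byte-identical across reruns with the same seed. Property
tests run hypothesis in derandomized mode.

## Known limitations

* Binning defaults to k = 2; assemblies with additional well-separated
  genomes (mitochondria, gut bacteria) need `n_clusters="auto"` or an
  explicit k.
* The coverage classifier needs a host depth prior; it is logged in the
  report and should come from the observed host mode in real use.
* Strand is not modelled in the synthetic annotations (all CDSs are
  forward); CAI on real minus-strand CDSs requires reverse-complemented
  input.
* The pathway encodings answer capability questions at
  presence/absence resolution; they are not a metabolic model, and the
  IAA multi-route pooling can in principle accept a chimera of two
  half-routes.
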
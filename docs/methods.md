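# Methods

This note documents the models and procedures implemented in redwoodkit,
the parameter choices behind them, what the synthetic-data generators do
and do not emulate, and the numerical decisions taken where the underlying
protocol left the design open.

## K-mer genome sizing

A haploid sequencing library of a genome of size G at per-copy depth c
produces, for k-mers at a given copy number m, a histogram component of
roughly Poisson shape centered at m·c with area (distinct k-mers) ~ G·f_m/m,
where f_m is the genomic fraction whose 31-mers are identical across m
subgenomes. Base-calling errors create a large mass of low-coverage k-mers
decaying from coverage 1. The estimator:

1. smooths counts with a median of 3 adjacent bins (minimal robustness
   without distorting peak shape; the protocol names no smoother);
2. takes the **error cutoff** as the first local minimum (strictly below
   its left neighbor, not above its right) that has a peak above it to its
   right; monotone-decreasing histograms fall back to cutoff 1 with a
   warning;
3. takes the **main peak** as the argmax of the smoothed series at or above
   the cutoff, ties toward the smaller coverage;
4. **refines the depth** via local count ratios: under Poisson coverage,
   count(x+1)/count(x) = mu/(x+1), so each adjacent bin pair gives an
   estimate (x+1)·count(x+1)/count(x); the median over bins within ±3 of
   the argmax removes the up-to-one-unit grid bias of the argmax (Poisson
   mass at mu−1 exactly equals the mass at mu). The refinement is rejected
   if it leaves ±25% of the argmax;
5. reports **G = T/c** with T = Σ_{X ≥ cutoff} X·count(X). T deliberately
   includes the 2c/3c peaks: dividing by the single-copy depth then counts
   subgenome-shared sequence once per copy, which is what the published
   T/c arithmetic implies. Both the exact quotient and a 1-decimal Gbp
   rounding are reported, since the published figure (~26.5 Gbp) is looser
   than its own quotient (26.37 Gbp).

Residual error mass above the cutoff biases G upward by well under 1% at
the default error decay; the recovery tests bound the total error at 2%
across G ∈ {10^6, 10^7} and c ∈ {30, 57, 100}.

Subgenome peaks are reported as interior local maxima of the smoothed
series within m·c ± 0.25·c for m = 2, 3 — absent peaks are never invented.

## Scaffold curation

**Telomeres.** The tandem unit CCCT[A/C]AA is expanded to its two variants
and scanned exactly on both strands; exact copies are chained into runs
when separated by at most one unit length, with inter-copy bases counted
as mismatches capped at `max_mismatch_frac` (default 0.1) of the run span.
Runs shorter than `min_array_bp` (default 100 bp) are dropped. Orientation
is the strand of the C-rich motif: '+' (C-rich forward) marks a 5' end,
'−' a 3' end. The upstream protocol used tandem-repeat and whole-genome
aligners without printing thresholds; these defaults make planted-truth
recovery exact at toy scale and are all configurable.

**Centromeres.** The bundled 148-bp consensus (shipped as package data and
length-checked at 148 bp) is slid ungapped across both strands; windows at
identity ≥ 0.8 merge into maximal hits. Hits separated by gaps < 250,000 bp
(strict, envelope-to-envelope) merge into centromeric regions by single
linkage — "separated by less than 250 kb" is read literally, so a gap of
exactly 250 kb separates. Merging is idempotent and equals transitive-
closure clustering (checked against a brute-force oracle in tests).

**Splitting.** A scaffold with ≥ 2 centromeric regions is a mis-join. For
each consecutive region pair: internal telomere arrays whose orientation
faces the nearer centromere mark chromosome ends, and the scaffold is cut
at each such array's boundary distal to that centromere (the telomere
stays with its arm). With no qualifying telomere the cut falls at the
midpoint of the largest N-run between the regions; with neither, the pair
is flagged unresolved and left joined rather than cut blindly.
Concatenating the output pieces reproduces the input byte-exactly.

**Statistics.** Contigs are scaffold stretches between runs of ≥ 10 Ns
(the protocol is silent; 10 is the package default). N50 is the length L
such that sequences ≥ L sum to at least half the assembly; NG50 replaces
half the assembly with half a fixed genome size and may be undefined.

**Toy scale.** The generator's chromosomes use 20 kb arms with centromeric
clusters of 2 fragments × 8 copies 1 kb apart, so tests and examples that
curate generated data scale the merge radius to 10 kb. The 250 kb rule
itself is exercised at full scale in the acceptance checks.

## Gene-model filtering

Stages run in a fixed, reported order; each reconciles removed + retained =
input.

1. **Structural**: CDS present, ≥ 100 bp, a multiple of 3, starting with
   ATG, ending in a stop, no internal stop, every exon and intron ≥ 9 bp.
2. **Functional evidence**: a model is kept if it has any of: a similarity
   hit, at least one protein domain, a gene-family assignment. The discard
   sentence in the source protocol is parsed as "lacking all three kinds"
   (retain on any evidence); the alternative reading (a single domain hit
   is insufficient) contradicts the sentence's list structure.
3. **Retroelement**: removed only when retro-domain-flagged AND softmask
   fraction ≥ 0.70 (inclusive). The softmask fraction of a gene is
   lowercase bases within the gene span / span length — the direct reading
   of the 70%-softmasked rule; a CDS-only fraction was rejected as
   narrower.
4. **Mono-exonic**: mono-exonic proteins matching any multi-exonic protein
   at ≥ 0.75 identity over ≥ 0.70 of their own length are removed as
   processed pseudogenes (the gene space is "inflated due to pseudogenes");
   the opposite keep-if-supported reading is available via
   `keep_matches=True`. Identity = matches / aligned columns and coverage =
   aligned query residues / query length, computed from a k-mer-seeded
   local alignment (Biopython PairwiseAligner; match 2, mismatch −1, gap
   −5/−0.5) — the protocol defines neither quantity.
5. **Overlap resolution**: where prediction and transcriptome-derived
   models overlap by ≥ 1 bp of CDS on the same strand, the transcriptome
   model wins (transcriptome evidence doubled measured gene-space
   completeness in the source project). Whether the original resolution
   was strand-aware is unstated; strand-awareness is this package's
   choice.

Transcript-to-genome alignment records are filtered at ≥ 0.95 identity and
≥ 0.95 trimmed coverage (both inclusive) before their models enter the
structural filter.

## Orthogroup analysis

- Expansion/contraction baseline = mean count over non-focal species that
  possess the family (the comparator is undefined upstream;
  mean-of-present is the least assumption-laden choice). Expanded: focal ≥
  2× baseline; contracted: focal ≤ baseline/2. Note the 3:1:1 and 2:1:1
  classes satisfy the expansion rule by construction — the classes
  overlap, and the truth bookkeeping in the generator reflects that.
- Tandem flag: ≥ 2 focal members on one scaffold within 100 kb (no
  threshold is stated upstream).
- Gene-tree candidates: focal copy number ∈ {2, 3}, every reference species
  exactly 1, every member protein strictly > 300 aa and ≥ 75% of the
  family's maximum length (the "75% of maximum" rule is applied per member
  against the family maximum; a pairwise reading is possible but less
  direct), tandem-flagged families excluded, deterministic seeded
  subsampling.
- Copia proximity: a gene qualifies if any Copia interval overlaps or lies
  within 3 kb of the gene span (span boundaries, not TSS — no anchor is
  stated upstream), same scaffold, strand-agnostic.
- The 70%-identity duplication-status clustering is provided as a greedy
  longest-first centroid clusterer with identity = matches / shorter
  length — a documented approximation of heuristic centroid clusterers.

## Divergence estimators

**K2P.** P and Q are transition and transversion proportions over columns
where both sequences have an unambiguous base (pairwise deletion,
mirroring gap-as-ambiguity treatment); K = −½·ln((1 − 2P − Q)·√(1 − 2Q)).
Nonpositive log arguments are reported as saturation, not clamped. When
all substitution types are equally likely (P = Q/2), K2P reduces exactly
to Jukes–Cantor; the tests verify this to 1e-6.

**Counting dN/dS.** Nei–Gojobori (1986) counting replaces the ML codon
model used upstream (reimplementing it was out of scope); the report
schema marks the method as NG86+JC. Per codon, each position's synonymous
fraction is counted over its non-stop alternatives (nonsense mutations
disregarded), so N + S = 3 × codons compared. Codon pairs containing a
gap, ambiguity, or stop in either sequence are excluded. Observed
differences follow minimal mutational pathways, uniformly weighted, with
stop-crossing pathways excluded (falling back to all pathways only when
none survive). Jukes–Cantor correction d = −¾·ln(1 − 4p/3) maps
proportions to rates; p ≥ ¾ is reported as saturation and dS = 0 yields
omega = NA. Under substitutions placed blind to codon structure the
estimator returns omega = 1 within sampling error (tested at 10,000
codons, ±0.1); it agrees with an independent NG86 implementation at the
few-percent level, the residual coming from differing nonsense-mutation
conventions.

## Polyploid-origin topology test

The autopolyploidy signature is operationalized exactly as focal-copy
monophyly — all gene copies of the focal species closer to each other
than to any other species — and nothing more; no inference about
hybridization history beyond the tally is produced. Trees are rooted
strictly on the designated outgroup (midpoint rooting is refused: it can
silently change monophyly calls). If the focal copies are monophyletic,
the sister is the candidate lineage present in the sibling subtree of the
focal clade; both or neither candidate there gives "unclear". An optional
support threshold (default off; 70 when enabled, the common bootstrap
convention) downgrades weakly supported sister calls to unclear — the
upstream tally of "unclear relationships" stated no support rule, so the
rule here is this package's policy.

## Population genetics

Per-site π = 2j(n−j)/(n(n−1)) over non-missing alleles; sites with fewer
than two alleles are skipped. Windows are 1-based, anchored at position 1,
advancing by the step; window π divides the summed site π by the window
length, and empty windows within the covered span are reported at 0.

Weir–Cockerham components a (among populations), b (among individuals
within populations), and c (within individuals) are computed per site for
diploids with observed heterozygosity and unequal sample sizes; missing
genotypes reduce per-population sample sizes rather than dropping the
site. Windowed θ = Σa/Σ(a+b+c) (ratio of sums, the behavior of the
windowed-Fst option in the standard VCF tooling); a mean-of-ratios switch
is provided. Negative estimates are reported as computed. Because the
averaging denominator behind published single-number summaries is
ambiguous, both a windowed mean and a global ratio of sums are emitted.

## Synthetic data: what it does and does not emulate

Generators are deterministic in (seed, config); the master seed fans out
to fixed per-generator substreams so regenerating one data type never
perturbs another. Defaults: 3 chromosomes + 1 fused mis-join with 20 kb
arms, 30-copy telomere arrays, 2 × 8-copy centromere clusters at 3%
divergence; histograms at G = 10^7, c = 57, sharing fractions
(0.6, 0.25, 0.15), geometric error decay 0.7; a 31-gene annotation set
(12 valid multi-exonic, 3 valid mono-exonic, 6 broken, 5 retroelement at
85% masking, 5 pseudogenes at 80% protein identity); orthogroup matrices
over 6 species with all planted classes; 50 trees per scenario; 2
populations × 30 diploids × 20,000 Balding–Nichols loci at F = 0.05.
Problem sizes are toy-scale by design — large enough for the statistical
recovery bounds tested, small enough to regenerate everywhere.

Not emulated: read-level sequencing (no base errors, no coverage
variation along the genome), real repeat landscapes (telomere/centromere
arrays are planted exactly, background sequence is i.i.d. uniform),
alignment uncertainty (gene trees are generated topologies, not inferred
ones; NNI noise is a topological proxy for inference error), linkage
disequilibrium (Balding–Nichols loci are independent), and selection.
Passing tests therefore demonstrate the correctness of the *rules and
estimators* under their stated models, not robustness to every artifact
of real data.

## Known limitations

- The telomere scanner chains exact motif copies; arrays diverged beyond
  ~one corrupted copy per chained run fragment into multiple hits (still
  merged downstream when they pass the length threshold).
- The centromere scan is ungapped; indel-diverged copies lose identity
  linearly with offset. At the 0.8 default threshold this is acceptable
  for the ~3% divergence regime it targets.
- NG86 counting underestimates rates at high divergence relative to ML
  codon models; it is intended for the low-divergence regime (dS ≲ 0.3)
  where the upstream comparisons live.
- The Fst estimator assumes biallelic sites; multi-allelic records are
  skipped at parse time with a warning count.
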
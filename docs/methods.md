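# Methods

## Coordinate and record model

All internal coordinates are 1-based inclusive (VCF convention); BED depth
inputs (0-based half-open) are converted on read. An SV record carries
`pos`, `end` (`end == pos` for insertions), type, signed `svlen` as the
caller reported it, and a derived `abs_len = |svlen|` (falling back to
`end − pos + 1` for span types without SVLEN). When a caller VCF carries
both END and an inconsistent SVLEN, END wins: END is positional ground
truth in caller output, while SVLEN conventions differ between tools.
(For the same reason the VCF writer emits text directly: htslib-based
writers re-derive END from SVLEN under the newer VCF convention at
serialization, which would silently overwrite an explicit END.) Records
whose coordinates cannot be resolved are kept but demoted to type OTHER,
which the filter removes — parsing never silently drops input.

## Record filter

Defaults: QUAL ≥ 20, read support ≥ 4, PRECISE only, genotype not `./.`
or `0/0`, type in {DEL, INS, INV, DUP}, `abs_len` ≥ 50 bp. All thresholds
are strict in the printed direction (equality passes). The 50 bp floor is
applied both at filtering and inside the merge predicate; applying it in
both places is redundant but harmless, and keeps each stage individually
safe. Records lacking a support field pass the support rule in the
default lenient mode (callers name the field differently); the reference
pipeline uses strict mode for male/offspring callsets, whose caller
always reports support. The composite maternal callset is never
record-filtered — it serves only as a subtraction reference, where extra
sensitivity is conservative.

The maternal composite set is built by plain concatenation of the
per-caller callsets without deduplication: its only use is as a
subtraction reference, where duplicates are harmless, and concatenation
preserves the published per-caller count arithmetic.

## Match predicate and clustering

Two records match iff same chromosome, same type (when type agreement is
on), compatible strands (unknown strand matches anything — most DEL/INS
records carry none, and requiring strands would void all matches), and
both breakpoints within `max_dist`: `|Δpos| ≤ d` **and** `|Δend| ≤ d`.
For insertions `end == pos`, so the predicate degenerates to
insertion-point distance. SV length similarity is deliberately not part
of the predicate: the six positional merge parameters used throughout
(`max_dist, min_support, type, strand, size_estimate, min_size`) have
`size_estimate = 0` in every analysis stage. Records below `min_size`
never match.

Merging takes connected components of the match graph over the
position-sorted record pool (a sweep bounds candidate pairs by
`Δpos ≤ max_dist`, which is necessary for a match; union-find gives the
components). Determinism: records are globally sorted by
(chrom, pos, end, type, sample) and the representative is the first
member. Subtraction/intersection come in two modes — `cluster` (member of
a component containing a reference record; the default, mirroring
cluster-based merge tools) and `pairwise` (direct O(n²) match; the
independent oracle). Cluster-mode removal is always a superset of
pairwise removal; on sparse data (intra-callset spacing > 2·max_dist) the
two coincide, which the property tests exploit.

## DSV detection

Maternal subtraction is iterated until a pass removes nothing (or
`max_iterations = 10`). Cluster-mode subtraction normally certifies the
fixpoint on its second pass; the loop is kept because it is the faithful
reading of the procedure and guards against pairing-heuristic
differences. The iteration count includes the certifying no-op pass.

The coverage screen keeps records whose **mean** per-base maternal depth
over `[pos, end]` (point depth for insertions) is ≥ 4. Mean was chosen
over min because it is robust to ragged interval ends and matches
windowed-depth inputs; a `min` statistic is available via
`DSVParams(coverage_stat="min")`. Reported DSV fractions are relative to
the sample's filtered record count.

## MSSV detection

Both the offspring and the male DSV sets are pre-filtered to
`max(abs_len, span) ≤ 10 kb` — measuring on the max covers long
insertions (span 1 on the reference) and imprecise deletions
symmetrically, and applying it to both sides keeps the intersection
well-defined. The intersection uses the tight 100 bp window. Common-MSSV
detection pools the per-offspring MSSV records, clusters them under the
same window, and keeps clusters with ≥ 9 distinct offspring; the
per-chromosome tally uses cluster representatives.

## Region annotation

Category precedence follows the standard gene-centric convention, most
severe first: exonic (CDS overlap) > splicing > UTR5 > UTR3 > intronic
for coding transcripts; ncRNA_exonic > ncRNA_splicing > ncRNA_intronic
for non-coding; any gene-body hit beats a flank hit; within 2 kb of a
gene on its own-strand 5′/3′ side → upstream/downstream (both, from
different genes → upstream_downstream); otherwise intergenic. Across
multiple transcripts/genes the most severe category wins and `genes_hit`
lists every gene contributing it. Splicing means within 2 bp of an
intron/exon boundary without touching an exon. Exonic consequence typing
is sequence-free: INS/DEL are frameshift iff `abs_len mod 3 ≠ 0`
(inversions/duplications are typed "other" with a warning). Exon overlap
in a coding transcript outside annotated CDS/UTR intervals falls back to
exonic rather than intronic.

## Synthetic cohort generator

The generator emulates the study design at callset level: maternal SV
loci drawn over a small genome; each male = maternal loci + a private
male-specific set (the heterologous male's scaled 50-fold); each
offspring = maternal loci (dropout 2%, breakpoint jitter σ = 20 bp) +
each paternal locus independently with the leakage probability + Poisson
de-novo and false-positive records. Maternal coverage is a constant 9×
track with optional zero-depth holes. Every record is logged in a sidecar
truth table (maternal / male_specific / paternal_transmitted / denovo /
false_positive); truth never enters the VCFs.

Default scale (the package's own choice of desk-scale problem sizes):
4 chromosomes × 5 Mb, 1,000 maternal loci, 100 male-specific loci
(heterologous: 5,000), de-novo rate 80 and false-positive rate 5 per
offspring, 9 offspring per male, DEL/INS-dominant type mix
(0.48/0.48/0.02/0.02), log-normal lengths (median ≈ 300 bp, clipped to
[50, 8000] bp). Leakage defaults: 0.2 for the homologous cohort and
0.001 for the heterologous one, which place the MSSV/DSV fractions near
the homologous (≈ 0.2) and heterologous (≈ 0.05) regimes of the real
study — a demonstration of the same qualitative behaviour, not a claim of
reproducing the real counts. Quality fields are sampled above the filter
thresholds by default (qual = 20 + Exp(15), support = 4 + Poisson(5)), so
truth-based recovery statements are about the detection stages, not about
random sub-threshold draws; filter behaviour is tested on explicitly
constructed records.

Jitter perturbs breakpoint positions while the emitted SVLEN keeps the
underlying variant's length — mirroring callers whose length estimate
comes from the read consensus while breakpoint placement carries
alignment uncertainty. Re-reading such records exercises the END-wins
reconciliation path and keeps `abs_len` stable under noise (a record can
never jitter itself below the 50 bp floor).

**Locus spacing.** Distinct loci are placed with a minimum start-to-start
spacing of 2,100 bp — beyond the 1,000 bp DSV window even after jitter —
so records of *different* origin can never be chained into one merge
cluster, while copies of the *same* locus across samples always cluster.
This is what makes exact zero-noise recovery well-defined: without noise,
DSV detection returns exactly the de-novo + transmitted records and MSSV
detection exactly the transmitted ones. Only start spacing is enforced;
a long SV's footprint may overlap the next locus start, which is
irrelevant to matching (a match requires both `pos` and `end` within the
window). Placement that cannot satisfy the spacing raises an error; the
zero-noise suite that uses 500 male-specific loci (hence 25,000
heterologous ones) therefore runs on an enlarged 4 × 20 Mb genome.

The toy gene model tiles ~40 genes/Mb (3–5 exons each, 80%
protein-coding with annotated CDS/UTRs, 15% lncRNA), making roughly 80%
of simulated MSSVs gene-associated — a gene-dense regime comparable to
compact teleost annotations.

**What the simulator does not model:** sequence content, read-level
evidence, caller-specific genotyping errors, SV length/type biases beyond
the configured mix, clustered or recurrent breakpoints, and real genome
architecture (repeats, segmental duplications) that drives false matches
in practice. Passing recovery tests therefore validates the pipeline's
set logic and window arithmetic, not caller accuracy on real data.

## Numerical and degenerate-input choices

- All thresholds strict as printed; equality is retained everywhere
  (QUAL 20, support 4, depth 4.0, span 10,000, offset `max_dist`).
- Empty callsets/reference sets are legal everywhere: subtracting an
  empty reference is the identity, intersecting with it is empty,
  summaries of empty callsets are zero.
- Fractions with zero denominators are reported as 0.0.
- Re-running any stage on identical input is bit-identical: stable global
  sorts, seeded RNG, no hash-order dependence.
- The simulator's RNG is a single `numpy` generator consumed in a fixed
  order; the gene model uses a generator derived from `seed + 7` so
  cohort and annotation randomness do not interleave.

## Known limitations

- Breakends/translocations are out of scope (parsed as OTHER, filtered).
- Cluster-mode subtraction can remove a target record that matches no
  maternal record directly but chains to one through other target records;
  this is the intended merge-tool semantics, and the pairwise oracle mode
  quantifies the difference on request.
- The coverage screen uses windowed mean depth; a deletion fully inside a
  short coverage hole that is averaged away by flanking depth would pass.
- Annotation picks one category per record; a 10 kb SV spanning several
  genes reports only the most severe context.
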
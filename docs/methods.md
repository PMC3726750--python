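# Methods

`estqc` evaluates genome-assembly quality with transcript evidence: it
treats a genome's EST library as an independent witness of what the
assembly should contain, and reports how much of the genome was assembled
(integrity), how much of the transcript evidence the assembly can account
for (accuracy), and how evenly that evidence spreads along the chromosomes
(segment coverage). This note records the models, parameter choices and
numerical conventions behind each stage, and what the synthetic studies do
and do not demonstrate.

## Metrics

* **Integrity** = 100 x assembled size / estimated genome size, written
  CS/GS for chromosome-level and SS/GS for scaffold-level assemblies. The
  genome-size estimate is an external input (flow cytometry, k-mer
  estimate); values above 100% are reported with a warning, not clamped.
* **Accuracy** = 100 x matched ESTs / selected clean ESTs (mEST/sEST). An
  EST is *matched* when its best spliced placement reaches both the
  identity and EST-coverage thresholds (defaults 0.95 and 0.50). Only the
  single best hit per EST counts, so each EST contributes once.
* **Segment coverage** = the percentage of 0.1 Mb (100,000 bp) segments
  touched by at least one matched EST's exon blocks, pooled across all
  chromosomes of a species (per-chromosome values are also emitted).
  A boundary-spanning exon block counts in every segment it overlaps.
* **Quality level** (chromosome-level assemblies only), evaluated in order
  with first match winning:
  1. integrity > 85 and accuracy > 85 and segment coverage > 70;
  2. integrity > 85 and accuracy > 85 and segment coverage > 30;
  3. integrity > 80 and accuracy > 80;
  4. otherwise.
  Published group definitions of this kind overlap and leave holes (e.g.
  accuracy 82% with coverage 75%); the ordered evaluation with level 4 as
  the residual class reproduces all published assignments while remaining a
  total function.

Percentages are rounded half-up to two decimals (`decimal.Decimal`, not
binary floating point, so printed table values reproduce digit for digit).
Group averages are unweighted means of the already-rounded per-species
percentages — the convention the published survey tables use — rather than
means of exact ratios.

## Two-round EST selection

Libraries are sampled in two rounds keyed to the library total N:

* round 1: N > 10,000 keeps 50% of accessions, otherwise all;
* round 2 (after cleaning): N > 100,000 keeps 1%, N > 10,000 keeps 10%,
  otherwise all clean ESTs.

Both percentages apply to the *library total* N, not to the clean-pool
size (the worked sizes 1,529,700 -> 15,297 and 10,855 -> 1,086 require
this); the draw is uniform without replacement, capped at the pool with a
logged warning. Sample sizes round half up (10% of 10,855 is 1,086).
Boundaries are strict: N of exactly 10,000 or 100,000 falls to the lower
tier — the tier wording uses strict inequalities and the boundary never
occurs in practice.

## Cleaning

Vector/adaptor clipping runs first, then contaminant screening; residues
are never altered except by terminal trimming, and every input EST gets
exactly one recorded outcome.

Similarity search is exact k-mer seeding (k = 12) with edit-distance
verification: seeds shared with a reference are joined into an EST
segment, and the segment's identity is 1 − d/len where d is its edlib
edit distance to the best placement inside the reference. Because a
candidate needs seed support along most of the EST to reach the coverage
threshold, isolated background 12-mer collisions (expected about one per
EST against a 60 kb reference set) cannot trigger a removal.

Thresholds (none are published for this step; these are conventional
screening practice and all sit in `CleanParams`):

| parameter | default | meaning |
|---|---|---|
| vector_identity_min | 0.95 | identity of a vector hit |
| vector_hit_min | 20 bp | minimum vector hit length |
| terminal_window | 50 bp | a hit touching this window is terminal |
| min_clean_length | 100 bp | survivor length after trimming |
| screen_identity_min | 0.90 | contaminant-hit identity |
| screen_coverage_min | 0.80 | contaminant-hit EST coverage |

A confident vector hit in the EST interior marks a chimera and removes the
EST (reason `internal_vector`, logged distinctly). Score ties between
screening classes resolve by the fixed precedence rRNA > chloroplast >
mitochondrial > bacterial, so reports are deterministic.

## Spliced alignment

The aligner follows the est2genome model: best local alignment in which
the genome side may open introns at a flat penalty, discounted when the
intron is flanked by GT..AG; ordinary gaps cost a linear per-base penalty.
Scoring defaults are that program's documented defaults: match +1,
mismatch −1, gap −2/base, intron 40, GT..AG intron 20, intron length
30–100,000 bp.

The dynamic program has two ideas: a standard local-alignment recurrence,
plus an intron transition that, at column j, takes the best previous-row
cell in the sliding window [j−1−max_intron, j−1−min_intron] minus the
intron penalty. Two monotonic deques (all donors; GT donors) make each row
O(n), so the whole fill is O(mn) regardless of intron length; the kernel is
numba-compiled. Identity is matches over aligned EST bases; coverage is
aligned EST bases over EST length; N pairs score as mismatches and never
count as matches.

Determinism: among equal scores the earliest end cell in row-major order
wins; the traceback prefers diagonal, then the smallest intron donor
(spliced before plain), then target-gap, then EST-gap; across windows and
strands, ties break by lowest target id, smallest target start, then the
+ strand.

Strand handling reverse-complements the *EST* and always reads splice
sites on the forward target. This makes strand symmetry exact (aligning
the reverse complement flips the strand label and preserves score and
blocks), at a known cost: a minus-strand gene's introns read CT..AC on the
forward target, so they pay the plain intron penalty, and the aligner may
shift a junction a few bases toward a chance GT..AG at the price of a
mismatch or two. Matched/unmatched decisions are unaffected (identity
stays well above threshold), and the convention keeps the scoring function
a pure function of the forward target, which the spliced/plain invariants
rely on.

Chromosome-scale targets are handled by exact k-mer seeding (k = 12):
positions sharing at least `min_seed_hits` k-mers, clustered at gaps up to
max_intron, define candidate windows extended by max_intron on both sides;
over-represented k-mers (more than 64 occurrences, i.e. repeats) are
skipped as seeds. On assemblies totalling at most `full_scan_max`
(200,000 bp) every record is additionally scanned in full on both strands,
so the seeded and exhaustive paths coincide exactly there — this is the
regime the aligner-oracle test suite exercises. The exhaustive entry point
refuses targets beyond ~200 kb (and DP matrices beyond ~200M cells)
rather than silently thrashing memory.

For synthetic studies, `synthetic_align_params` scales the search to the
simulated genome: max_intron = max(2,000, 5 x the simulated intron
maximum) and min_seed_hits = 8 (a true placement of a 150+ base EST shares
hundreds of k-mers; eight suppresses windows built from background
collisions). Scoring is never changed.

## Repeat and GC profiling

Three self-contained detectors cover the three reported repeat classes;
none needs a curated library, and none counts N runs (gaps are assembly
artifacts, not repeats):

* **Simple repeats** — exact maximal tandem arrays of primitive units of
  1–6 bp with at least `min_copies` = 4 full copies spanning
  `min_length` = 20 bp; rotated reports collapse to the lexicographically
  smallest rotation. The detector agrees exactly with a brute-force
  enumeration oracle in the test suite.
* **Low complexity** — DUST-style windowed composition entropy: 64 bp
  windows at step 16, flagged at <= 1.0 bit, merged when touching; windows
  more than half N are skipped.
* **Interspersed** — positions covered by canonical (strand-symmetric)
  13-mers occurring >= 10 times genome-wide, runs merged across gaps
  < 50 bp, intervals shorter than k dropped. This reports where dispersed
  multi-copy families sit, not their taxonomy.

Defaults were chosen to detect the planted families of the simulation
reliably while flagging under 2% of repeat-free control sequence; all are
arguments.

Per-segment repeat profiles count an interval in every segment it
overlaps and split its length by overlap, so summed per-segment lengths
conserve the total masked length. GC is reported in two modes:
`n_inclusive` (G+C over total length, the default — N-rich assembled
sequence dilutes the value, which is how whole-chromosome averages far
below 30% arise) and `n_exclusive` (G+C over A+C+G+T, undefined on all-N
input). In the default mode the whole-record value equals the
length-weighted mean of segment values exactly.

## The synthetic study

The generator produces the regime the pipeline is built for, with one
root seed and a named RNG stream per stage (adding a stage never perturbs
another stage's draws):

* multi-chromosome genomes (default 5 x 400 kb) with per-region GC targets
  (50 kb regions drawn from {0.30, 0.38, 0.45}) and N-gap runs of mean
  5 kb totalling 2% of the genome;
* 200 spliced genes of 2–5 exons (80–300 bp) and introns of 30–300 bp,
  with canonical splice dinucleotides written at the intron ends of the
  transcribed strand; 80% of gene midpoints are drawn from two
  edge-concentrated triangular distributions (the rest uniform),
  reproducing the empirical pattern that transcript evidence piles up
  toward chromosome ends;
* planted repeats of all three classes (3 interspersed families of 20
  exact 500 bp copies; biased-composition tracts; primitive-motif tandem
  arrays);
* derived assemblies that delete `drop_fraction` (default 0.20) of each
  chromosome as blocks of 10–30 kb (recorded in original coordinates), or
  additionally fragment chromosomes into scaffolds around a 50 kb mean
  with a 5% unplaced share;
* EST libraries (default 2,000 reads of 150–500 bp) as contiguous slices
  of spliced transcripts with 1% substitution noise by default, plus
  vector-flanked reads (25–60 bp flanks) and contaminant reads drawn from
  synthetic rRNA/bacterial/organelle references.

Deliberate simplifications, and what they imply about test evidence:
substitutions only by default (an indel rate exists for stress tests), so
the expected identity of a genic EST is analytically 1 − error rate;
repeats and N gaps are planted in intergenic sequence only, so planted
ESTs stay exact spliced substrings and contaminant screening recall is
attributable to the screen, not to repeat coincidences; deletion blocks
are wider than any gene, so an EST hit by a deletion keeps one contiguous
flank and its matched/unmatched outcome is predictable from the surviving
fraction alone (`matchable_fraction`). Passing the recovery tests
therefore shows the pipeline measures what was planted under these
conditions; it does not show robustness to indel-heavy reads, transcribed
repeats, polyploidy or heterozygosity, none of which are modelled.

Problem sizes used in the checked studies — a 2 Mb genome, 2,000 ESTs,
500 aligner-oracle pairs, 200 oracle sequences for the repeat detector —
are the package's chosen desk scale: large enough that binomial error
bands are a few percent, small enough to iterate on.

## Known limitations

* The GT..AG discount applies on the forward target only (see strand
  handling above); CT..AC introns of minus-strand genes score as plain
  introns.
* The interspersed detector is k-mer exact: diverged repeat copies below
  ~92% identity at k = 13 lose coverage.
* `matchable_fraction` assumes substitution-free ESTs and deletion blocks
  wider than genes; outside that regime it is only an approximation.
* The est2genome text output format is not reproduced; hits are exported
  as BED12 and TSV.
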
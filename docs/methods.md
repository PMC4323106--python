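# Methods

This document records the statistical model behind each analysis, the
default parameters and why they were chosen, what the synthetic-data
generator does and does not establish, and the numerical choices that a
user re-implementing or extending the package should know about.

## 1. Read model and alignment (`sio`)

Reads are counted RNA sequences (internally U; converted to T for genome
comparison). Size selection keeps 15–33 nt inclusive, matching standard
small-RNA gel selection. `collapse_unique` keeps one count-1 read per
distinct sequence while retaining the original total as
`total_input_count` so reads-per-million stay computable.

`align_exact` reports a read iff its sequence occurs exactly in the
genome on either strand — the behaviour of a perfect-match one-best
short-read aligner. Among multiple placements, the lexicographically
smallest `(contig, start, strand)` wins with `+` ordered before `-`;
the number of placements is retained as `n_occurrences`. The index is a
15-mer hash (15 = the minimum retained read length, so every candidate
placement is seeded). Ties are broken deterministically rather than
randomly so whole-pipeline runs are byte-identical; the statistics
computed downstream (length/5′-nt profiles, overlap histograms) are
placement-invariant in expectation, so the tie-break rule does not bias
them.

## 2. Protocol differencing (`profiles`)

Each library is reduced to a (length, 5′ nucleotide) fraction table.
For the triphosphate call, each cell's enrichment is

    (f_indep + ε) / (f_dep + ε)        ε = 10⁻³

and a cell is called triphosphorylated when enrichment ≥ 2.0 **and**
f_indep ≥ 0.01. Rationale:

- ε regularizes empty cells; 10⁻³ is below any abundance of interest
  (1% floor) but large enough that a cell absent from both libraries
  has enrichment exactly 1.
- The 1% abundance floor suppresses calls on rare cells where the
  ratio is sampling noise; at the 100,000-read scale used throughout,
  1% ≈ 1,000 reads, far above multinomial fluctuation.
- Enrichment ≥ 2 is deliberately coarse: RdRP products are essentially
  invisible to 5′-monophosphate-dependent ligation, so true cells show
  enrichments of 10–100×; 2× only has to separate signal from unit
  ratios.

The periodate `protection_ratio` divides a cell's fraction after
periodate treatment by its fraction in the untreated control, requiring
the library pair to actually carry those treatments; a class is called
protected (2′-O-methylated) above 0.5.

## 3. piRNA analyses (`pirna`)

**Upstream motif.** For every aligned candidate read (default: 21 nt,
first nucleotide U), the 60 nt immediately upstream of the 5′ end are
extracted strand-awarely; windows truncated by a contig edge are
skipped and counted. An 8-column ZOOPS (zero-or-one-occurrence per
sequence) EM mixture with a 0-order background is fitted; restarts seed
from the 50 most over-represented 8-mers, the best-likelihood model
wins, and the run is deterministic given the seed. Information content
is the Kullback–Leibler divergence of the PWM from background. Eight
columns match the core upstream motif width; ZOOPS (not OOPS) because
only ~90% of planted loci carry the motif and real loci are similarly
imperfect.

**Cluster density.** Reads are binned into fixed windows per contig;
the flagged fraction is the proportion of reads in windows whose
density exceeds `threshold_factor` (default 10) × the mean window
density. The pipeline uses `window_size=2000` on its 100 kb contigs.
The 10×-mean rule is scale-sensitive: for a fixed planted architecture
the flagged fraction falls as windows grow (measured on 50 kb test
contigs: 0.50 at 1 kb windows, 0.22 at 2 kb, 0.0 at 5 kb), because
wider windows dilute clusters toward the mean. Window size should be
chosen ≈ cluster span relative to genome size; tests use 1 kb windows
on their 50 kb fixtures for the same windows-per-genome ratio as the
pipeline. `compare_density` contrasts two density profiles by a
two-sample KS test on per-window densities.

**Ping-pong.** For every opposite-strand pair of alignments whose 5′
ends overlap by 1..30 nt, the overlap length is tallied
(count-weighted); each unordered pair is counted once. For 10 nt
overlaps, the identity of position 10 of the 5′-most (plus-strand)
read is recorded, giving `tenth_a_fraction`. The caller restricts the
alignment set (the pipeline and acceptance runs use piRNA-length reads,
21 nt) because ping-pong is a piRNA-pathway signature; including all
lengths admits Dicer-duplex geometry into the histogram.

## 4. Repeat siRNA analyses (`tesirna`)

Reads are assigned to the repeat annotation interval with the largest
overlap, requiring > 50% of the read inside the repeat; ties and
sub-threshold overlaps are dropped. Orientation is read strand vs
annotated repeat strand. `strand_bias` is an exact binomial test
against 0.5. `class_bias_2x2` is the Yates-corrected 2×2 chi-squared
(cross-checked against `scipy.stats.chi2_contingency(correction=True)`),
with the small-deviation clamp to 0 when the corrected |deviation| is
negative. `overhang_signature` tallies, for opposite-strand pairs in
the Dicer length range, the two 3′ overhangs implied by the pair
geometry; a planted 2 nt overhang appears as a mode at +2.

## 5. Protein conservation and jackknife (`homology`)

Local protein alignment is BLOSUM62 with affine gaps (open 11,
extend 1) via Biopython's `PairwiseAligner`; the test suite checks it
cell-by-cell against an independent three-state DP oracle. Raw scores
convert to bits with the standard gapped Karlin–Altschul constants for
BLOSUM62/11/1, λ = 0.267 and K = 0.041:

    bits = (λ·raw − ln K) / ln 2,    E = m·n·2^(−bits) (database scale)

The conservation matrix stores best-hit bits normalized by query
length; presence is `normalized ≥ 0.18`. That threshold sits well
above the score an unrelated length-200 decoy attains (all 30 decoys in
the test suite score < 0.18 against a length-matched query) and well
below an exact self-hit (≈ 0.5–0.6 bits/aa for typical compositions).

The jackknife removes a fixed fraction (default 10%) of proteins
uniformly without replacement, `reps` times (default 10,000), and
recounts how often the outgroup's presence count exceeds the minimum of
the comparison species' counts ("incongruity inverted"). The estimated
p is `hits / reps`; when no resample inverts the ordering the result is
reported as the bound `p < 1/reps` (flagged `p_is_bound`), never as 0.
The resampling loop is a vectorized boolean-mask × presence-matrix
product; an exhaustive enumeration oracle validates it at small n.

The WAG amino-acid model supplies the evolved-decoy machinery:
R = S·diag(π) with zero row sums, normalized to one expected
substitution per site; P(d) = expm(R·d). Detailed balance, equilibrium
recovery at large d, and the expected changed-site fraction are all
tested. `spike_in_test` evolves a query to divergence d and asks
whether its best hit still beats the best unrelated decoy.

## 6. Methylation (`meth`)

Cytosine contexts are CG / CHG / CHH, classified strand-awarely
(minus-strand context read on the reverse complement); sites whose
context window is truncated by a contig edge are dropped. Per-site
methylation level is unconverted/total bisulfite reads; uncovered
sites are NaN and excluded. A site is "methylated" when its level is
strictly greater than the 0.05 cutoff (exactly 5% does not count).
`repeat_enrichment` is a one-degree chi-squared of each repeat class's
methylated-site count against the genome-wide rate, reporting only
classes with covered sites and flagging direction
(observed > expected). `srna_association` compares per-gene small-RNA
densities (distinct reads, or count-weighted) between methylated and
unmethylated gene bodies by Mann–Whitney U with `method="exact"` when
sample sizes permit (scipy falls back to the asymptotic method in the
presence of ties), requiring ≥ 3 genes per group.

## 7. miRNA conservation tiers (`mircons`)

The seed is nucleotides 2–8. Tiers are cumulative, each requiring
≥ 1 RPM of supporting reads:

- tier 1: seed match only;
- tier 2: seed match and ≤ 3 mismatches over the full mature sequence;
- tier 3: ≤ 1 mismatch over the full mature sequence.

These cutoffs are declared substitutes for homology tiers whose exact
published definitions are not reproducible here; their property that
matters — tier fractions are non-increasing with stringency and decay
with evolutionary distance — is what the correlation analyses consume.
`distance_correlation` and `dev_expression_correlation` are Spearman
rank correlations (scipy), raising `UndefinedCorrelationError` on
constant input rather than returning NaN.

## 8. The generator (`synth`) — scope and guarantees

`make_genome` builds uniform-random contigs and then plants, in order:
repeat families (divergent copies of a consensus at a configured
per-site divergence), genes, piRNA loci (5′ T at the locus position and
the `CTGTTTCA` motif at offset −47..−40 on the locus strand, 90% of
loci; loci concentrated in 4 clusters of 2 kb by default), miRNA loci,
and ping-pong locus pairs (the secondary-read position 10 is adenine
with probability 0.8). Planting is collision-checked: every written
position is recorded, and a locus is only placed where all positions it
writes are free of repeats and earlier loci, with a bounded retry
budget (exhaustion raises rather than silently corrupting truth
labels). 22G and ping-pong read sampling selects genomic positions
whose existing base matches the class 5′ nucleotide instead of mutating
the genome.

`simulate_library` draws class counts from a multinomial over
`class_weights` and renders protocol effects faithfully: a
5′-monophosphate-dependent protocol drops triphosphorylated reads
(22G), periodate drops everything without 2′-O-methylation (keeping
only the piRNA-like classes). Truth labels (class per read id) are
emitted alongside. Bisulfite data draw per-site levels from beta
distributions around `meth_repeat_level` (0.6) vs background (0.02)
with concentration 30, and binomial converted counts at `coverage` 50.

**What passing recovery tests establish:** the analysis code computes
the intended statistic and recovers parameters *from data generated
under its own assumptions*. They do not establish robustness to
sequencing error (the generator emits error-free reads), multimapping
ambiguity beyond exact duplicates, partial protocol efficiency, or
genome misassembly. The generator shares no code with the analyses —
class geometry is written into sequence and rediscovered via alignment
— but it is a model organism, not a benchmark of biological truth.

## 9. Determinism and seeds

All randomness flows from integer seeds through
`numpy.random.SeedSequence([seed, *salt])`, with a distinct salt per
operation, so stages are decoupled (re-running one stage never shifts
another's stream) and whole runs are byte-identical across thread
counts and platforms. Seeds must be below 2³¹.

## 10. Limitations

- Exact-match alignment only; no mismatch tolerance, so divergent-copy
  repeat reads that acquire substitutions are unalignable (the
  generator samples 22G reads from actual genome sequence, so this
  does not distort the planted recovery, but it would on real data).
- The EM motif finder fits one fixed-width motif with a 0-order
  background; it will not find multi-part or variable-width motifs.
- The cluster-density flagged fraction depends on window size relative
  to genome and cluster scale (see §3); it is a descriptive statistic,
  not a calibrated test.
- Karlin–Altschul constants are the standard gapped BLOSUM62/11/1
  values; scores for other matrices/penalties would need new constants.
- miRNA tier cutoffs are substitutes (see §7).
- The Mann–Whitney exact method silently degrades to asymptotic under
  ties (scipy behaviour); with the default distinct-read densities ties
  are rare but possible at very low coverage.
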
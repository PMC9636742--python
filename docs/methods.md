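# Methods

## The discovery model

`epilinc` treats an aberrantly methylated single CpG (an epimutation)
as a landmark for lncRNA discovery. The pipeline has three statistical
components: a differential methylation caller, a positional filter
against the annotation, and a coding-potential cascade. Each is
described below with its assumptions and defaults.

### Differential single-CpG calling

Per site, reads are pooled within each group and the 2×2 table
[methylated, unmethylated] × [case, control] is tested with a two-sided
Fisher exact test (sum-of-small-p rule). The effect size is the pooled
fraction difference Δ. Pooling treats reads within a group as
exchangeable: it is the simplest defensible statistic at the low
per-sample coverages of targeted bisulfite capture, and it is exact —
no asymptotic approximation — but it does **not** model biological
variability between individuals. When each individual's methylation
level is itself dispersed (beta-binomially), the pooled test is
anti-conservative; a per-sample beta-binomial likelihood ratio would
handle that and is deliberately out of scope. The test suite makes this
boundary explicit: calibration is asserted under the exchangeable null
(one Beta(5,5) level per site shared by both groups), where the test is
valid and conservative, while the overdispersed generator is used as a
harder recovery stressor.

The exact test is computed from a cached log-factorial table,
vectorized over sites, with tables whose probability is within a 1e-7
relative tolerance of the observed one counted as ties (the same
convention as `scipy.stats.fisher_exact`, which serves as an
independent cross-check in the tests alongside an exact-rational
enumeration oracle). Adjustment is Benjamini–Hochberg across all tested
sites (`statsmodels`). Sites pass with |Δ| ≥ `min_abs_delta` (default
0.3) and q ≤ `alpha` (default 0.05), ranked by |Δ| descending with ties
broken by smaller p then genomic position; determinism of the whole
output is tested byte-for-byte.

Coverage QC keeps sites where at least `min_fraction_samples` (default
0.5) of the samples in **each** group reach `min_cov` (default 5)
reads. These two defaults are declared choices — standard bisulfite
practice, not derived from data. Missing cells are coverage 0, never
imputed; the exact test handles empty cells natively. CpGs on opposite
strands are kept separate by default (`--merge-strands` sums minus-
strand counts onto the plus-strand cytosine); the non-destructive
default loses no information.

### Primer-region search (MS-HRM follow-up)

For wet-lab validation by methylation-sensitive high-resolution
melting, the caller enumerates every amplicon window of length
`min_len..max_len` (defaults 80–250 nt) that fully contains the anchor
CpG dinucleotide, counts the CG dinucleotides fully inside, and returns
windows with `min_cpgs..max_cpgs` (defaults 2–25), most CpGs first then
shortest: more CpGs per amplicon give a larger melt-curve separation
between methylated and unmethylated templates. Primer thermodynamics
(Tm, dimers) are out of scope.

### Anchoring and positional classes

A transcript is anchored to a call when the site lies inside its
genomic span (default) or within `anchor_window_nt` of it; the window
default of 0 reflects that reads are expected to map directly onto the
epimutation. Distances use half-open arithmetic with the convention
that the first base past a span is at distance 1.

Against the annotation (gene spans = union of each gene's transcript
spans) a candidate is `sense_overlap` when one of its exons overlaps a
same-strand gene span, `antisense_overlap` when only opposite-strand
span overlap exists, `flank_proximal` within `flank_nt` (default 1000)
of the nearest gene, else `intergenic`; the four classes are mutually
exclusive and exhaustive, and the nearest gene and distance are always
reported (∞ for an empty annotation).

The 1-kb flank filter removes candidates overlapping gene spans
extended ±1000 nt. Read literally and strand-blind, that criterion
would also remove any antisense lncRNA overlapping its host gene —
contradicting the very configuration the pipeline is designed to find —
so an antisense exemption (candidates whose only extended-span overlaps
are opposite-strand are retained) is ON by default and configurable.
Cascade order is immaterial to the verdict because every criterion is
always evaluated and reported; nothing short-circuits.

### Coding-potential cascade

Criteria and defaults: length > 200 nt (strict); longest ORF < 400 nt
counted inclusive of the stop codon (no ORF passes); PFAM best E-value
> 1e-5 or no hit (table ingested, criterion skipped when absent — a
skipped criterion is reported as such, never as a pass); external
noncoding score > 0.5 (likewise ingested/skipped); coding probability
vs the classic 0.375 cutoff.

On the probability direction: a cutoff of 0.375 under the CPAT
convention separates *coding* (above) from *noncoding* (below), so a
filter that screens **for** lncRNAs must keep transcripts **below**
it. The default does exactly that and logs a prominent note; the
`--cpat-direction literal` flag restores the inverted comparison for
strict reproduction of pipelines that state the criterion the other
way round.

The built-in probability model is CPAT-style: logistic regression
(scikit-learn, features standardized, C = 100) on [longest ORF nt, ORF
coverage, Fickett TESTCODE, hexamer bias], serialized to versioned
JSON; loaded models reproduce probabilities bit-identically because
scoring uses the frozen parameters directly. ORFs are ATG-initiated,
stop-terminated (or flagged open-ended at the 3' end), forward frames
only — the transcript is already strand-resolved; codons containing N
match neither start nor stop; nested ORFs sharing a stop keep the most
5' ATG.

The Fickett statistic uses the published TESTCODE position/content
lookup tables and weights with all ten content bins (boundaries 0.33 …
0.17), position asymmetry max/(min+1) per base, and base frequencies
over ACGT only; more than 50 % ambiguous bases makes the score
undefined. Hexamer bias is log(f_coding/f_noncoding) over all 4096
6-mers, add-one smoothed, with coding counts taken in-frame (step 3)
from ORF/CDS training sequences and noncoding counts in all frames
(step 1); a transcript scores the mean log-ratio over the in-frame
hexamers of its longest ORF, 0 without one.

Because the model is trained at run time on the synthetic corpus below
(seeded, disjoint stream from any fixture), its probabilities are
calibrated to that corpus, not to human GENCODE training sets; users
with real data should train on matched coding/noncoding sequences via
`train_hexamer_table` / `train_coding_model`.

### Expression

RPKM = 10⁹ · reads / (library size · summed exon length), taking
uniquely-mapped counts as a 3-column input table; alignment and
counting are external (as is read QC's upstream: the FASTQ filter keeps
reads with < 10 % N bases and > 85 % of bases above Q20, both strict,
reading the quality clause per-base — a per-read mean-quality reading
is also conceivable and the thresholds are configurable).

## The synthetic study

The generator emulates the target study design: two groups of six
bisulfite-sequenced individuals; ~1000 CpG sites with coverage
Poisson(30); null sites Beta(5,5); two planted epimutations with case
levels Beta(9,1) versus control Beta(1,9), i.e. a planted |Δ| of 0.8 —
one under a planted transcript locus, one with no expression over it.
The 60-kb genome carries six annotated plus-strand genes; over the
first planted site sit one antisense lncRNA (600 nt, 4 exons, minus
strand, ORFs capped below 300 nt) and two mRNA-like decoys (900 nt,
~70 % ORF of biased codons, one per strand), exons interleaved so all
three span the site; further coding and noncoding decoys sit far from
any call. Planted expression gives the lncRNA 250 reads in a 2×10⁷
library (RPKM ≈ 20.8). mRNA-like sequences draw each internal codon
from a GC-rich preferred-codon set with probability 0.8 (the codon-bias
strength), which drives both the hexamer and Fickett separation.

One global seed fans out through fixed per-component offsets
(`SeedSequence([seed, component])`), so regenerating with a partially
changed configuration leaves unrelated components untouched; identical
configurations are byte-identical (SHA-256-tested).

What the simulation does **not** model: bisulfite conversion errors,
sequencing error profiles, fragment-length effects, realistic CpG
island structure, correlated methylation along the genome, or
human-genome codon/hexamer statistics. Passing tests therefore
demonstrate the machinery's correctness and the method's behaviour
under its own assumptions, not performance on real tumour methylomes.

A second, parameter-free fixture encodes a reported antisense locus
structure — three minus-strand transcripts of 888/603/382 nt with 7/5/3
exons over a plus-strand gene — with arbitrary but deterministic
internal exon boundaries and synthetic background sequence; it
exercises GTF round-tripping, length criteria and antisense
classification against printed values.

## Problem sizes and numerical choices

Test and acceptance problem sizes were chosen so the full suite runs in
well under a minute on one core while keeping comfortable statistical
margins: calibration uses 500 (tests) / 200 (acceptance script)
replicates of 1000 sites; planted recovery 200 / 100 replicates; the
exact-test oracle sweep covers all 246 016 tables with margins ≤ 30.
Fisher tie tolerance is 1+1e-7 relative; BH ties mean q is not
guaranteed ≥ p per site; ranking tie-breaks (|Δ|, then p, then
position) make output order total and deterministic. Degenerate inputs:
empty matrices and empty call lists yield empty outputs; a group with
zero pooled coverage is untestable (skipped in bulk calling, an error
in the single-site statistic); windows near contig ends are clipped,
never errors.

## Known limitations

- Pooled Fisher is anti-conservative under between-individual
  overdispersion (see above); interpret q-values accordingly on real
  cohorts, or pre-filter to high-|Δ| sites as the ranking does.
- The flank filter's antisense exemption is a design decision; disable
  it (`--no-antisense-exemption`) to apply the criterion strand-blind.
- The built-in coding model is only as good as its training corpus;
  external PFAM/noncoding scores, when supplied, provide orthogonal
  evidence and are reported per criterion.
- "Region"-level aggregation of adjacent CpGs is out of scope: calls
  are single sites, and a "region" here means the primer window around
  a site.
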
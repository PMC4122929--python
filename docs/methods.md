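# Methods

This note documents the models, conventions, numerical choices, and
known limitations behind `paralogkit`, in enough detail to reproduce or
challenge any of its decisions.

## Duplicate-pair identification

**Collapse.** Each isogroup (an assembler's cluster of isoforms and
alleles of one putative gene) is collapsed to its longest isotig; ties
go to the lexicographically smaller id so reruns are byte-identical.
Sequences missing from the isogroup map are treated as singleton
isogroups rather than rejected.

**Similarity search.** The internal search is a k-mer seeded local
aligner: a pair is aligned only where it shares an exact k-mer (default
k = 11, both strands), and the alignment is an affine-gap
Smith–Waterman (match +2, mismatch −3, gap open −5, gap extend −2;
first gapped position pays the open score) restricted to a window
around the seeded region, computed by Biopython's `PairwiseAligner`.
Because windows are padded by the query length, the reported score
equals the unrestricted optimum whenever the subject is not much longer
than the query; the test suite verifies this against a hand-written
Gotoh dynamic program. E-values follow the Karlin–Altschul form
E = K·m·n·exp(−λS) with fixed constants (λ = 0.625, K = 0.41): only hit
ranking and the E ≤ 1e−20 threshold crossing matter to the workflow, so
the constants are configuration, not estimates.

Two pruning rules keep the search fast without changing retained
output: candidate pairs must share at least 4 k-mers, and a window must
carry at least 4 seeds (10 for the transcript-vs-genome scan, where
multi-megabase intergenic sequence produces chance collisions). An
alignment crossing the E-value threshold needs on the order of fifty
identical bases — dozens of overlapping 11-mers — so these floors
discard only hopeless work. The one theoretical exception (a
threshold-crossing alignment whose identities are so fragmented that
fewer than 4 exact 11-mers survive) sits at the extreme edge of the
retention boundary and is accepted as a sensitivity/speed trade-off.

**Pairing and filtering.** Pairs are reciprocal best hits (mutual
argmax by raw score, ties broken by longer alignment then smaller
subject id — deterministic, and each sequence joins at most one pair),
then filtered to alignment length ≥ 300 bp (inclusive) and percent
identity > 80 (strict), thresholds read literally from their
definitions.

## Origin classification

Anchors are the best genome hit per transcript plus any hit within 10%
of the best score; minus-strand hits are normalized to forward-strand
intervals. Classification applies rules in order:

1. any anchor combination on one contig with overlapping intervals
   (≥ 1 bp) → ALLELIC (two alleles of one locus; discarded);
2. same contig, nearest-end gap strictly greater than 5 kb → LGD.
   When an annotation table is supplied, an identical best-hit
   accession on both members vetoes this call (→ AMBIGUOUS); one
   missing annotation counts as distinct. The veto is optional because
   it is database-dependent;
3. same contig, non-overlapping, gap ≤ 5 kb → AMBIGUOUS (excluded from
   WGD/LGD statistics; their origin is genuinely undecidable at this
   resolution);
4. different contigs → chromosomes via the linkage map: same
   chromosome → LGD (chromosome-level identity, not contig-level,
   defines "local" here), different chromosomes → WGD, any unmapped
   contig → UNASSIGNED;
5. unanchored transcript → UNASSIGNED.

Gaps are measured between nearest interval ends (the most conservative
reading of "more than 5 kb apart"). Multi-anchor transcripts resolve to
the top-scoring anchor; chromosome conflicts among retained anchors are
recorded in the pair's evidence string, never silently dropped.

## Ka/Ks estimation

Frames come from comparing all 36 combinations of six-frame
translations under a local BLOSUM62 alignment (stops translate to `*`
scored −10 against everything; gap open −11, extend −1). The longest
stop-free codon run overlapping the translated-alignment region is the
ORF — stop-to-stop, with no start-codon requirement, minimum 30 codons.
The run is then clipped to the translated-alignment span: stop-free
runs frequently read through into untranslated flanks, and forcing
those non-homologous tails through the global alignment inflates both
Ka and Ks (in simulation, clipping moves the Ks regression slope from
~1.18 to ~1.05).

Peptides are globally aligned (BLOSUM62, gap open −10, extend −1,
deterministic traceback) and back-expanded to codons; the concatenated
non-gap codons must reconstruct each ORF exactly or the expansion is
rejected.

Nei–Gojobori counting uses the universal code. Per-codon synonymous
site fractions count a change into a stop codon as nonsynonymous (so
S + N = 3 × counted codons exactly); site totals average the two
sequences. Multi-nucleotide codon differences average over all
orderings of the single steps, excluding orderings that pass through a
stop codon (all orderings weighted equally if every one is blocked) —
conventions differ between published implementations, so the test suite
pins this one against exhaustive enumeration over the full 61 × 61
sense-codon grid. Columns containing a gap, an ambiguous base, or a
stop codon are excluded from counting. The Jukes–Cantor correction maps
proportions to distances; p ≥ 3/4 is reported as a saturation flag and
Ks = 0 as a flag (Ka/Ks is then undefined rather than infinite).
Alignments shorter than `min_codons` (default 100 gap-free columns) are
flagged TOO_SHORT — a measurable stand-in for the original toolchain's
alignment-quality filter, declared, not asserted equivalent.

Relative dating is the Ks ratio scaled by a calibration age,
t = t_ref · Ks_focal/Ks_ref, reported at full precision (integer
truncation is a display choice).

Group comparisons follow standard practice for these data shapes:
percent identities are arcsine-square-root transformed and checked with
Shapiro–Wilk before a two-sided Mann–Whitney test; Ks values are
log-transformed (zeros excluded and counted) before a Welch t-test.

## Functional divergence

C1 pairs two isotigs from one isogroup, never reusing an isogroup; C2
pairs isotigs from different isogroups, never reusing a sequence, with
rejection sampling (1,000 attempts per slot) implementing the
"replace until different" rule. Hit concordance is SAME_HIT (both
members share one best hit), DIFFERENT_HIT (different hits, or exactly
one member has a hit), NO_HIT; the χ² test is Pearson's on the full
3 × 3 table (df = 4), erroring on zero expected counts rather than
silently merging. Jaccard overlap of GO term sets is compared by
Kruskal–Wallis plus pairwise Mann–Whitney with Bonferroni correction.

The permutation test pools the two groups' values, reassigns the
original group sizes per round, and counts rounds whose |Δ median|
(resp. |Δ IQR|) reaches the observed value; p = count/rounds with
resolution 1/rounds, and ties count toward the p-value (the
conservative ≥ rule; the strict > variant and a bootstrap resampling
variant sit behind flags). The pooled values are sorted before
resampling so the result is invariant to argument order. Calibration is
part of the acceptance suite: under a uniform null the nominal 5% level
rejects at 4–5% and the p-values are distribution-uniform.

GO enrichment is a per-term two-sided Fisher's exact test of foreground
versus the rest of the background, Benjamini–Hochberg adjusted,
flagged at q ≤ 0.05. Sidedness and the FDR procedure are the package's
choices where the convention is not forced.

### Coding-potential scorer

The built-in scorer is a regularized logistic regression over three
features: longest-ORF coverage over all six frames; mean trinucleotide
log-odds (coding composition versus uniform background) inside that
run; and the same log-odds outside it. The third feature carries the
key signal for pseudogenizing duplicates — an intact transcript has
background-composition UTR outside its ORF, while a frame-disrupted
duplicate still looks coding-like outside its surviving ORF fragment.
The model is fitted once, deterministically, on an internally generated
corpus of transcript-like sequences (UTR + stop-free ORF + UTR at GC
0.40–0.58; negatives are uniform random sequences and frame-disrupted
ORFs). It is a lightweight scorer with the conventional 0.5 threshold,
not a reimplementation of any published classifier; externally computed
score tables pass through untouched and are the fidelity path for real
data.

## The synthetic-data generator

The generator's defaults are the study conditions every end-to-end
check runs under:

| parameter | default | rationale |
| --- | --- | --- |
| ancestral genes | 120 | enough planted events for stable percentages at desk scale |
| gene length | 200–400 codons | typical assembled coding transcripts |
| chromosomes × contigs | 4 × 2, doubled by the WGD | small but non-trivial linkage structure |
| WGD Ks / LGD Ks | 0.40 / 0.23 | the two duplication cohorts' observed synonymous divergence |
| Ka/Ks | 0.21 | relaxed purifying selection typical of retained duplicates |
| tandem gap | 6–50 kb | safely beyond the 5 kb decision boundary |
| allele divergence | 0.5% | within-locus variation; half the alleles are emitted unclustered (own isogroup) to model assembly failures, which is what gives Step 3's ALLELIC rule real work |
| isoform fraction | 0.25 | in-frame internal deletions of 10–30%, sharing the parent's isogroup |
| noncoding drift | 15% of duplicate copies | pseudogenization: codon shuffle outside a preserved 40% anchor, frameshifting deletions every ~20 codons, 30% neutral decay of outside sites |
| annotation inheritance | 0.5 | a diverged copy retrieves a different best hit from a redundant protein database about half the time, reproducing the observed paralog same/different-hit split |
| standalone noncoding transcripts | 0.5 × gene count | transcribed intergenic sequence; real assemblies are dominated by unannotated sequence, and without this class the C2 control could not be the widest group |
| transcript GC | 0.43–0.55 per gene | vertebrate transcript range; above ~0.58 random sequence contains chance ORFs long enough to make "noncoding" objectively undetectable by ORF structure |
| UTR flanks | 30–300 / 50–600 nt | per-copy transcribed flanks; they give ORF coverage and composition realistic between-gene variance |

Substitutions are applied sequentially (synonymous and nonsynonymous
Poisson processes over NG site counts, redrawing hits that would create
stops), so realized divergence is Poisson-dispersed around targets;
truth rows carry realized counts. Transcripts are unspliced genomic
substrings (coding region plus UTRs), so genome anchoring is exact by
construction; intron structure is deliberately out of scope. Tandem
spacers are sized so the planted transcript-to-transcript gap is exact
after both UTRs are cut from them. GO terms are inherited with 10%
per-term turnover, which separates the C1/paralog/C2 Jaccard
distributions by construction.

**Recovery scoring.** A planted WGD/LGD pair is *recoverable* when both
members are still protein-coding and each member's nearest planted
relative is its partner: reciprocal-best-hit pairing structurally
cannot recover a pair whose member has a closer relative (a tandem copy
at Ks 0.23 always outcompetes the WGD partner at Ks 0.40 for the shared
member, exactly as in real data, where only a minority of pairs could
be assigned an origin). Recovery percentages are therefore reported
over recoverable pairs; allelic exclusion and homeology concordance are
reported over all planted events.

**What passing does and does not show.** The generator has no introns,
no sequencing error, no chimeric or fragmented transcripts, no
repeat/transposon content, no assembly collapse of near-identical
duplicates, and clean linkage data. Passing the planted-truth checks
shows the decision logic, the estimators, and the statistics are
implemented correctly under the divergence regime the thresholds were
designed for — not that the thresholds themselves are optimal for any
particular real dataset.

## Numerical and interface choices

- Coordinates are 1-based inclusive throughout, minus-strand subject
  hits encoded by sstart > send (the tabular search-output convention);
  the 12-column hit format is read and written losslessly.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and seeds give
  byte-identical outputs, including the emitted dataset files.
- Degenerate inputs are contracts, not crashes: empty anchor lists
  label pairs UNASSIGNED, an empty WGD set reports concordance as
  undefined, both-empty GO sets report Jaccard as undefined, Ks = 0 is
  excluded (and counted) before log transforms.
- The command-line pipeline hands off between stages through TSV files
  so externally computed hits can replace the internal search at any
  seam; a JSON manifest records config, seed, checksums and row counts.

## Problem sizes

Default end-to-end runs use 120 ancestral genes (≈ 460 transcripts,
≈ 4.7 Mb of genome), estimator-recovery experiments 50 replicates of
500 codons per Ks target, and permutation calibration 1,000 replicates
of 2,000 rounds; these sizes give stable percentages while keeping a
full run in minutes on one core.

## Known limitations

- Paralog pairs where one copy is unexpressed (or expressed in
  unsampled tissues) are invisible to a transcriptome-based search.
- The Nei–Gojobori estimator is an approximate counting method; no
  maximum-likelihood dN/dS, rate variation among sites, or codon-usage
  correction is attempted.
- Same-contig non-overlapping pairs within 5 kb remain AMBIGUOUS;
  resolving them needs synteny or gene-model evidence outside this
  package's scope.
- The internal aligner is for desk-scale and validation use; very large
  transcriptomes are better served by feeding an external search's
  tabular output into the same workflow.
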
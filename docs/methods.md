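# Methods

This note documents the models, conventions and numerical choices behind
`lstclust`, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not demonstrate.

## Read trimming

Reads are trimmed one base at a time from the 3' end until the remaining
prefix simultaneously satisfies: lower-median Phred score ≥ 25; fewer than
5 bases with Q ≤ 10; fewer than 10 bases with Q ≤ 20; cumulative error
below 1e-2, with per-base error p = 10^(−Q/10). Reads whose longest
compliant prefix is under 60 nt are rejected; a surviving read whose mate
is rejected becomes an orphan. Because trimming only ever removes 3'
bases and stops at the first compliant state, the result equals the
longest compliant prefix, which is what the property tests check against
a brute-force prefix scan.

Two readings of "cumulative error" are implemented. The default,
`mean_per_base`, requires the *mean* per-base error to stay below 1e-2
(≈ Q20 average): under the literal *sum* reading, a typical 90-nt read
would need an average quality above Q40 to pass, which would reject
essentially all HiSeq-era data and is inconsistent with the retention
rates this kind of filter is known to produce. The sum reading remains
available (`cum_error_mode: sum`). The lower median is used for
even-length prefixes so all comparisons stay in integers. Phred offset 33
is assumed and configurable.

## Pairwise alignment statistics

All clustering decisions consume two per-pair quantities:

* **identity** — matching columns / aligned columns of the reported
  block, gap columns included (the `pident` convention of tabular search
  output);
* **overlap** — aligned span on the shorter sequence / shorter sequence
  length. Measuring overlap on the shorter partner makes a fragment or an
  intron-free isoform fully "covered" by its longer sibling, which is the
  behaviour the clustering needs; `overlap_denominator: longer` is
  available.

Scoring is megablast-like: match +1, mismatch −2, affine gap of length L
costs 5 + 2L. IUPAC ambiguity codes (N included) score as mismatches
against everything, themselves included. Both strands of one partner are
aligned and the better-scoring strand reported; clustering is therefore
strand-agnostic, as assembled transcripts have arbitrary orientation.
Inputs to a pair computation are ordered canonically (by length, then id)
before aligning, so all statistics are symmetric by construction.

**Block splitting.** A single best local alignment would bridge a
retained intron with one enormous gap, collapsing the identity of a
perfectly good isoform pair (a 200-nt gap contributes 200 non-matching
columns). Search tools instead report such pairs as separate HSPs. To
mirror that, the best local alignment is split into blocks wherever an
indel run reaches `max_gap` (30 nt), and pair statistics come from the
highest-scoring block. A qualifying block needs ≥ 30 aligned columns at
≥ 50% identity (noise floor), otherwise the pair yields nothing.

**Overall identity** (the coarse-stage criterion) uses the *unsplit*
alignment instead: identical bases anywhere in the best local alignment
divided by the shorter length. This is the greedy-incremental-clustering
convention and deliberately tolerates differential intron retention.

The all-against-all stage may skip pairs sharing no 12-mer on either
strand. This prefilter is a documented approximation — a qualifying
alignment without a shared 12-mer would be missed — and is disabled
wherever tests compare against the exhaustive dynamic-programming oracle.

## Coarse clustering (secondary loci)

Within each initial locus, transcripts that are exact substrings of
another (either strand) are discarded (duplicate ties keep the smallest
id). The rest are visited longest-first; each joins the first cluster
whose *founding seed* shows ≥ 85% overall identity to it, else founds a
new cluster — the greedy incremental scheme of CD-HIT-EST, including its
property that membership is only ever tested against the seed
(`membership: longest_current` re-tests against the longest current
member instead). Subsequence removal is applied per locus by default; a
global mode exists. Clustering never crosses initial-locus boundaries at
this stage.

## Annotation profiles and tertiary loci

The longest transcript of each secondary locus is searched against the
reference peptides of each annotation species. A hit qualifies with
bitscore strictly over 85 and e-value ≤ 1e-20 (both operators read
literally from the thresholds' usual statement). Per species, the best
qualifying hit fills one profile slot; ties break by bitscore, then lower
e-value, then subject id, making profiles independent of input order.
Secondary loci with slot-wise identical, non-empty profiles merge into
tertiary loci. All-empty profiles never merge (otherwise every
unannotated locus would collapse into one), and protein-sourced profiles
are never compared with nucleotide-sourced ones. Whether profiles should
also be allowed to merge on compatible-but-unequal slots (e.g. (X, —) vs
(X, Y)) is genuinely open; strict slot-wise equality is implemented.

Unannotated clusters may repeat the procedure with EST/cDNA hits; those
still unannotated can be screened against contaminant collections
(non-plant, tRNA/rRNA) and are flagged at e-value ≤ 1e-5, excluded from
the main collection and written separately.

**The internal translated search.** Where no external search results are
supplied, a minimal six-frame translated search provides the hits: shared
5-mer peptide seeds nominate (protein, diagonal) candidates; each
stop-free stretch of a candidate diagonal contributes its best ungapped
segment (BLOSUM80) when the raw score reaches 40. A translated segment
never crosses a query stop codon — a reading-frame disruption ends the
HSP, which is exactly what makes retained introns visible as HSP breaks.
Bitscores use approximate ungapped BLOSUM80 Karlin–Altschul constants
(λ = 0.3447, K = 0.177) and e-values the product of query length and
database residues; these are adequate for best-hit ranking and
thresholding, not for publication-grade statistics. Precomputed 12-column
tabular hits can replace this backend everywhere.

## Cutoff estimation and final clustering

All within-tertiary-locus pairs are aligned; the empirical distributions
of their identities and overlaps describe what pairs from one true locus
look like. The cutoffs are the nearest-rank lower `tail_fraction`
quantiles (default 1%; the ceil(q·n)-th order statistic — deterministic,
no interpolation), estimated independently for identity and overlap, so
that 99% of genuine within-locus pairs pass each cutoff marginally. The
quantile direction deserves a note: a "rightmost tail" of these
distributions, read literally as an upper quantile, would sit at ≈ 100%
identity and could not serve as a *minimum* threshold; the lower-tail
reading is the one consistent with treating the tail fraction as an
accepted false-negative rate, and with cutoffs like "95% identity, 65%
overlap" actually passing the bulk of within-locus pairs. An `upper` mode
is provided for completeness. Estimation with zero within-locus pairs is
a hard error instructing the user to set cutoffs manually.

Transcripts shorter than 350 nt are routed to a separate short collection
before final clustering (strictly-below boundary). Final LSTCs are the
connected components of the graph whose edges are transcript pairs with
identity and overlap both at or above the cutoffs — single linkage, so
chains of qualifying matches merge ("complete" linkage is available). A
final cluster inherits the union of member flags; its profile is taken
from the member with the highest-bitscore hit.

**Representatives.** Annotated clusters: the member with the highest
qualifying translated-search bitscore; members within 1% of the top score
count as ties ("similar highest scores" quantified as a 1% band,
configurable) and the shortest of them wins — retained-intron carriers
are longer, so this biases representatives toward mature isoforms.
Unannotated clusters: the longest member. All remaining ties break by id.

## Evaluation metrics

Three reference-free proxies compare clusterings: (i) the number of
distinct reference genes matched by representatives and the mean number
of representatives per matched gene (fragmentation/redundancy); (ii) the
Pearson correlation between reference gene-family sizes and family sizes
inferred from representative best hits, over the union of families with
absences counting zero; (iii) the distribution of conserved single-copy
orthologs over {≥4, 3, 2, 1, absent} matching representatives.
Clusterings are compared with a two-sided paired t-test across reference
species (two-sample Welch available); identical vectors give p = 1 and a
zero-variance non-zero shift degenerates to p → 0 with a warning. N50 is
the largest L such that sequences ≥ L hold half the assembled bases.
Representatives hitting two or more distinct gene families are reported
as chimera candidates. On synthetic data the Adjusted Rand Index against
the true gene partition supplements these proxies; it does not replace
them, because only the proxies are computable on real assemblies.

## Intron and UTR inference

For a transcript paired with a reference ortholog, the maximum-bitscore
subset of HSPs strictly co-linear in both query and subject (dynamic
programming over HSPs sorted by subject start; overlaps ≤ 2 aa / 6 nt
tolerated and clipped from the downstream HSP) defines the coding frame.
Coordinates follow codon arithmetic exactly: 3 nt per unaligned terminal
amino acid are subtracted from the UTRs; for consecutive chained HSPs the
subject-side gap is allotted 3 nt per amino acid adjacent to the upstream
HSP and the remaining query gap is the putative retained intron. Excesses
under `min_intron` (30 nt) are treated as alignment jitter and not called
— a deliberate deviation from a purely literal "any excess" rule, needed
because chained local alignments fray by a few codons at their ends. A
transcript is *confidently annotated* when the chain covers more than 75%
of the ortholog. Minus-strand hit sets reverse-complement the transcript
before span arithmetic. The CDS convention throughout excludes the stop
codon (expected CDS length = 3 × protein length; the stop falls to the
3' UTR).

GC content is computed per sequence over unambiguous bases and compared
between inferred CDS and intron classes with a Welch t-test. Exon/intron
read-depth folds accept an external per-base depth vector (read mapping
is out of scope); the aggregate is reported both as a ratio of pooled
means (default) and a mean of per-transcript ratios, since either
convention is defensible.

## The synthetic benchmark

`lstclust.synthetic` generates the study conditions the package is tested
under. Defaults, chosen once: 10 gene families; paralog count geometric
with mean 1.8; paralog divergence 0.2 (each further paralog mutated from
the family ancestor at rate 0.2, giving ~80% pairwise identity — below
the fixed 85% coarse cutoff, i.e. the regime where annotation and
data-driven cutoffs, not the coarse stage alone, must separate paralogs);
3 reference species at ortholog divergence 0.05 (cross-species best hits
resolvable per paralog, the premise of annotation-profile merging);
isoform count geometric with mean 2; isoform divergence 0.01 emulating
assembler/base-call noise between variants of one gene (without it the
within-locus identity distribution would be a spike at 1.0 and cutoff
estimation degenerate); intron retention probability 0.3 with intron
lengths 150–400 nt at GC 0.30 (mirroring the real GC contrast between
coding and intronic sequence); fragmentation probability 0.2 keeping at
least half the transcript; CDS lengths 120–250 codons and UTRs 30–150 nt.
Initial loci are corrupted by over-merging consecutive paralogs with
probability 0.3 and splitting a locus's transcripts with probability 0.2.
Everything is drawn from one generator seeded by `seed`; identical seeds
give byte-identical outputs.

Retained introns are planted at codon boundaries, at least 10 codons from
either CDS end, and begin and end with in-frame stop codons. This
emulates the reading-frame disruption that makes a retained intron
visible to translated searches and gives the structure module a clean
round-trip: recovery is exact at zero divergence and ≥ 90% base-level
Jaccard at 5% divergence. Substitutions are uniform across sites with no
transition/transversion bias — adequate for threshold behaviour, not for
phylogenetic realism.

What the benchmark does **not** emulate: chimeric mis-assemblies,
heterozygosity, expression-level variation, contaminant sequences,
sequencing-error models beyond per-cycle quality profiles, and paralogs
above the identity cutoffs. That last case is a documented failure mode
of the method itself, not of the implementation: with paralog divergence
0 the pipeline merges paralogs by design, since no alignment statistic
distinguishes identical genes. Passing tests on this benchmark show the
machinery is correct under the stated conditions; they do not certify
performance on any particular real assembly.

Problem sizes in the test suite and the acceptance study (10 families,
≈ 20–50 transcripts per instance, 40 seeds) were chosen as the smallest
instances in which every failure mode the generator models occurs many
times per run.

## Determinism

Every random choice funnels through one seeded generator; all output
ordering is explicit (cluster id, then transcript id); reruns with
identical inputs and configuration are byte-identical, and the test suite
asserts this end to end.
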
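# Methods

`ssrmine` implements the analytical chain used in carrot (*Daucus
carota*) microsatellite marker studies: repeat mining in genomic and
transcript sequence, a reading-frame-aware classification of repeats as
coding or non-coding, compositional null models and chi-square tests for
the repeat landscape, and marker-level statistics (polymorphism index,
cross-taxa transferability, gene diversity).  This note records the
models, the defaults and why, what the synthetic generators do and do
not emulate, and the places where a genuinely open design choice was
made.

## Microsatellite model and detection

A perfect microsatellite is a maximal uninterrupted run of a repeat unit
of 1–10 nt.  Detection follows the MISA convention: per unit length *k*,
the scanner anchors at the leftmost position admitting at least two
whole units, extends greedily by whole units, and resumes after the run,
so same-*k* loci never overlap.  A run whose unit is a whole-number
repetition of a shorter motif (e.g. ACAC at *k* = 4) is reported only at
the shorter, primitive unit length.  Runs never cross an N.  One
consequence of whole-unit leftmost anchoring worth knowing: when the
underlying periodic stretch has a partial trailing unit, the reported
window sits at the left of the stretch, so mirroring the sequence can
shift a locus by up to *k* − 1 bases.

Thresholds are a conjunction, repeat span ≥ 12 nt AND ≥ 3 units —
so dinucleotides need 6 units, trinucleotides 4, and tetra- through
octanucleotides 3.  Mononucleotide runs are excluded by default (they
are dominated by sequencing artefacts in Sanger-era data) but the unit
range is configurable to 1–10.

**Motif classes merge cyclic rotations only, not reverse complements.**
GA, AG, and their rotations form class AG; TC and CT form the distinct
class CT.  This yields 6 dinucleotide and 20 trinucleotide classes and
is deliberate: strand-specific spectra are the observable in
single-strand resources such as EST collections, where AG and CT
frequencies genuinely differ.  Many MISA-adjacent pipelines additionally
merge reverse complements; counts from such pipelines are not directly
comparable to ours.

Compound microsatellites are chains of consecutive perfect loci on one
sequence whose inter-locus gap is at most `d_max` nt.  The perfect and
compound outputs partition the detected loci: a compound's members are
not double-counted in the perfect tallies.  `d_max` defaults to 100 nt,
the conventional MISA interruption distance; it is exposed in
`SSRSearchConfig` because the appropriate value is assay-dependent.

## ORF model

An ORF is an ATG followed in-frame by a stop codon (TAA/TAG/TGA) at a
coding distance of at least `min_orf_len` nt (default 100), with no
in-frame stop in between; the reported span excludes the stop codon and
"distance ≥ 100" is read as stop-start − ATG-start ≥ 100.  All six
frames are scanned by default (genomic BAC-end sequence is unoriented);
`strands="forward"` restricts to three frames for oriented transcripts.
Codons containing N match neither ATG nor a stop.

Two start-codon rules are implemented because the convention is
genuinely ambiguous when a stop-to-stop segment holds several ATGs:
`"longest"` (default; first ATG after the previous stop — the standard
maximal-ORF convention) and `"innermost"` (last ATG before the stop,
i.e. no intervening ATG).  Both are regression-tested; the default was
chosen because it is the standard convention and the more conservative
one for "SSR inside ORF" calls.

When ORFs in different frames or strands overlap, the longer is kept.
The published rule is pairwise; chains of mutual overlaps are resolved
greedily by descending length (ties: smaller start, then + strand, then
lower frame), which is order-independent and reproduces the pairwise
rule exactly when only two candidates conflict.

Each microsatellite is then `inside` (span contained in a retained
ORF), `outside` (disjoint from all), or `bridging` (partial overlap).
Bridging repeats are excluded from the inside/outside tests, mirroring
the practice of discarding repeats that straddle a frame boundary.

## Statistical layer

*Repeat-type tables* aggregate counts, percentages of total perfect
loci, mean unit numbers, mean lengths, and densities per Mbp.  Density
is count / dataset Mbp; for hybridization-enriched libraries no density
is reported (the library is not a random genomic sample), which the
table renders as NaN/"—".

*Compositional null for motif classes.* Expected class probabilities
come from a zero-order (mononucleotide) model: the probability of a
class is proportional to the summed probability of its distinct
rotations under independent per-base draws from the dataset's A/C/G/T
frequencies (N excluded).  Because rotations share one base multiset,
this is (number of distinct rotations) × Π p(base), normalized over the
primitive classes of that unit length.  A dinucleotide-aware model is
deliberately not attempted; the zero-order model is the stated basis of
the published expectations.

*Tests.* Goodness of fit is Pearson's chi-square with df = classes − 1
(via `scipy.stats.chisquare`); an expected count of zero raises with
advice to pool classes.  Inside/outside placement is a two-class test
per repeat type with expected inside = n × (fraction of dataset bp in
retained ORFs), df = 1.  Dataset comparisons of unit number and length
use Welch's unequal-variance t-test; identical constant samples report
p = 1 by convention.  Report formatting floors displayed p-values at
"< 0.0001".

## Marker panel statistics

The polymorphism index of a marker screened in *n* F2 populations is

    PI = 100 · (2C + D) / (2 · (n − nd))

with C/D the numbers of codominantly/dominantly segregating populations
and nd the populations with no information.  The printed form of this
formula brackets ambiguously; this precedence is the only reading that
gives 100 for all-codominant and 50 for all-dominant markers, which is
how it is implemented.  "No information" means truly missing
evaluations only: ambiguous band patterns and amplification failures
were scored (as effectively monomorphic) and therefore stay in the
denominator.  The nd rule is configurable (`nd_calls`).

Repeat-number classes `<6`, `6-10`, `11-15`, `>15` bin markers by the
summed unit count over all perfect repeats in the amplicon (a marker
carrying (AT)6 and (CTT)5 counts 11).  PI is regressed on repeat units
(Pearson r, two-sided p, least-squares slope) and summarized per class.
F2 segregation distortion is tested against 1:2:1 (codominant, df 2) or
3:1 (dominant, df 1) with distortion declared at p < 0.01.

Transferability: an accession succeeds for a marker when some amplicon
lies within ±100 bp (`size_window`) of the size expected in the source
species; fragments present but all outside the window are non-specific
and count as failures.  Summaries cover per-accession and per-group
success, markers succeeding in every member of the nested accession
sets (all carrot; all *Daucus*; all accessions), and markers succeeding
in ≥ 80% of non-carrot accessions (with 15 non-carrot accessions the
threshold is 12; exactly 12/15 counts).  Interspecific allele counts
cluster fragment sizes by single linkage at the gel resolving limit
(merge below 3 bp), reflecting that high-resolution agarose cannot
separate closer fragments.

## Diversity statistics

Per locus, allele frequencies are computed over the non-missing gene
copies (missing genotypes drop out; no imputation) and expected
heterozygosity uses Nei's unbiased estimator He = n/(n−1) · (1 − Σp²),
the convention of the population-genetics software used in such panels
(Arlequin); the uncorrected 1 − Σp² is available behind `unbiased=False`.
Alleles are identified by exact fragment size (capillary resolution);
the 3-bp gel rule applies only to the interspecific agarose data.  Panel
summaries sum distinct alleles over loci, pool the size range, and
average NA and He with n−1 standard deviations.  Note that summary rows
recomputed at full precision can differ in the last digit from published
rounded summaries (e.g. a mean of per-locus values each printed to 2
decimals).

## Synthetic data

The generators are pure functions of a spec that includes the seed, and
they return exact ground truth with the data.

Sequence datasets: background is drawn from a zero-order composition
model at the target GC (defaults 38.3% for the BAC-end-like preset,
42.3% for the EST-like preset).  Microsatellites are planted with a
configurable unit-length spectrum, unit counts of (threshold minimum) +
Poisson, a compound fraction (two repeats 2–10 nt apart), and an
inside-ORF probability; planted ORFs are ATG + sense codons
(composition-weighted, free of stops and internal ATGs, so both start
rules agree) + stop.  Guard bases prevent planted repeats from extending
into their flanks, inter-feature background exceeds `d_max` so separate
plants never merge, and every record is rejection-sampled until the
package's own detectors recover exactly the planted features — the
emitted ground truth is therefore exact by construction, with no
accidental above-threshold repeat or ORF in the background.  Default
problem sizes (tens of records of ~0.7 kb) are scaled-down analogues of
the Mbp-scale study datasets chosen so the full suite and the
reproduction script run in seconds; all rates are size-free and
unaffected by the scaling.

Screening matrices: 300 markers (156 enriched-library, 144 BAC-end-
derived) × 7 populations.  Repeat totals are 3 + Poisson(6) for
enriched-library markers and 3 + Poisson(1.5) for BAC-end markers,
echoing the longer repeats obtained by hybridization capture.  Calls
are drawn independently per population with per-repeat-class
codominant/dominant probabilities that rise with repeat number, plus
small ambiguous/no-amplification/missing rates.  This independence is a
simplification: in real panels a marker's polymorphism is correlated
across populations, so the real spread between percent-polymorphic and
mean PI per class is wider than the generator's.  Tests that recover
the generating class probabilities validate the estimators, not that
correlation structure.

Transferability matrices: 8 carrot, 8 non-carrot *Daucus* and 7
non-*Daucus* accessions with per-group success probabilities
0.86/0.58/0.41 (the study's observed group means, giving ~63% overall);
successful cells get the expected size ± 30 bp, failures are mostly
null with a minority of off-size (> 100 bp deviant) fragments.

Genotype tables: 65 diploids × 10 loci; frequency vectors are Dirichlet
draws over 10–29 alleles (or user-fixed vectors), sizes on a 2-bp
ladder.  The fixed vector (0.3, 0.1 × 7) used in recovery tests has
gene diversity exactly 0.84, the panel's published mean He.

What the generators do not emulate: repeat mutation processes
(slippage, interruptions), imperfect/approximate repeats, real
base-composition heterogeneity along sequences, linkage between
markers, and population structure.  Passing tests therefore certify the
detectors and estimators under the stated models, not robustness to
those real-data complications.

## Numerical and interface conventions

Internal coordinates are 0-based half-open; all exported files (GFF3,
TSV) are 1-based inclusive.  GC content excludes N from the
denominator.  Mbp values print to 2 decimals and GC to 1 in reports;
full precision is kept internally — published density figures derived
from rounded Mbp totals (e.g. 821/3.82 = 214.9 against a printed 214.8)
are reproduced at full precision rather than matched to the rounding.
Detection and the pipeline are deterministic: identical inputs and
configuration give byte-identical outputs, and every pipeline run
writes its resolved configuration and input digest next to the reports.

## Known limitations

- The overlap-resolution rule beyond pairwise conflicts (greedy by
  length) and the compound interruption distance (100 nt) are
  conventions, not published parameters.
- The regex scanner is O(sequence × unit lengths) and comfortable at
  tens of Mbp; it is not engineered for chromosome-scale scans.
- Screening-call independence across populations (above) and the
  absence of imperfect-repeat detection are the main realism gaps.
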
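# Methods

This note records the statistical model, the coordinate and windowing
conventions, the synthetic-data design, and the numerical choices behind
`agshift`, together with what the simulation-based tests do and do not
establish about real data.

## Coordinates and windows

Internally every interval is 0-based half-open on the genomic forward strand;
the 1-based closed conventions of GTF and STAR `SJ.out.tab` are converted in
`agshift.io` and nowhere else.  An intron is `[start, end)`; its donor
boundary is `start` on `+` and `end` on `−`, the acceptor boundary the
opposite end.  Boundary-coverage tables key boundaries by the *inter-base*
coordinate of the exon|intron junction point, which is strand-free.

Acceptor context windows cover positions −35..+3 in transcription
orientation: the invariant G at −1, A at −2, first upstream intronic base at
−3, first exonic base at +1 (no position 0).  All derived windows use this
frame: the branchpoint search and adenine-enrichment window −8..−18 (11
positions, inclusive), the polypyrimidine window −5..−20.  Distances between
acceptors are G-to-G offsets (the candidate AG's G to the canonical AG's G),
so "cryptic AG at 18 nt" means the exonic extension created by using it is 18
nt long.  Candidates overlapping the canonical AG (offset < 3) are excluded;
the background scan for "the first AAG/TAG/CAG upstream" walks from the
canonical site upstream, i.e. returns the nearest-to-canonical motif, which
is also the tie-break used by the conservation scan.  These anchor choices
are conventions; ranges quoted as "−5 to −20" in the field rarely state them,
so they are configurable (`ag_window`, `bp_window`).

## PSI model

A boundary group is two or more junctions sharing an anchor with distinct far
ends, optionally extended by an intron-retention pseudo-member whose count is
the number of reads fully covering the 6-bp window (3 exonic + 3 intronic nt)
at the anchor boundary; single junctions form a group only when retention
data exist for their anchor.  PSI is count over group total, with the
retention member in both numerator set and denominator, so within a defined
group/sample PSI sums to 1 and is invariant under count scaling.  A group
needs `min_total` reads (default 10) in a sample for PSI to be defined there;
the floor is a variance-control choice, not a published criterion.  Only
uniquely mapped read counts are used.  Unknown-strand junctions keep their
PSI but are excluded from sequence-context analyses, which need an
orientation.  Retention windows are evaluated at the group's shared anchor
boundary only.

## Moderated t-test

Member PSI is compared between the two genotypes on the raw fraction scale
(an arcsine-square-root option exists but is off by default, since the
underlying method is defined on raw PSI).  Per member: pooled residual
variance s²_g on d_g = n₁+n₂−2 df, requiring at least two defined samples per
group (others are skipped with a reason).  Hyperparameters follow the
standard hierarchical model in which s²_g | σ²_g is scaled chi-square and
1/σ²_g is chi-square with prior df d₀ and scale s₀²: moment matching on
z_g = log s²_g uses

    e_g   = z_g − ψ(d_g/2) + log(d_g/2)
    ψ′(d₀/2) = mean[(e_g − ē)²·n/(n−1) − ψ′(d_g/2)]      (solved by Newton)
    s₀²   = exp( ē + ψ(d₀/2) − log(d₀/2) )

with ψ, ψ′ the digamma/trigamma functions; the trigamma inversion iterates
Newton steps from the asymptotic start 0.5 + 1/y to relative tolerance 1e−8
(≤50 iterations).  A non-positive moment target means no excess spread:
d₀ = ∞ and every posterior variance equals s₀² (warned).  Zero residual
variances are excluded from hyperparameter estimation but still shrink
toward the prior.  The implementation agrees with limma's `lmFit`/`eBayes`
to machine precision on dense two-group designs (verified in the test suite
through an independent Rscript run).

Each member is tested against its group complement; the group's *reference*
member (highest mean wild-type PSI among junction members) is excluded from
testing because its shift is the mirror image of the others'.  P-values are
BH-adjusted (step-up with cumulative minimum from the largest rank, stable
under input permutation).  Events are the tested members with q < `q_max`
(default 0.05) and |ΔPSI| ≥ `min_abs_delta_psi` (default 0.1; the effect
floor is an extension knob — 0 reproduces a pure q-based criterion).
Classification is geometric: retention pseudo-member → intron retention; a
member whose intron fully contains an annotated exon that the reference's
does not → cassette exon; shared donor → alt-3′ss; shared acceptor →
alt-5′ss.  Novelty means the member's far-end boundary coincides with no
annotated exon boundary on the proper side for its strand.  Distances are
reported in transcription orientation (positive = upstream of the canonical
site; on the minus strand genomic downstream is transcriptional upstream).

### Calibration caveat

With a single shared prior, members whose true sampling variance sits far
below s₀² are tested conservatively and high-variance members slightly
anti-conservatively; on the synthetic null the aggregate rejection rate is
nominal (≈5% at p < 0.05) while the low-baseline cryptic members alone are
conservative.  This is inherent to one-prior empirical-Bayes shrinkage on
proportion data with heterogeneous baselines and depths; a mean-variance
trend on the prior would remove it but is deliberately out of scope.

## NMD prediction

`substitute_acceptor` extends the downstream exon's transcriptional 5′
boundary by the event distance (the intronic sequence between cryptic and
canonical AG is absorbed; exon count unchanged; extensions crossing the
upstream exon are rejected).  The modified transcript is re-read from the
annotated start codon in the original frame; the first stop terminates
translation (no readthrough or selenocysteine handling).  The stop is a PTC
when its 3′ end lies more than `nmd_distance` nt (default 50, the classical
50-nt rule — a field default, configurable) upstream of the last exon–exon
junction of the *modified* isoform; stops in the last exon never qualify;
stop-free transcripts are flagged nonstop.  A gene is NMD-predicted when all
CDS-bearing isoforms that contain the affected intron gain a PTC — isoforms
not using the intron cannot gain the PTC and are excluded from the universal
quantifier.  Expression association uses mean log2 CPM across mutant samples
with pseudocount 0.5 added to the raw count, compared between NMD and
non-NMD genes with a tie-corrected Kruskal–Wallis H (chi-square p, k−1 df;
an exact enumeration p is available for two groups of ≤8).

## Conservation cascade

Orthology is consumed as a precomputed table (event id, conserved flag,
species-B −35..+3 acceptor window, observed-spliced flag); genome alignment
is out of scope, and "observed spliced" is external evidence, not computed.
Per conserved event the species-B window is scanned for the
nearest-to-canonical AG with offset in −5..−20 and, given one, for an
adenosine at −8..−18 from it; counts are nested by construction
(input ≥ conserved ≥ capable ≥ observed).  A 38-nt window cannot cover the
full branchpoint range for candidate AGs deeper than −17; the cascade then
scans the covered positions only (direct calls to `has_bp_adenosine` raise
unless `require_full=False`).  Detected events lacking an orthology record
(possible false positives on synthetic data) are dropped from the cascade
input rather than failing the run.

## Synthetic data design

The generator emits the conditions the analysis assumes, as fixed study
parameters: 200 genes (3–6 exons of 90–150 nt in multiples of 3, introns
150–300 nt, both strands, one isoform per gene, 50 genes per chromosome), 20
planted events, ΔPSI = 0.3, baseline cryptic PSI 0.02 in the wild type (a
shift, not an onset, and no zero-variance groups), retention PSI 0.05,
depth 200 (negative binomial with variance μ + μ²/φ, φ = 10), n = 3 per
genotype, gene expression mean 500 with NMD genes down-scaled ×0.5 in the
mutant.  Group totals are drawn per sample and split multinomially between
canonical, cryptic and retention members by the group's true PSI; every
non-event intron also receives retention read-through at the same constant
PSI, so each forms a testable null boundary group — this supplies the null
background against which false-discovery control is measured.

Sequence engineering guarantees exact truth recovery: each event's cryptic
AG is the *only* AG within its engineered acceptor region (extension
interiors are G-free); the tract upstream of the cryptic AG (positions
−3..−25) is pyrimidine-poor and adenine-rich, with an adenosine forced at
the designated branchpoint offset and every adenine position inside −8..−18
recorded in the truth; canonical acceptors carry pure-pyrimidine tracts,
A- and G-free through the whole cryptic-offset scan window, so the
genome-wide AG background starts beyond 24 nt.  PTC-true events embed
`TGACTGACTGA` at the extension start — a stop in all three reading frames
(frame-independent truth) that is AG-free and adenine-sparse; PTC-false
events use frame-preserving offsets (multiples of 3 within 15–24) with
all-C extensions, so no stop can arise in or across the insertion.  Events
are planted only on introns whose downstream exon is internal, keeping the
planted stop >50 nt upstream of the last junction.  Orthology windows are
emitted per event with truth flags drawn hierarchically (conserved 0.8,
capable 0.6 of conserved, observed 0.5 of capable); capable windows plant
the AG at min(offset, 17) so the full branchpoint range is assessable within
38 nt, and non-capable conserved windows contain no candidate AG — the
cascade's negative branch.

All randomness derives from `SimConfig.seed`; identical configurations give
byte-identical FASTA/GTF/count outputs.  The replicate count (n = 3) and
depth are package choices for a typical bulk hematopoietic RNA-seq design.

What the generator does **not** emulate: read-level artifacts (alignment
error, overhang filters, positional bias, GC effects), multi-isoform genes,
correlated events within genes, realistic branchpoint sequence context
beyond adenine placement, or biological variance beyond the negative
binomial.  Passing the planted-truth tests therefore demonstrates the
*correctness of the computations* (coordinate handling, strand symmetry,
statistics, reconstruction logic) under the assumed model — not the field
performance of the method on real libraries.

## Problem sizes used by tests and the acceptance script

The test suite and `scripts/acceptance.py` run three scenarios: the default
(200 genes / 20 events, end-to-end), a recovery scenario (2000 genes / 20
events at depth 100 — ~7000 boundary groups, measuring sensitivity ≥ planted
truth and empirical FDR), and a global null (2000 genes, all with delta-free
planted groups, measuring the raw p < 0.05 fraction and the count of
q-significant events across 20 count replicates).  These sizes were chosen to
make Monte-Carlo error small relative to the margins being checked while the
whole suite stays interactive (≈10 s).
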
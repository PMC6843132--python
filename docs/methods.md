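# Methods

This note documents the models, conventions and defaults behind
`nfymatrix`, the choices made where the design was genuinely open, and what
the synthetic benchmarks do and do not demonstrate.

## Competition EMSA quantification

An off-rate competition series challenges a preformed NF-Y/probe complex
with an unlabeled competitor oligo at fold ratios r = competitor/probe
(default doses 0, 1x, 5x; the dose set is data, not code — the regression
uses whatever ratios the input provides). Per lane, percent bound is
100·bound/(bound+free), invariant under rescaling both band intensities.
The competitor's dose curve is summarized by the ordinary-least-squares
slope of percent bound on r, with a freely fitted intercept (the line is
not forced through the no-competitor point). The *competitor efficiency*
is slope/WT, the slope divided by the wild-type oligo's slope from the
same experiment (so gel-to-gel scale drops out); efficiencies are averaged
across replicate experiments (mean, sample sd with n−1; a warning below
three replicates). Slopes are kept signed; a competitor whose slope has
the opposite sign to the WT slope is reported as efficiency 0 with a
warning flag, and a WT slope below a configurable floor (default 10⁻⁶
percent per unit ratio) is an error. Replicate aggregation averages
efficiencies, not slopes.

Positions are named by the crystal-structure numbering of the human HSP70
CCAAT oligo: CCAAT occupies N8–N12, the mutagenized flanks N5–N7 (−3…−1)
and N13–N16 (+1…+4). Each oligo carries a `numbering_offset` mapping
crystal index N to sequence position N − offset; anchoring on the unique
CCAAT of the 31-mer CAB2 probe gives offset −1 (N8 ↦ position 9).

## Synthetic EMSA generator

The generator's default binding model is an off-rate **exchange** model:
during the competition incubation a fraction κ (`exchange_fraction`,
default 0.5) of the preformed complexes re-equilibrate, and the competitor
captures a share equal to its relative affinity a times its mole fraction
x = r/(1+r), so noiseless percent bound is

    percent(r) = 100 · β · (1 − a · κ · x(r)),   clipped to [0, 100],

with β the bound fraction in the reference lane (default 0.6). Because the
expectation is affine in a, the slope/WT statistic is *exactly*
proportional to the true relative affinity for any dose design, as long as
no lane clips (a·κ·x ≤ 1, i.e. a ≤ 2.4 at the default 0/1x/5x doses with
κ = 0.5). That is the property the quantification procedure relies on, and
it is what makes the generator a meaningful benchmark: the pipeline must
recover the truth, not merely co-vary with it. Outside the operating range
the response saturates at 0 and efficiencies compress; benchmark grids stay
within a ≤ 2.4. A saturating equilibrium-**partition** alternative,
percent = 100·β·(1−x)/((1−x)+a·x), is available via `model="partition"`
for sensitivity analyses; under it slope/WT is monotone in a but biased
toward 1 at high affinity.

Noise is additive Gaussian on percent bound (densitometry-style, default
sd 0, benchmarks use 3), clipped to [0, 100]; lanes are emitted as
(bound, free) intensities scaled by a random per-lane total factor so that
downstream percent-bound computation must be scale invariant. All
generators are bit-reproducible given a seed.

## Affinity table, matrix and logo

The saturation design measures one slope/WT efficiency per (position,
mutant base); the WT base at each position is 1 by construction. Negative
mean efficiencies (possible under noise) are clamped to 0 with a warning;
conflicting annotations are an error; multi-base mutants do not enter the
single-position table. Efficiency is treated as a relative affinity — the
assay's operational affinity proxy — and mapped to probabilities by the
minimal assumption-free transformation, an ε-floored normalization per
position (ε default 0.01, configurable). Bases never assayed at a position
are filled before normalization according to `missing_policy`:

* `floor` (default): untested ≈ negligible (value ε). The CCAAT core was
  assayed with a single transversion per position, and the published logo
  draws the core letters near full height, which is exactly the behavior
  floor-filling produces.
* `wt-share`: untested bases assumed as competitive as WT (value 1), a
  conservative low-information prior.
* `drop-position`: positions with no measured non-WT cell are omitted.

Column information content is the Schneider measure 2 + Σ p log₂ p bits
(0·log 0 ≡ 0, range [0, 2]); logo letter heights are p·IC. Matrix
comparison uses the per-position Jensen–Shannon divergence in bits after
aligning columns on the CCAAT anchor.

The bundled reference affinity table
(`nfymatrix.synthetic_reference`) is a *synthetic* stand-in: the published
per-oligo efficiencies exist only as a figure. Its flank values encode the
reported qualitative trends (T favored and WT A weakest at −3; C/G above
A=T at −2; purines over the WT T at −1; C over the WT G at +1; purines
over pyrimidines with C weakest at +2; all similar with WT A weakest at
+3; A favored at +4), and its core values (transversions 0.03, the second
C mildest at 0.08) are calibrated so the derived logo reproduces the
near-full-height core of the published artifact. It is for examples and
benchmarks, not a measurement.

## Scanning

The PWM becomes a log-odds matrix in bits, entry log₂(max(p, ε)/bg), by
default against a uniform background. Scanning is windowed on both
strands; minus-strand windows are scored on the reverse complement and
reported in top-strand 0-based half-open coordinates (the EMSA layer's
1-based crystal numbering never leaves the in-vitro modules). Ambiguous
bases score as the background-weighted column average. Ties in `best_hit`
break to the lowest offset, then the + strand.

Score thresholds are expressed as a fraction f of the achievable range,
min + f·(max − min). The default is f = 0.9. A lower default (e.g. 0.8)
was considered and rejected: with a realistically low-information plant
matrix (~8.4 bits total, flanks near zero), f = 0.8 sits ~7.6 bits below
the maximum and tolerates about 1.5 core mismatches, so 40–60% of random
AT-rich 50-mers "contain" the motif and both scanning and enrichment lose
their meaning. At f = 0.9 the per-window false-positive rate on
composition-matched random sequence is ≈ 1/(2·windows) for a 50-bp
sequence (≈ 7% per sequence), a standard detection operating point; the
fraction remains a plain parameter on every interface.

## Peak pipeline

Coordinates are 0-based half-open throughout; GFF3 (1-based) is converted
at the parser boundary, and the TSS of a gene feature is its strand-aware
5′ end. narrowPeak parsing is tolerant: track/comment lines are skipped,
lines with fewer than 10 columns are counted and logged, and a summit
column of −1 is replaced by the interval midpoint with a warning. Summit
windows are [summit − flank, summit + flank), default flank 25 — exactly
50 bp, resolving the off-by-one between "50-base windows" and "±25 bp"
(51) in favor of the half-open 50. Promoters are strand-aware: [tss−500,
tss) on +, (tss, tss+500] on − (as half-open [tss+1, tss+1+500)), clipped
at zero; a strand-agnostic distance rule can be emulated by classifying
against windows instead. Interval intersection is a sorted sweep line with
ends processed before starts at equal coordinates, so abutting half-open
intervals do not overlap; it is property-tested against an all-pairs
oracle. Venn "shared" counts are reported per set because peak overlap is
many-to-many; overlap uses the original peak intervals by default, with
`overlap_mode="window"` available for sensitivity analysis. Promoter
association likewise uses the raw peak intervals.

## Enrichment

Enrichment is known-motif ZOOPS + exact hypergeometric — a transparent
stand-in for de-novo discovery tools: a sequence either contains ≥ 1 hit
on either strand or it does not; targets and background form one pooled
universe (N = n_t + n_b sequences, K containing) and the p-value is the
exact upper tail P(X ≥ k) for k containing targets among n_t draws,
computed via the log-space survival function (stable to N ~ 10⁶; the
linear p may underflow for extreme tails, so log₁₀ p is always reported
alongside). The significance flag defaults to the in-vivo analysis bar
p ≤ 10⁻³⁰. The default background is one dinucleotide-preserving shuffle
per target (Altschul–Erickson: a uniform random last-edge tree plus
permuted out-edges of the dinucleotide multigraph, seeded and
bit-reproducible), which matches GC and dinucleotide composition without
needing a genome; length-matched uniform genomic sampling is the
alternative. No multiple-testing correction is applied for a single known
motif. The test statistic is discrete and therefore conservative: under
the null it rejects at or below the nominal level (measured ≈ 3% at
α = 0.05).

## Synthetic genomes and peak sets

Genomes are i.i.d. bases at a stated GC (default 0.36, Arabidopsis-like),
single chromosome by default; gene TSSs are placed uniformly with a
minimum spacing (default 400 bp) and random strands. Peaks (default width
200 bp) get non-overlapping uniform summits; for a stated fraction of
peaks a PWM-sampled site is written into the genome at the summit plus
Gaussian jitter (sd default 5 bp) on a random strand, and the narrowPeak
summit column points at the peak center. A truth table records each
peak's implant status, offset and strand.

## Benchmark problem sizes

The standing benchmarks (tests and `scripts/acceptance.py`) use: 12-oligo
saturation experiments with true affinities spanning 0.2–2.0, noise sd 3,
3 replicates, 20 seeds for the recovery Spearman (noiseless runs recover
affinities to < 10⁻⁶; noisy mean Spearman ≈ 0.99); enrichment power on
500 summit windows with 60% implant fraction over 20 seeds (log₁₀ p
median ≈ −42, all seeds < −30); null calibration over 500–1000
simulations of 100 vs 100 motif-free sequences (rejection ≈ 3% at
α = 0.05); interval-intersection oracle checks on 100 random
1000-interval sets.

## Limitations

The generators capture the statistical structure the analysis relies on,
not the full biology: gels have Gaussian densitometry noise but no smear,
saturation or lane-correlated artifacts; the exchange binding model is
affine by design, so benchmark recovery being exact says nothing about
model misspecification on real gels; genomes are i.i.d. with no repeats,
CpG structure or chromatin context, so enrichment power on them is an
upper bound for real peak sets; implanted sites are independent draws from
the PWM, ignoring dependence between positions. Reproducing the published
in-vivo peak counts requires the deposited peak files and genome
annotation, which must be fetched separately (see
`data/external/GSE80568/` in the acceptance test); agreement can also
depend on the exact BED dialect of the deposit — both peak- and
window-based overlap modes are provided for that reason. Binding-constant
(Kd) estimation, de-novo motif discovery, dinucleotide matrix models and
peak calling are out of scope.
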
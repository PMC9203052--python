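# Methods

## The assay model

A plasma sample is modelled as a pool of DNA molecules per amplicon
marker. Each molecule originates either from the target tissue (brain),
in which case every CpG of the amplicon is unmethylated, or from the
background pool (dominated by leukocytes), in which case every CpG is
methylated. The all-or-none assumption reflects how the markers are
chosen: loci with max beta ≤ 0.2 in the target class and min beta ≥ 0.8
everywhere else are close to bimodal, and the counting statistic — the
*fully* unmethylated molecule — is deliberately insensitive to partial
patterns. A per-CpG background "flip" rate is available
(`background_flip_rate`, default 0) to probe robustness to this
assumption.

Bisulfite chemistry is simulated per cytosine: unmethylated C → T with
probability `bisulfite_conversion_rate` (default 0.99, a typical
conversion efficiency), methylated CpG C → T with probability
`inappropriate_conversion_rate` (default 0.005). Sequencing adds uniform
substitution errors at `seq_error_rate` (default 0.001 per base,
Phred ≈ Q30 territory; emitted qualities are constant Q37 by default).
Reads are single-end, top strand, one per molecule; no PCR duplicates,
chimeras or indel errors are simulated (indel tolerance in the matcher is
exercised with constructed reads instead).

A consequence worth knowing: a truly unmethylated molecule is *called*
fully unmethylated only if all of its k CpGs convert and neither base of
any CpG dinucleotide is miscalled, so the recovered fraction is
`f · c^k · (1 − ε)²ᵏ` ≈ 0.94–0.95 of the spiked `f` at the defaults.
This mirrors the real assay's conversion efficiency and is why recovery
tests compare against binomial intervals around the spike rather than
exact equality. Conversely, a background molecule can only masquerade as
brain if *every* CpG converts inappropriately (≈ `0.005^k` ≤ 10⁻⁶), so
the simulated zero-spike background is essentially clean and the
simulated detection limit is set by sampling depth, not by chemistry
noise. At 30,000 molecules/marker × 13 markers the pooled pipeline
resolves a 0.05% spike; a wet-lab assay quoting a 0.1% limit is
additionally constrained by input DNA mass and degradation, which the
simulator does not model.

## Read processing

Reads are demultiplexed by exact barcode match (header field after the
last colon, the Illumina index convention, or an inline prefix); one
mismatch can be allowed. Quality filtering keeps reads with mean
Phred ≥ 30 (boundary passes). Amplicon assignment computes
`1 − edit_distance/target_length` against each target's fully converted
sequence with CpG cytosines as the IUPAC code Y, so methylated (CG) and
unmethylated (TG) molecules score identically and assignment cannot bias
the methylation estimate; reads below 0.8 similarity against every
target are rejected, ties resolve to panel order, and reads shorter than
half of every target are unassigned. Edit distance (edlib) rather than
Hamming distance keeps the 80% rule meaningful for reads with indels.

CpG states are read through the alignment: CG → methylated,
TG → unmethylated, anything else (CA, TA, a gap) → ambiguous. A read
must cover every expected CpG; by default one ambiguous site discards
the molecule, which protects the fully-unmethylated count from
miscalling either direction (a lenient mode instead drops the ambiguous
site). Every read lands in exactly one status category and the counts
are reported, so reads are conserved through the pipeline. Distinct read
sequences are memoised — amplicon data is massively redundant, which is
what makes read-level simulation at 30,000 molecules/marker cheap.

## Quantification

`fraction = n_fully_unmethylated / n_pass`; zero coverage propagates as
missing, never zero, so a dropped-out marker cannot deflate a cohort
signal. `GE/mL = fraction × total_cfdna(ng/mL) × 1000 / 3.3` with
3.3 pg/haploid genome (config-exposed; every rank-based cohort statistic
is invariant to this constant). Total cfDNA is the pre-bisulfite
measurement, which makes the absolute scale robust to the 60–90%
molecule loss bisulfite causes — uniform thinning leaves the fraction
estimator unbiased, a property the test suite verifies directly. Cell
type signals are unweighted marker means; the combined brain score sums
the neuron, astrocyte and oligodendrocyte means. Whole-brain markers
respond to the same DNA the cell-type markers already count, so they are
excluded from the sum by default (flag to include). A fraction-based
aggregate (no concentration factor) is emitted in parallel.

## Marker selection

Selection on a beta matrix is worst-case by design: max beta over target
samples ≤ `t_low` (default 0.2) and min beta over every background
sample ≥ `t_high` (default 0.8) — conventional array cutoffs, exposed in
the API since no canonical values exist. Candidates rank by margin
(background min − target max). Whole-brain candidates use the union of
the three brain classes as the target; loci also passing a single class
go to that class (most specific assignment). Loci with a missing beta in
any deciding sample are dropped, not imputed. Group means are *not* used:
a single permissive background tissue disqualifies a locus, matching the
requirement that markers be methylated in *all* other cell types.

## Cohort statistics

Mann-Whitney is exact (full enumeration, via the exact null
distribution) for tie-free samples with `n₁·n₂ ≤ 400`, else normal
approximation with tie and continuity correction; all tests two-sided.
The AUC is reported with a DeLong 95% CI (hand-implemented; a seeded
stratified bootstrap is the alternative) and a p-value against 0.5 from
the Mann-Whitney on the same scores. Sensitivity at 90% specificity uses
only empirical thresholds with specificity ≥ target — conservative, no
interpolation, so the reported operating point is achievable. Scores are
oriented higher-in-patients and never auto-flipped: an AUC below 0.5 is
reported as such.

The drug screen covers 18 variables (13 markers, 4 cell-type averages,
total cfDNA) × 2 dose windows (day of draw, cumulative hospitalization)
× 4 tests, with Benjamini-Hochberg adjustment across the grid
(Bonferroni by flag). Dose records convert to olanzapine equivalents via
an editable YAML of consensus factors; unknown drugs raise rather than
silently contributing zero. Constant inputs and n < 3 yield flagged
missing results.

## Synthetic cohorts and what passing tests show

Cohort defaults emulate the study design this package targets: 29
patients vs 31 controls; brain signal log-normal with control median
1.5 GE/mL and patient median 3.0 (σ_log 0.5) — a two-fold shift that
yields AUC ≈ 0.8 before sampling noise; total cfDNA log-normal, 4.0
ng/mL controls vs 5.2 in patients (σ_log 0.4), a 1.3-fold shift whose
Mann-Whitney p lands near 0.02 at these group sizes. Simulated doses are
independent of the brain signal, i.e. the null the screen is calibrated
against. Two simulation routes exist: a read-level route through the
full FASTQ pipeline, and a fast count-level route
(`simulate_cohort_table`) that draws per-marker binomial counts with the
`c^k` detection factor and reuses the same quantification code — used
for replicate-heavy calibration experiments (problem sizes: 500 null
cohorts for type-I error, 100 cohorts for separation recovery, 10
read-level dilution replicates at 30,000 molecules/marker).

Synthetic data does not emulate: fragment-length structure, PCR
amplification bias and duplicates, CNVs of source tissues, inter-marker
efficiency differences, age/sex effects on cfDNA, or correlated doses.
Passing tests therefore demonstrate the *pipeline's* correctness and
calibration under the stated generative model, not the clinical effect
size; the clinical headline check runs only when a real per-sample table
is supplied.

## Numerical conventions

Similarity ties break to panel order (logged); mean-quality boundary
passes; missing values are "." in TSV output; NaN fractions propagate
through GE/mL; combined score is missing when any component cell type
has no informative marker; all RNG flows through
`numpy.random.Generator` seeded from explicit integers, and identical
seeds give byte-identical FASTQ and tables.
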
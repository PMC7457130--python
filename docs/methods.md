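# Methods

## Scope and data model

The pipeline starts at normalized probe-level intensities: a shared probe
map (chromosome, 1-based position) and, per tumor sample, one BAF value in
[0, 1] and one LRR value per probe, with NaN for missing. Upstream array
normalization (IDAT → BAF/LRR) is out of scope. All internal coordinates
are 1-based inclusive base pairs; UCSC-style inputs (cytoBand.txt) are
converted on read and the converters are exact inverses. Analysis is
restricted to autosomes by default: X/Y LRR is confounded with patient sex
in a mixed cohort, and a flag re-enables them for single-sex designs.
Missing intensities are excluded from every mean and denominator.

## Segmentation

LRR is segmented per chromosome by backward elimination over all candidate
breakpoints. The score of a breakpoint between the two segments currently
flanking it is

    t = |mean_L − mean_R| / (σ · sqrt(1/n_L + 1/n_R)),

a two-sample z-like statistic under a known noise scale σ. Elimination
deletes the globally weakest breakpoint (ties broken by leftmost genomic
position, so output is deterministic) and rescores its neighbours until
every survivor exceeds the threshold `T` (default 10). A cleanup pass then
removes segments shorter than `min_probes` (default 50) by deleting their
weaker flanking breakpoint, ascending score order, unless the whole
chromosome is shorter. The defaults are the standard operating point for
Illumina tumor arrays of this class.

σ is estimated from successive differences, MAD/(0.6745·√2), which is
consistent for Gaussian noise and insensitive to step changes and
outliers; the per-sample σ is the median of per-chromosome estimates
(stabilizes scores on short or highly altered chromosomes) and is floored
at `sigma_floor = 1e−6` so noise-free input remains well-defined.
Missing values are dropped with index bookkeeping and re-absorbed into the
adjacent segment, so segments always partition the probe sequence.

A sparse-Bayesian pre-selection stage, as some published segmenters use
before their backward-elimination step, is deliberately not implemented:
the elimination stage alone honors the standard operating parameters
(score threshold and minimum length) and is fully testable against
brute-force change-point enumeration on small inputs.

## State calling

Each segment takes exactly one of four states from (mean LRR, LOH):

* gain iff mean LRR ≥ 0.075 (inclusive),
* loss iff mean LRR ≤ −0.075 (inclusive),
* otherwise CNNLOH when the segment's LOH fraction ≥ 0.5, else normal.

LOH detection slides a window of 100 consecutive *informative* SNPs
(non-missing BAF; with tumor-only data there are no matched normals to
restrict to germline heterozygous sites). A window is LOH when strictly
more than 80% of its SNPs appear homozygous, defined as BAF outside
(0.1, 0.9). A probe is LOH-flagged when at least one LOH window covers
it; a segment's LOH fraction is the flagged share of its informative
SNPs. The homozygosity rule is symmetric in BAF mirroring (b → 1−b).

Two consequences are worth knowing. First, windows straddling a true
loss/CNNLOH boundary flag up to window−1 probes of the neighbouring
segment; on sparse probe grids a short adjacent copy-neutral segment can
therefore exceed the 0.5 LOH fraction and be called CNNLOH. The effect
shrinks with probe density and the 0.5 segment threshold bounds it.
Second, CNNLOH regions have no LRR step at all, so LRR-only segmentation
(BAF-informed segmentation is out of scope) cannot place their
boundaries: CNNLOH is only called within boundaries that LRR (or a
supplied partition) provides. The recovery tests reflect this split:
gain/loss boundaries are checked end to end, CNNLOH states are checked on
the true partition.

## Burden

A sample's CNV set is its gain and loss segments; CNNLOH is tracked
separately and never counted as a CNV. Size bins are half-open:
[1, 500 kb), [500 kb, 1 Mb), [1 Mb, 5 Mb), [5 Mb, ∞) on the inclusive
span end−start+1. Altered fractions divide the SNPs under a state by the
SNPs in the chromosome or genome, so states plus normal always sum to 1.

## Recurrent regions (MCR calling)

Marker amplitude is the covering segment's mean LRR when it is a gain at
or above +0.1 or a loss at or below −0.1, else zero (these thresholds are
deliberately stricter than the calling thresholds, standard for
recurrence scoring). The marker G-score per direction is the sum of
carrier amplitudes — frequency × mean amplitude × n.

The null permutes each sample's amplitude vector across the genome
independently, preserving per-sample amplitude distributions, and pools
the resulting null G-scores over markers and permutations (default 1,000
permutations). Empirical p per marker is the pooled tail fraction;
q-values are Benjamini–Hochberg within each direction (chosen over the
rank-scaled q variant some tools use: standard and directly testable).
Significance is q < 0.01.

Peaks are extracted by peel-off: take the genome-wide maximal-G
significant marker; the region's boundaries are the intersection of the
carrier segments covering that marker (the minimal common region); remove
those carriers' amplitudes on that chromosome; re-score and repeat until
nothing is significant. The procedure terminates because each round
removes at least one carrier contribution. A confidence-level parameter
(default 0.99) is accepted and recorded for interface completeness but
unused — no boundary widening is applied, so reported regions may be
narrower than those of tools that widen boundaries to a confidence
target.

Carrier status for a finished region requires segments of the matching
state to cover ≥ 50% of the region's span; the opposite state is reported
when it reaches the same coverage, giving the loss / no change / gain
statuses the association layer tests. Region frequency is the carrier
percentage of the whole cohort. With a cytoband file regions are labelled
by band; otherwise by coordinates.

## Association

Region-by-phenotype tables use Pearson's chi-square, Σ(O−E)²/E with
margins-based expectations and **no continuity correction**, df =
(rows−1)(cols−1). The bundled published tables confirm this choice: all
seven key published p-values (and 38 of the 42 overall) are reproduced to
three significant figures only without Yates correction, including 2×2
tables and a table with a zero cell (Fisher's exact test is deliberately
not substituted). Rows are the statuses actually observed for a region;
all-zero rows are dropped and single-status regions are skipped with a
log message. Raw p-values are reported at the p ≤ 0.01 significance
level; no multiple-testing adjustment is applied across regions (a flag
adds supplementary BH q-values). Four of the 42 bundled published
p-values disagree with recomputation in the third significant figure and
appear more coarsely rounded in the source; they are flagged with a wider
tolerance in the fixture data.

The Wilcoxon rank-sum test is two-sided; with both groups ≤ 20 and no
ties the exact null distribution of the rank sum is computed by dynamic
programming (equivalent to enumerating all rank assignments), otherwise a
normal approximation with tie-corrected variance and 0.5 continuity
correction is used. Burden comparisons report the overall CNV-count test
plus one test per size bin (reported as not applicable when a bin is
empty everywhere); three-level grade adds all pairwise tests, the overall
test being grade I versus pooled high grade (II + III).

## Survival

The prognostic subcohort keeps primary lesions with gross total resection
(Simpson I–III; Simpson IV operationalizes subtotal resection) and no
postoperative radiotherapy. A missing radiotherapy column is treated as
"no" with a logged warning.

Cox proportional hazards is fit by Newton–Raphson on the partial
likelihood with Efron tie handling (Breslow by flag), step-halving, and a
divergence guard: |β| > 25 raises a convergence error naming likely
complete separation — expected occasionally at very low event counts.
Wald p-values and 95% CIs exp(β ± 1.96·se) are reported per covariate.
The implementation matches lifelines' estimates on shared data and
additionally exposes the score test at β = 0, whose chi-square equals the
log-rank statistic on tie-free two-group data (verified to 1e−6); the
tie-handling and CI conventions are documented assumptions, matching the
de facto defaults of standard survival software. Kaplan–Meier curves and
the log-rank test itself come from lifelines.

The recurrence scan fits one univariate Cox model per region indicator
and clinical covariate (constant or separated covariates are skipped with
a log message), then one multivariate model over the covariates with
univariate p ≤ 0.05 — no stepwise selection. The combined risk score
stratifies patients by their count of carried prognostic losses, compares
strata by log-rank, and fits the count as a single ordinal covariate to
report a hazard ratio per additional prognostic CNV.

## Synthetic cohorts

The generator emulates Illumina-style tumor-only arrays:

* LRR = shift·purity + N(0, `lrr_noise_sd`), with shifts +0.30 (gain),
  −0.45 (loss), 0.0 (CNNLOH). No published per-state intensity
  distributions exist for the target platform, so these are typical array
  attenuation values, configurable and clearly stand-ins.
* Genotypes are heterozygous with probability 0.35, else AA/BB equally;
  BAF is 0/0.5/1 plus N(0, `baf_noise_sd`) clipped to [0, 1]. Inside
  loss/CNNLOH regions heterozygous BAF moves to 0.5 ± 0.5·purity (the
  lost haplotype chosen per probe); inside gains to (1 ± purity)/(2 +
  purity), i.e. the 3-copy bands 1/3 and 2/3 at full purity. Purity
  (default 1.0) scales LRR shift and BAF displacement linearly.
* Defaults: 100 samples × 20 chromosomes × 1,000 probes (positions
  uniform within 100 Mb chromosomes), LRR noise SD 0.15, BAF noise SD
  0.03. The reference configuration plants six regions — a 30% loss, a
  35% gain, a grade-enriched loss (5%/45%/65% across WHO grades I/II/III),
  a 20% CNNLOH, and two low-frequency losses (8% and 6%) carrying
  recurrence hazard multipliers 5.7 and 5.0 — every region at least 50
  probes at the default density.
* Clinical marginals mirror a 383-patient meningioma cohort (female share
  265/383, grades 331/46/6, median diameter 4.3 cm, Simpson distribution
  122/132/48/81, …); the size split is large iff diameter > 4.3 cm,
  strictly. Recurrence-free survival is exponential with baseline hazard
  7e−4/month, multiplied by the hazard multipliers of carried regions,
  censored administratively at 60 months — roughly a 4–5% event rate in
  the prognostic subcohort, matching the sparse-event regime such studies
  operate in. The generator draws phenotypes independently; real cohorts
  correlate grade, size and recurrence, so passing association tests here
  show calibration and power on planted effects, not robustness to
  confounding.
* Reproducibility: one master seed split by fixed counters (probe map,
  clinical, carriers, survival, one stream per sample), so a cohort is a
  pure function of its config and independent of generation order.

Not modelled: GC waves, probe-specific bias, subclonality, sex
chromosomes.

## Numerical and procedural choices

* Thresholds are inclusive exactly as stated (gain ≥ 0.075, loss ≤
  −0.075, window homozygosity strictly > 80%, carrier overlap ≥ 0.5).
* The LOH homozygosity cut interprets "homozygous-appearing" as BAF
  outside (0.1, 0.9) — i.e. major-allele frequency ≥ 0.9 — the standard
  tumor-only convention.
* Empirical permutation p-values are the literal pooled tail fraction
  (an all-zero matrix yields p = q = 1 everywhere).
* Pipeline stages share one seed; artifacts carry parameter headers and a
  SHA-256 manifest, and reruns are byte-identical. A cohort whose
  prognostic subcohort has no events gets header-only survival outputs
  with a logged warning rather than a failed run (the survival functions
  themselves reject event-free input).
* Test and benchmark problem sizes (scaled cohorts of 12–100 samples,
  500–20,000 markers, 200–1,000 permutations) were chosen as the smallest
  sizes at which each property is stably measurable.

## Known limitations

* Backward elimination is greedy; it matches exhaustive change-point
  search on well-separated steps (tested by brute force at small n) but
  is not guaranteed optimal on pathological noise configurations.
* The score normalization of the original published segmenter is not
  restated in print; results on real data may differ from tools whose T
  statistic is normalized differently.
* CNNLOH boundaries require an LRR-visible neighbourhood or an external
  partition (see State calling).
* MCR boundaries are un-widened carrier intersections and can be narrower
  than confidence-widened published regions.
* Cox fits with a handful of events can separate completely; the package
  flags rather than regularizes (no Firth correction).
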
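# Methods

This note documents the models behind pdxkit: what the synthetic cohort
generator simulates and why, how each analysis is defined, the defaults
that matter, and the choices made where the underlying methodology is
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic cohort generator

The generator (`pdxkit.simulate`) produces the inputs a PDX study's
computational layer consumes — lineage metadata, mutation calls, germline
SNP profiles, copy-number segments, B-allele fractions, expression, fusion
records — with complete ground truth. It simulates *calls*, not reads:
everything downstream of alignment and variant calling is modeled
directly, which is what the analysis modules actually consume.

### Cohort layout

Each case contributes one human tumor, one human normal (both optional)
and `models_per_case` independently engrafted models carried over
`passages_per_model` passages. Samples form a forest: passage 0 points to
the human tumor (or is a root when no human tumor exists), passage *p* to
passage *p − 1*. Defaults (12 cases × 2 models × 3 passages) give a
96-sample cohort that runs in under a second.

### Clonal architecture and the engraftment bottleneck

A case's tumor carries one truncal clone (CCF 1, 60 mutations by default,
plus one clonal driver) and subclones with fixed cancer-cell fractions
(defaults 0.5 and 0.3, 25 private mutations each). At each engraftment,
every subclone independently survives with probability
`bottleneck_survival_prob` (0.5); surviving subclones inherit the lost
subclonal mass proportionally (capped at CCF 1). Each model additionally
fixes 15 private clonal mutations at engraftment, and each passage adds a
small private subclone (3 mutations at CCF 0.35). These two mechanisms —
differential subclone survival and model-private fixation — are what make
passages of one model mutationally closer to each other than to sibling
models of the same case, the heterogeneity signature the similarity module
is designed to measure.

### Read counts and caller provenance

For a variant with cancer-cell fraction *c* in a sample of purity *p*, the
alt count is drawn `t_alt ~ Binomial(t_depth, p·c·m/CN + ε)` with
multiplicity *m* = 1 and total copy number CN = 2 (heterozygous point
mutation in a diploid region; the mutation–CNA interaction is not
modeled), `t_depth ~ Poisson(80)`, sequencing error ε = 0.1 %. Normal
counts use `n_alt ~ Binomial(n_depth, ε)` so the n_VAF ≤ 0.01 filter rule
is exercised. Hence the mean VAF of clonal heterozygous variants
converges to *p*/2 (tested at depth 10,000 to ±0.005).

Caller support is simulated by flagging each variant independently per
applicable caller (SNVs: strelka/mutect/varscan; indels:
strelka/varscan/pindel) with per-caller sensitivities (0.90–0.95), plus
two artifact classes per sample: single-caller low-VAF false positives
(Poisson mean 4) and two-caller germline leak-through with n_VAF ≈ 0.5
(Poisson mean 1). The first class dies on the ≥ 2-caller rule, the second
on the normal-VAF rule — each filter has real work to do.

### Purity

Human tumors draw purity from Beta(8, 8) (centered at 0.5); PDXs from
Beta(17, 3) (centered at 0.85) — engrafted tumors run purer because mouse
stroma replaces human stroma and is removed upstream. Constant overrides
(`human_purity`, `pdx_purity`) exist for noise-controlled experiments.
These distributions are modeling defaults, not estimates.

### Germline SNP panel

A cohort-wide panel (default 1,500 loci) with per-locus population allele
frequencies uniform on [0.1, 0.9]. Each case draws one Hardy–Weinberg
genotype vector shared by all its samples; observed VAFs are binomial
draws at Poisson(60×) depth, missing below 4×.

### Copy number, WGD, TP53 LOH

The genome model is 22 autosomes × 100 Mb. Per case, three binary flags
are drawn: WGD (P = 0.5), TP53 LOH (P = 0.9 given WGD, 0.2 otherwise) and
deletion abundance (same 0.9/0.2 odds structure) — the planted dependence
the association tests must recover. Segments get allele-specific integer
copy numbers: background (2,2) under WGD else (1,1); loss-like events
(single-copy loss, occasionally homozygous deletion) and gain-like events
(gain, occasionally amplification) carve 20–30 % of the genome on the
abundant side and 3–7 % on the other. The observed log2 ratio mixes tumor
copy number with normal contamination and is centered on the sample's
median total copy number, `log2 = log2((p·CN + 2(1−p)) / (p·CN_med +
2(1−p))) + N(0, 0.05)` — the reference-normalization behavior of
coverage-ratio CNA callers, which is why single-copy losses fade at low
purity (a real effect, not a bug). A 6 Mb window around TP53
(chr17:7,678 kb midpoint) is carved as its own segment; under LOH its
B-allele fractions shift to `(p·CN_B + (1−p)) / (p·CN_T + 2(1−p))` with
the B allele on the lost or kept haplotype at random; balanced otherwise.
A fraction of events (default 15 %) is subclonal (clone proportion
uniform on [0.2, 0.8]) and recorded as fractional copy number.

### Expression, fusions, arm spike-ins

Expression is log-like: per-gene baseline N(6, 1), per-sample noise
N(0, 1), and each of 4 groups up-shifts its 40 signature genes by
`effect_size × noise_SD` (default 2 SD). Groups are assigned per case
(uniform, or round-robin with `balanced_expression_groups` for designs
with equal group sizes); samples drift to a random group with
`cluster_shift_prob` (5 %), which is what the cluster-shift score should
catch. Optional per-center gene offsets emulate collection-center batch
effects.

Arm spike-ins plant one alteration class per chosen model — a hotspot
mutation, a whitelist protein change, a high-level amplification or
homozygous deletion segment over the target gene, or an in-frame fusion —
in every passage of the model, plus an expression shift of the target
gene (+6 for activating classes, −4 for deletions). So that planted truth
is exact, the spike target genes are reserved: random mutations, CNA
events and background fusions avoid them. Background fusions include
normal-panel-tagged and low-FFPM records so the fusion filter is
exercised.

### What the generator does *not* emulate

Read-level artifacts (mappability, strand bias, FFPE damage), mouse-read
contamination itself (only its downstream false-positive signature),
mutation–copy-number dosage interaction, clonal evolution *within* a
passage series beyond neutral drift, correlated gene–gene expression
structure, and fusion breakpoint sequences. Passing tests demonstrate
that the algorithms recover structure *of the kind planted, at the planted
effect sizes*; they do not certify performance on real data with artifact
classes the generator lacks.

## 2. Identity QC

Concordance of two samples is the Pearson correlation of their germline
SNP VAFs over loci covered ≥ 8× in both (minimum 200 shared loci for any
verdict). Cohort-level concordance additionally subtracts each locus's
cohort-mean VAF first. The reason: panel loci differ in population allele
frequency, so raw VAF vectors of two *unrelated* individuals share an
AF-driven component — with the default panel this alone produces r ≈ 0.35
between strangers and r ≈ 0.92 between a sample and its 30 %-contaminated
replicate, which no fixed threshold can triage. Locus centering removes
that component: unrelated pairs land near 0, clean same-germline pairs
near 0.96–0.98, 30 %-contaminated pairs near 0.88–0.91, first-degree-like
relatives near 0.5.

Verdict thresholds follow from those separations: **match at r ≥ 0.92**
(between clean-replicate and 30 %-contaminated concordance), **mismatch at
r ≤ 0.40** (between relative-like and unrelated), ambiguous in between —
the contamination signature, reported for manual review. Both are
exposed, not hard-coded.

The pedigree report flags a sample as swapped only when its best-matching
profile sits in another case *and* it no longer matches its own case. The
second condition matters: after a cross-case swap, the swapped-in sample
genuinely carries the germline of its new case-mates, who may numerically
best-match it; they still match their own case and must not be flagged.
Within-case mismatch and ambiguous pairs are reported as pairs (blame
assignment needs the best-match evidence). Singleton cases are
unverifiable, not failed.

## 3. Variant filter cascades

All thresholds are module constants; boundary conventions follow the
discard rules being strict inequalities, so a value *at* a keep-side
boundary survives (tumor VAF exactly 0.05, normal VAF exactly 0.01,
segment length exactly 5 kb, coverage exactly 20). "Total reads" means
site depth (ref + alt) in the respective sample; VAF is alt/depth with
0/0 → 0. The indel-proximity window is ±20 bp around the indel's anchor
(leftmost) position — whether the window should span the whole indel is
ambiguous in common practice; the anchor convention is documented and
oracle-tested. The known-somatic whitelist is a pluggable key set, so
curated databases (COSMIC-like, MC3-like) drop in without code changes;
pathogenicity labels for germline variants are accepted as input rather
than re-derived. Each cascade returns a per-call decision row listing the
rules that failed, so filtering is auditable and `retained ⇔ failed_rules
empty` holds by construction.

## 4. Mutational similarity

Similarity is Jaccard, `|A∩B| / |A∪B|`, on (chrom, pos, ref, alt) keys.
The union denominator is deliberate: when a small PDX mutation set sits
inside a much larger human-tumor set, most PDX mutations can be shared
while the similarity is still far below 1 — which is exactly the regime in
which a model poorly represents its tumor. The overlap coefficient
(`|A∩B| / min`) is available as a switch and reported side by side where
the distinction matters. Two empty sets score 1 with a warning (vacuous
agreement keeps driver-only scopes from poisoning medians); exactly one
empty set scores 0. The human-vs-PDX model score is the median across
passages; models below 0.2 are flagged low-similarity. 1 − Jaccard is a
metric, which the suite property-tests (triangle inequality).

## 5. Copy number, WGD, LOH, associations

Log2 thresholds −1.3/−0.4/0.3/0.9 bin segments into deletion / loss /
neutral / gain / amplification with upper bounds inclusive (`log2 ≤ t`
assigns the lower bin), the usual behavior of threshold-binning CNA
tools. Five bins cannot map one-to-one onto integer copy states 0/1/2/3/>5,
so `integer_cn = round(2·2^log2)` is reported alongside for pipelines
wanting a strict CN > 5 amplification rule. Deletion abundance compares
bp fractions in {deletion, loss} vs {gain, amplification} (strict
inequality; a deletions-only mode is a switch).

The WGD call is a deliberate proxy for full allele-specific factorization:
WGD ⇔ the length-weighted fraction of the genome with major allele copy
number ≥ 2 exceeds 0.5. On integer allele-specific inputs this is exact
by construction; pipelines with a dedicated WGD caller can bypass it.
Missing allele-specific fields yield *not applicable*, never a silent
False. TP53 LOH: mean |BAF − 0.5| > 0.25 over ≥ 10 heterozygous SNPs in
the 6 Mb window (half-width 3 Mb, locus configurable and genome-build
agnostic). The 0.25 threshold corresponds to the imbalance of a clonal
one-allele loss at purity ≈ 0.65+; lower-purity samples genuinely cannot
be called from BAFs alone.

Subclonality: intra-sample ⇔ some retained segment's fractional total CN
deviates from the nearest integer by > 0.1 (a single-copy event deviating
that much implies a clone above the 10 % minimum proportion);
inter-sample ⇔ a categorized non-neutral segment in one sample has no
same-category reciprocal-overlap ≥ 0.5 match in another sample of the
case (the overlap rule is a documented choice).

Associations between binary sample features use Pearson's χ² on the 2×2
table without continuity correction, p from χ²₁; degenerate margins raise
rather than return a misleading p.

## 6. Transcriptional grouping

Genes with ≥ 30 % missing values are dropped; the rest are ranked by
NA-ignoring median absolute deviation, ties broken by gene identifier for
determinism, top 1,000 kept. Genes are z-scaled across samples before
clustering (missing → 0 after scaling).

Consensus clustering subsamples 80 % of samples per iteration (default
1,000 iterations), partitions with k-means (`n_init=3`, seeded; a
hierarchical base partitioner is a switch — k-means is the default for
determinism and speed), and accumulates co-assignment frequencies
normalized by co-subsampling counts. Final labels cut an average-linkage
tree of 1 − consensus. k is selected at the elbow of the consensus-CDF
area curve: the area under the consensus CDF is 1 − mean(consensus); its
relative gain Δ(k) rises while added clusters capture real structure and
collapses after; the chosen k maximizes the fold-drop Δ(k)/Δ(k+1) among
candidates with Δ(k) ≥ 0.1. This sharpened elbow is needed because
k-means splits of a true cluster are themselves fairly consistent, so
Δ(k) does not fall to zero beyond the true k; the fold-drop criterion
recovers both a planted k = 2 and a planted k = 4 reliably. A `force_k`
override replaces manual inspection.

Group DEGs: one-vs-rest two-sided Wilcoxon rank-sum per gene, BH-FDR
within each comparison, reported at FDR < 0.05 with fold change
(group mean / rest mean, on the supplied scale) > 1; groups smaller than
3 are skipped with a warning. The cluster-shift score of a model is the
largest fraction of its samples assigned to one group (1 = perfectly
stable). Cis/trans tests exclude silent mutations when defining the
mutated group, test each target with Wilcoxon, BH-correct across targets
and report FDR < 0.1 with direction; cis means the target is the query
gene itself.

The rank-sum implementation uses the exact null distribution whenever it
is cheap and valid (tie-free, smaller group ≤ 15, total ≤ 100) and the
normal approximation beyond — so small-sample p-values agree with
brute-force enumeration exactly, and a handful of mutated samples against
a large wild-type background can still reach the deep tail p-values that
survive correction across thousands of targets (the normal approximation
saturates near 10⁻⁵ there even under complete separation).

Batch adjustment between collection centers is a median-alignment
stand-in: per gene, each center's median is subtracted and the global
gene median restored; centers of size 1 pass through with a warning. It
removes location shifts only (not scale or covariance effects); an
externally adjusted matrix can be supplied instead.

## 7. Arm matching and S_arm

Arm rules are data (JSON/YAML): inclusion criteria over five alteration
classes, disease exclusions, optional biomarker requirements. The bundled
default set is illustrative (PI3K, BRAF-V600, HER2-amplification,
CDKN2A-deletion and FGFR-fusion arms); real trial criteria load at the
same interface. Amplification/deletion criteria match the gene-level
category (max-overlap retained segment); deletion means the homozygous
class, not single-copy loss. Fusions match on either partner unless a
rule demands 5′-only. Matching is monotone: adding alterations never
removes a match; adding exclusions never adds one.

`S_arm` bins the relevant PDX samples by passage index; a bin is positive
if at least one sample with that index carries the matching alteration
**in its own data** (per-sample re-detection, not inheritance — the
conservative reading of persistence); `S_arm = positive bins / N_pb`. By
default N_pb counts the passage indices present among the arm's matched
models; a cohort-wide-bins variant is a switch, since "across the cohort"
admits both readings.

## 8. Problem sizes and determinism

Test and acceptance runs use deliberately small cohorts chosen to make
the targeted effect measurable with comfortable margins: 96-sample default
cohorts for end-to-end checks; 100 two-case cohorts for the intra/inter
similarity win rate; 50 swap and 20 contamination cohorts on 1,200-locus
panels; 2,000 null simulations at n = 100 for χ² calibration and 50–100
twenty-case cohorts (~100 tumor samples each) for planted-association
detection; one 200-sample noise-controlled cohort (purity 0.9, log2 noise
0.02, clonal events only) for WGD/LOH accuracy; 10–20 cohorts of 120
samples (4 balanced groups × 30, 2-SD signatures, 600 genes, top 300 by
MAD, 80 consensus iterations) for clustering recovery; 10⁴ random
patterns for the S_arm and shift-score brute-force identities. All
randomness flows from explicit seeds; fixing the seed fixes every emitted
byte of a generated cohort.

## 9. Known limitations

* The WGD proxy needs allele-specific copy numbers; purity/ploidy and
  clone deconvolution are out of scope.
* TP53 LOH from BAFs is blind below purity ≈ 0.6 and in regions where
  the 6 Mb window is not covered by informative SNPs.
* The batch stand-in corrects location only; strong center-specific
  scale effects call for an external adjustment.
* Filter thresholds are calibrated for WES-scale depths; deep-targeted
  panels would warrant different VAF floors.
* The generator's independence assumptions (genes, loci, segments) make
  planted structure easier to recover than real correlated data; treat
  recovery rates as upper bounds.
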
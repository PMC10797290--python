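# Methods

This note documents the statistical procedures implemented in `nescore`,
the choices made where conventions differ, and what the synthetic data do
and do not establish.

## Single-sample enrichment engines

**ssGSEA.** For one column, genes get ascending average ranks r (least
expressed = 1, most expressed = N; ties share their average rank). Walking
the genes from most to least expressed, an in-set gene at position i adds
`r_i^α / Σ_{g∈S} r_g^α` to the hit CDF and an out-of-set gene adds
`1/(N−|S|)` to the miss CDF. The enrichment score is
`ES = Σ_i (P_hit(i) − P_miss(i))` over all N positions — the integrated
running sum that defines the single-sample variant, not the max-deviation
statistic of two-group GSEA. The weight exponent α defaults to 0.25, the
default of the widely used GSVA implementation of ssGSEA, and is exposed.
Raw scores of a cohort (up and down lists pooled) are normalized by their
overall max−min range; a degenerate zero range maps everything to 0. Joint
normalization is what makes the up/down difference antisymmetric under
exchanging the lists.

**AUCell.** Genes are ranked descending; within the top `⌈f·N⌉` ranks
(f = 0.05 by default, the AUCell tool's `aucMaxRank` convention) the
recovery curve counts in-set genes found at each rank. The score is the
area under this step curve divided by the maximal achievable area (all
in-set genes at the top), so it lies in [0, 1] with 1 meaning perfect
recovery. Because only ranks enter, raw counts, CPM or log-normalized
values give identical scores.

**Ties and determinism.** Tied expression values receive average ranks for
the ssGSEA weights; positions along the ranked list use a stable descending
sort, so input gene order breaks ties reproducibly. Everything is
deterministic for fixed inputs and parameters.

**Risk score.** `risk = NES_UP − NES_DN`, with `NES_DN ≡ 0` when the down
list is empty. Signature genes absent from the matrix are dropped before
scoring; the retained fraction is recorded, below 30% coverage of the up
list a warning is stored in the score table's params, and zero coverage is
an error. ssGSEA requires a TPM or log matrix (it errors on raw counts to
force an explicit normalization decision); a declared-TPM matrix whose
maximum is below 50 is rejected as probably already logged. AUCell accepts
any kind.

## Differential expression and signature derivation

**Cell QC.** Cells with fewer than 250 detected genes, fewer than 500
transcripts, or more than 20% mitochondrial content are removed; the
thresholds are strict on the removal side, so a cell exactly at a boundary
is retained. Mitochondrial genes are recognized by symbol prefix (`MT-`
human, `mt-` mouse) rather than a fixed list, keeping the rule
species-portable. A cell failing several criteria is counted under each in
the report but removed once. "High-dropout" genes are operationalized as
detection in fewer than 0.1% of cells (no published cutoff exists; the
parameter is exposed).

**Wilcoxon rank-sum DE.** Per gene, a two-sided rank-sum test of group A vs
B. When both groups have ≤ 8 members the p-value comes from full
enumeration of all C(n_A+n_B, n_A) group assignments of the observed
(midrank-tied) ranks — tie-safe and exact; two-sided p is twice the smaller
tail, capped at 1, so a fully separated 4-vs-4 gives p = 2/70. Larger
groups use the normal approximation with the standard tie correction and a
0.5 continuity correction. Full enumeration beyond 8 per group is
combinatorially infeasible and closed-form exact methods are not
tie-corrected, so 8 is where the exact regime ends; in practice pseudobulk
contrasts (tens of samples) and cell-level contrasts (hundreds of cells)
both fall in the asymptotic regime. Fold changes follow the single-cell
convention: `avg_log2FC = log2(mean(2^x − 1) + 1) − log2(...)` computed on
log2(x+1)-scale data (counts/TPM are transformed first), with pct_in /
pct_out the nonzero detection fractions. Bonferroni and Benjamini–Hochberg
corrections are available; the derivation pipeline uses Bonferroni.

**Feature genes and thinning.** Pseudobulk DEGs passing |avg_log2FC| ≥ 0.5
and adjusted p < 0.01 enter the feature-gene set when at least
`support_min` (default 1) of the other evidence streams — the published
marker meta-set or the co-expression module genes — also contain them; the
per-gene provenance is retained. The exact intersection arity of the
original construction is not published, hence the parameter. Thinning keeps
feature genes that are also cell-level NE-vs-rest markers at the same
thresholds, with up genes additionally required to be detected in more than
20% of NE cells; the detection floor applies only to the up direction,
since genes lost in NE cells are lowly detected there by construction.
Both steps are monotone in their thresholds: relaxing any threshold never
shrinks the gene lists.

**Pseudobulk contrast.** Cells are summed per sample and the NE-rich
samples are tested against the rest at sample resolution, after
counts-per-million normalization (the TPM routine with unit lengths). The
contrast definition ("NE-rich vs other tumor samples") is the package's
reading of a derivation whose grouping is not spelled out upstream.

## Evaluation

`roc_auc` is the Mann–Whitney U statistic divided by n⁺·n⁻, ties counted
0.5. `concordance_index` is Harrell's C over comparable pairs (an event
before a later event or a later censoring; score ties 0.5); with all
subjects sharing one event time it reduces exactly to the AUC. Scores are
oriented higher = riskier, and a C below 0.5 is reported as-is — silent
flipping would hide sign errors. Correlations use scipy's Pearson/Spearman
with their t-based p-values. Survival stratification splits at the median
(ties to the low-risk group; an explicit cutpoint can be given) and reports
the 1-df log-rank chi-square and p via lifelines, with the per-group
Kaplan–Meier step functions exposed for plotting. Signature comparison
scores every signature on identical columns, ranks by AUC with
deterministic name tie-breaks, and isolates per-signature failures.

## Synthetic data

The generators exist so every stage is testable without controlled-access
cohorts; their defaults are the package's study conditions.

**Bulk cohort** (default n = 100 samples × 500 genes): each sample is
`(1−f)·adeno + f·NE` on the linear scale with f ~ U(0, 1); the NE program
multiplies the 50 planted up markers by 2^2 and divides the 20 down markers
by the same factor; multiplicative log-normal noise (σ = 0.25) is applied
and columns are renormalized to TPM. Baseline abundances are log-normal
(natural-log mean 1.8, sd 1.0), spanning roughly three orders of magnitude.

**Single-cell atlas** (default 2,000 cells, five cell types, 500 genes, 32
donors of which half are NE-rich): negative-binomial counts with dispersion
θ = 2 and per-cell log-normal library factors (σ = 0.3). Marker means are
set analytically from detection targets by inverting the NB zero
probability, `μ = θ((1−p)^(−1/θ) − 1)`: planted markers are detected in
≈60% of cells of their expressing group and ≈5% elsewhere, with the
configured fold change as a floor (at these defaults the detection targets
imply ≈4.5-fold, which dominates). NE cells are placed only in NE-rich
donors so the pseudobulk contrast carries the planted program. The 32-donor
design is a power choice: with 16 vs 16 samples a fully separated rank-sum
test reaches p ≈ 1.4×10⁻⁶, which survives Bonferroni correction over 500
genes at the 0.01 threshold, whereas cohorts of ≤ 12 per arm cannot reach
that threshold at all. The baseline abundance is set high enough that
nominal cells clear the QC thresholds with a wide margin on a 500-gene
panel — the thresholds were calibrated for whole transcriptomes — so the
optional planted violators (cycling low-genes / low-counts / high-mito) are
exactly the cells QC removes.

**Survival**: exponential event times with rate
`h₀·exp(β·z)` on the standardized score (defaults h₀ = 0.05/month, β = 1),
censored by an independent U(0.01, 60) months time.

What the simulations do **not** contain: batch effects, realistic gene–gene
correlation beyond the planted programs, doublets, ambient RNA, partial NE
differentiation states, or platform-specific dropout. Passing the planted
recovery and calibration tests therefore shows the algorithms are
implemented correctly and are well calibrated under their own model — not
that the derived signatures will transfer to any particular clinical
cohort.

## Numerical and interface choices

* Gene symbols are matched case-sensitively after trimming; cross-species
  use goes through the ortholog mapper (explicit 2-column table, or the
  ALL-CAPS ↔ Title-case heuristic), which errors when more than half of the
  up list is unmapped.
* Duplicate gene rows collapse by sum for counts/TPM and by max on the log
  scale; MatrixMarket files are 1-based on disk, 0-based in memory.
* TPM conversion drops genes without a supplied length and guarantees
  column sums of 10⁶ to 10⁻⁶ relative.
* The pipeline writes a resolved-config copy and a manifest with SHA-256
  checksums, package version, config hash and seed next to its outputs;
  provenance lives in the manifest rather than in per-file comment headers
  so every table stays plainly machine-readable. Partial outputs of a
  failed run are renamed `*.partial`.
* All simulation randomness flows from one seeded `numpy` generator; the
  survival generator offsets the seed so attaching survival does not
  perturb expression draws.

## Known limitations

* The ssGSEA normalization is per scoring run (cohort); scores are not
  comparable across separately scored cohorts without re-normalization.
* The exact-enumeration DE regime ends at 8 per group; between 9 and ~25
  the normal approximation is used where a specialized exact algorithm
  could in principle do better on tie-free data.
* Harrell's C is the only concordance variant; no time-dependent ROC
  estimator, Cox model or hazard ratios are provided.
* The AUCell engine scores bulk columns happily (it is just rank-based),
  but its top-fraction window makes it less sensitive than ssGSEA for
  mixtures dominated by a minority program.
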
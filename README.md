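# nescore

Derivation, scoring and evaluation of neuroendocrine (NE) transcriptional
signatures for prostate cancer, in bulk and single-cell RNA-seq.

Neuroendocrine prostate cancer (NEPC) is an aggressive, androgen-receptor–
independent subtype that emerges from adenocarcinoma under treatment
pressure. Published NE marker lists disagree with each other and many of
their genes are not actually expressed by NE tumor cells, so bulk-derived
signatures recognize NEPC poorly. `nescore` implements the workflow that
fixes this: derive a cell-intrinsic up/down signature from single-cell
evidence, score any sample or cell with rank-based single-sample enrichment,
and quantify how well the score discriminates, correlates and stratifies.
It is aimed at computational biologists who have expression matrices and
want a reproducible NE risk score without touching R.

## The model

Given an up-regulated gene list *U* and a down-regulated list *D*, each
column (sample or cell) receives a risk score

```
risk = NES_UP − NES_DN
```

where `NES_UP` and `NES_DN` are single-sample enrichment scores of *U* and
*D* in that column. Two engines are provided:

* **ssGSEA** (bulk): genes are ranked within the sample; in-set genes add
  `rank^α / Σ rank^α` to the hit CDF, out-of-set genes add `1/(N−|S|)` to
  the miss CDF, and the enrichment score is the running difference summed
  over *all* rank positions (the integrated single-sample statistic, not
  classic GSEA's maximum deviation). Raw up/down scores of a cohort are
  jointly normalized by their max−min range. `α = 0.25` by default.
* **AUCell** (single cell): the score is the area under the in-set gene
  recovery curve within the top fraction of ranked genes (5% by default),
  normalized so a cell whose in-set genes occupy the very top ranks scores
  exactly 1.

Both engines use only within-column ranks, so they are invariant to any
monotone per-column normalization (TPM vs log2(TPM+1), library depth, …).

Signature derivation mirrors the single-cell construction: QC-filter cells
(<250 detected genes, <500 transcripts, or >20% mitochondrial content
removed), pseudobulk Wilcoxon rank-sum DE of NE-rich vs adeno samples with
Bonferroni correction (|avg_log2FC| ≥ 0.5, adjusted p < 0.01), intersection
with independent evidence streams (published marker meta-sets, co-expression
modules) into the feature-gene set, then thinning against cell-level
NE-vs-rest markers keeping up genes detected in >20% of NE cells.

## Worked example

```python
import nescore as ns

# a synthetic bulk cohort: 100 samples mixing an adeno and an NE program,
# with the true NE fraction of every sample recorded
cfg = ns.SimConfig(seed=1)
expr, ann, truth = ns.simulate_bulk_cohort(cfg)

table = ns.risk_score(expr, truth, method="ssgsea")
print(table.scores.head(3).round(4))

frac = ann.column("ne_fraction", table.scores.index)
r, p = ns.correlate(table.risk.to_numpy(), frac.to_numpy())
auc = ns.roc_auc(table.risk.to_numpy(),
                 ann.column("ne_status", table.scores.index).to_numpy())
print(f"Pearson r(risk, NE fraction) = {r:.3f} (p = {p:.2e})")
print(f"AUC for NE status = {auc:.3f}")
```

prints

```
         ES_up     ES_dn  NES_UP  NES_DN    risk
id
B001  171.8211 -112.1314  0.4478 -0.2923  0.7401
B002  134.8607  -34.1140  0.3515 -0.0889  0.4404
B003   66.8176  -18.4566  0.1742 -0.0481  0.2223
Pearson r(risk, NE fraction) = 0.988 (p = 3.42e-82)
AUC for NE status = 0.994
```

`ES_*` are the raw enrichment scores, `NES_*` the range-normalized ones and
`risk` their difference: sample B001 is mostly NE (high up-enrichment, low
down-enrichment), and across the cohort the score tracks the true NE
admixture almost perfectly and separates NE-high from NE-low samples.

The same flow is available from the shell:

```bash
nescore simulate bulk  --seed 1 --out-dir cohort/
nescore score    --expr cohort/expression.tsv --kind tpm \
                 --sig-up cohort/truth_up.txt --sig-dn cohort/truth_dn.txt \
                 --method ssgsea --out scores.tsv
nescore evaluate --scores scores.tsv --labels cohort/truth.tsv \
                 --label-col ne_status --out report.tsv
```

plus `nescore simulate atlas`, `nescore derive` (signature derivation from a
single-cell atlas) and `nescore pipeline` (everything end to end, with a
checksummed manifest).

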
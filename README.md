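# driftomics

Multi-omics analysis of brain-aging signatures and their pharmacological
suppression: transcriptomic/metabolomic **drift** statistics,
differential gene and metabolite calling, metabolite-set enrichment,
and gene+metabolite **network integration** with a permutation capture
null — plus a seeded synthetic-data generator so every stage is testable
without external data.

## The problem

Aging drags the transcriptome and metabolome away from their young
state: individual features shift up or down, and the *spread* of those
shifts grows. Given expression tables (counts/FPKM), metabolite
abundance tables with missing values, and a four-group design (young,
old, old+treatment A, old+treatment B), this package asks:

1. **How dysregulated is each group?** Per-feature drift
   `md = log(x / x̄_young)` is pooled within groups; its variance
   quantifies dysregulation, compared across groups with the
   Brown-Forsythe test. A treatment that suppresses aging pulls the aged
   drift variance back toward the young baseline.
2. **Which features move?** Genes: CPM > 1 in at least half the samples,
   TMM normalization, Welch tests on log2-CPM, significance at
   FDR < 0.05 and |log2FC| > 0.3. Metabolites: minimum-value imputation,
   glog variance stabilization, Welch tests at FDR < 0.05.
3. **Where do they concentrate?** Metabolite-set enrichment
   `score = (k/m)/(K/M)` ("altered/detected" relative to the background
   rate) with a hypergeometric p-value, and Fisher overlap tests between
   signatures.
4. **Do genes and metabolites agree on a mechanism?** A
   metabolite-reaction network (edges annotated with enzyme genes) is
   scored by `-log10(p) + log10(p0)` per feature, and the
   maximum-weight connected subgraph (active module) is extracted.
   Whether a hub metabolite (acetyl-CoA) appears in the module by chance
   is estimated by shuffling feature identifiers: `pnull` is the capture
   fraction over 10 shuffles, and evidence across experiments aggregates
   as `p = pnull^na · (1-pnull)^nb`.

## Worked example

```python
import driftomics as d
from driftomics.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="out", seed=1, synth=d.SynthConfig(seed=1))
summary = run_pipeline(cfg)
```

With the default synthetic study (4 groups × 6 samples, 2000 genes of
which 5% age-shifted with log2FC spread 0.8, treatment suppression
A = 0.9 / B = 0.5, the five TCA-panel metabolite folds, a 50-node
network with the module planted around acetyl-CoA) this prints into
`out/summary.json`:

```text
drift variances:  young 0.0514 < old+A 0.0708 < old+B 0.0755 < old 0.0883
Brown-Forsythe old vs young: F = 410.0, p = 3.3e-90
DE genes:        old_vs_young 23, old+A_vs_old 11, old+B_vs_old 0
DE metabolites:  5 per contrast (the planted TCA panel)
top enrichment:  planted_module  score 10.0 (5/5 altered/detected), p = 4.7e-07
network module:  {acetyl-CoA, aconitate, alpha-ketoglutarate, citrate, succinate}
capture null:    pnull = 0.2, na=1, nb=0 -> random-sampling p = 0.2
```

Read: drift variance interpolates between old and young exactly as the
suppression factors dictate; the module search recovers the planted
TCA neighborhood around the acetyl-CoA hub; and identifier shuffling
says a capture this specific would occur in ~20% of label-randomized
reconstructions of this single experiment.

The same stages are available from the shell:

```bash
driftomics simulate --seed 1 --outdir data
driftomics run-all --seed 1 --outdir out
driftomics drift --matrix data/fpkm.tsv --metadata data/metadata.tsv --pseudocount 5
```

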
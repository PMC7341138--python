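# nucsens

TSS-anchored nucleosome occupancy and MNase-sensitivity analysis for
paired light/heavy micrococcal-nuclease digests.

## The problem

Micrococcal nuclease (MNase) preferentially digests linker DNA and
releases nucleosome-protected ~150 bp fragments, so paired-end MNase-seq
fragment midpoints map nucleosome positions. Digesting the same
chromatin at a *light* (low) and *heavy* (high) MNase concentration
additionally reveals which nucleosomes are fragile: fragments
preferentially released by the light digest are **MNase-sensitive
fragments (MSFs)**, fragments that survive the heavy digest are
**MNase-resistant fragments (MRFs)**. At promoters, the sensitivity of
the −1/+1 nucleosomes flanking the transcription start site (TSS)
tracks transcriptional activity and regulatory-factor binding, and can
shift within minutes of an immune stimulus.

`nucsens` is for genomicists who have aligned light/heavy mononucleosome
fragment intervals per condition (e.g. a stimulation time course) and
want the standard promoter-centric analysis:

1. mononucleosome size selection (default 140–160 bp);
2. TSS-anchored fragment-midpoint matrices: 60 bp windows at a 10 bp
   step across TSS ± 1 kb, in fragments per million (FPM) mapped to the
   captured promoter regions, strand-oriented;
3. the MNase-sensitivity statistic per gene × window cell,

   `S = log2((L + c) / (H + c))`,

   with `L`/`H` the light/heavy FPM values and pseudocount `c = 1`;
   `S > 0` ⇒ MSF, `S < 0` ⇒ MRF;
4. heatmap-style sorting: per-gene maximum signal, expression quartiles,
   maximum-sensitivity quartiles, k-means promoter sets, per-cluster
   average profiles;
5. a paired *t*-test of per-gene mean sensitivity over the −1-nucleosome
   band (window centers in −200..0 bp) between a treated condition and
   its baseline, `t = mean(d) / (sd(d)/√n)` on n−1 df;
6. ENCODE narrowPeak regulatory-factor matrices overlaid in a shared
   sort order, and a Spearman check of expression vs differential
   occupancy.

Because real deposited sequencing data are too large to ship, the
package includes a first-class synthetic digestion simulator
(`nucsens.simulate`) with ground truth — positioned nucleosomes at the
canonical −3…+3 offsets around a nucleosome-free region, per-nucleosome
digest-dependent release probabilities, expression tiers, and TF peaks
in the NFR — used by the test suite and the recovery benchmark.

## Worked example

Simulate a two-condition study (100 promoters; the treated condition
doubles the light-digest release probability of the −1 nucleosome in
top-expression-quartile genes) and run the full analysis:

```bash
nucsens simulate --seed 7 --out data
nucsens run-all --config pipeline.yaml
```

with `pipeline.yaml`:

```yaml
fragments:
  untreated: {light: data/fragments_untreated_light.bed, heavy: data/fragments_untreated_heavy.bed}
  20min:     {light: data/fragments_20min_light.bed,     heavy: data/fragments_20min_heavy.bed}
tss: data/tss.bed
expression: data/expression.tsv
peaks: {synthTF: data/peaks_synthTF.narrowPeak}
baseline: untreated
k: 4
outdir: results
```

This prints:

```
Promoter nucleosome occupancy / MNase-sensitivity analysis
============================================================
genes: 100   windows: 195   conditions: untreated, 20min
baseline: untreated   -1 band: -200..0 bp

Paired t-tests vs untreated (band mean log2 light/heavy per gene):
  paired t-test (20min vs untreated, expression Q1, band -200..0 bp): n=25, mean diff=0.3122, t=6.588, df=24, p=8.175e-07
  paired t-test (20min vs untreated, expression Q2, band -200..0 bp): n=25, mean diff=0.01163, t=0.2205, df=24, p=0.8273
  paired t-test (20min vs untreated, expression Q3, band -200..0 bp): n=25, mean diff=-0.06995, t=-1.362, df=24, p=0.1858
  paired t-test (20min vs untreated, expression Q4, band -200..0 bp): n=25, mean diff=-0.02006, t=-0.4039, df=24, p=0.6898
  paired t-test (20min vs untreated, all genes, band -200..0 bp): n=100, mean diff=0.05846, t=2.018, df=99, p=0.04632
k-means (untreated, k=4): 1:16, 2:13, 3:38, 4:33
k-means (20min, k=4): 1:18, 2:27, 3:23, 4:32
```

Reading the numbers: the planted −1 sensitivity gain is confined to the
top expression quartile — its mean band sensitivity rises by 0.31 log2
units after treatment (p ≈ 8e−7), while quartiles Q2–Q4 show no
significant change. `results/` holds the occupancy and sensitivity
matrices (TSV, `NA` sentinel), MSF/MRF label matrices, sort orders,
quartile and cluster assignments, cluster mean profiles, the peak
matrices in the 20 min maximum-sensitivity sort order, and a run log of
every default applied.

The same analysis is available as a library via statsmodels-style
objects:

```python
from nucsens import PipelineConfig, run_full_analysis
results = run_full_analysis(PipelineConfig.from_yaml("pipeline.yaml"))
print(results.summary())
results.plot_heatmap("20min", "sensitivity_20min.png")
```

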
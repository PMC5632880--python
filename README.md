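# mitomir

Profiling mitochondria-enriched microRNAs (mitomiRs) in failing hearts from
pooled compartment-fractionation small-RNA data.

Studies of pressure-overload heart failure (transverse aortic constriction,
TAC, in mice) often sequence a *single pooled library* per group — here one
library per (compartment, condition) with compartments = {mitochondrial
fraction, whole-tissue RNA} and conditions = {sham, 4-week TAC, 8-week
TAC}. With no replicates, differential expression must come from an exact
two-library test, and a miRNA only counts as genuinely
mitochondria-enriched if it rises in the mitochondrial fraction *without*
rising in whole tissue, since the fraction always carries cytosolic
contamination. This package implements that full analysis chain for
computational biologists who want it reusable and testable:

- **Exact two-library DE** (`mitomir.de`): the exact Poisson test in its
  conditional form — under H₀, x₁ | x₁+x₂ = n ~ Binomial(n, N₁/(N₁+N₂)) —
  with a two-sided minimum-likelihood p-value, CPM normalization, log₂ fold
  changes with a pseudocount, Benjamini–Hochberg FDR, threshold calls
  (fold > 2 up, fold < 0.5 down, p < 0.05) and 1−Pearson average-linkage
  clustering for heatmap export.
- **ΔΔCt qPCR quantification** (`mitomir.qpcr`): ΔCt = AvgCt(target) −
  AvgCt(reference) over triplicates, ΔΔCt between conditions, fold change
  2^(−ΔΔCt).
- **Cross-compartment mitomiR calls** (`mitomir.classify`): enriched ⇔
  mitochondrial fold > 2 (significant where a p-value exists) and
  whole-tissue fold ≤ 1.2 ("decreased or unchanged").
- **Pathway enrichment** (`mitomir.enrich`): union target set of a miRNA
  list at a strict microT-style score cutoff (> 0.9), one-sided
  hypergeometric upper tail per pathway against a gene universe, BH across
  pathways.
- **Synthetic data with ground truth** (`mitomir.simulate`): pooled Poisson
  (or negative-binomial) count libraries with planted mitomiRs, cytosolic
  contamination of the mitochondrial fraction, matching Ct triplicates and
  toy target/pathway annotations with one planted pathway.

## Worked example

Run the whole pipeline on synthetic data (defaults: 300 miRNAs, 2×10⁶-read
libraries, 20 planted mitomiRs with an 8-fold early mitochondrial effect,
20% contamination):

```sh
mitomir all --seed 0 --out-dir run0
```

prints

```json
{
 "de_counts": {
  "sham_vs_tac4w": {"ns": 280, "up": 20},
  "sham_vs_tac8w": {"ns": 300},
  "tac4w_vs_tac8w": {"down": 20, "ns": 279, "up": 1}
 },
 "false_positive_rate": 0.0,
 "n_candidates": 20,
 "n_enriched": 20,
 "planted_pathway": "path000",
 "sensitivity": 1.0,
 "top_pathway": "path000"
}
```

Reading: the early-stage (sham vs 4-week) exact test calls 20 miRNAs up —
exactly the planted mitomiRs; none survive at 8 weeks where the planted
effect shrinks to 2-fold against a 1.47× renormalization drag; the
cross-compartment classifier keeps all 20 (sensitivity 1.0) and rejects
every unplanted miRNA (false-positive rate 0.0); and the planted pathway
ranks first in the enrichment of the enriched miRNAs' targets. Artifacts
(`counts.tsv`, `de_*.tsv`, `ct.csv`, `qpcr_*.tsv`, `mitomir_calls.tsv`,
`enrichment.tsv`, `heatmap.tsv`, `manifest.json`) land in `run0/`; the same
seed reproduces them byte for byte.

The stages are also plain functions, e.g.

```python
from mitomir import exact_poisson_test
exact_poisson_test(10, 0, 1_000_000, 1_000_000)  # 0.001953125 = 2/2**10
```

The package also bundles the published per-miRNA DE summary (log₂ fold
change and exact-test p, TAC vs sham, mitochondrial fraction) via
`mitomir.datasets.load_tac_de_summary()`; applying the standard thresholds
to those rows yields 2 down-regulated miRNAs at 4 weeks and 6 at 8 weeks.

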
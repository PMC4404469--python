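# refstab

Reference-gene stability analysis for RT-qPCR expression data.

Relative RT-qPCR quantification needs a normalizer: a reference
("housekeeping") gene whose expression is stable across the tissues,
treatments and time points of an experiment. Because no gene is universally
stable, candidate panels must be validated empirically. `refstab`
implements the two standard validation algorithms and everything around
them, from raw quantification-cycle (Cq) tables to a consensus ranking:

- **geNorm** — pairwise expression stability. For genes *j, k* with
  relative quantities *q* over samples, the pairwise variation is
  V<sub>jk</sub> = SD<sub>s</sub>(log₂ q<sub>js</sub>/q<sub>ks</sub>) and a
  gene's stability is M<sub>j</sub> = Σ<sub>k≠j</sub> V<sub>jk</sub>/(G−1).
  The least stable gene (highest M) is removed and M recomputed until a
  best pair remains. The series V<sub>n/n+1</sub> =
  SD(log₂ NF<sub>n</sub>/NF<sub>n+1</sub>) over normalization factors
  (per-sample geometric means of the n most stable genes) decides how many
  reference genes are needed; V ≤ 0.15 is the conventional "n genes
  suffice" cutoff, and M ≤ 0.5 (≤ 1 for heterogeneous panels) marks a gene
  as stable.
- **NormFinder** — a model-based decomposition. Log₂ expression is modelled
  per sample group as a two-way layout y<sub>igj</sub> = α<sub>ig</sub> +
  β<sub>gj</sub> + ε<sub>igj</sub>; unbiased intra-group variances
  σ̂²<sub>ig</sub> and shrunken differential group effects d̃<sub>ig</sub>
  combine into a per-gene stability value (lower = more stable).
- **Consensus** — each algorithm's ordering becomes integer weights 1..G
  (ties share the mean) and genes are re-ranked by the geometric mean of
  their weights across methods.

Supporting modules handle Cq I/O (long/wide CSV), RNA-quality filtering
(RQI and A260/280 thresholds), technical-replicate averaging, standard-curve
fitting with the efficiency formula E(%) = (10^(−1/slope) − 1) × 100, the
ΔCq relative-quantity transform, and a synthetic Cq generator with known
ground truth that emulates a factorial plant study design (4 tissues ×
PGPR inoculation × 3 temperatures × 3 sampling weeks, 3 biological and 2
technical replicates).

`GeNorm`, `NormFinder` and `CqQuantityTransformer` are scikit-learn-style
estimators (`fit` on a samples × genes matrix, fitted attributes with
trailing underscores), so they compose with sklearn pipelines; every
operation is also available as a plain function.

## Worked example

Generate a synthetic dataset with a known stability ladder and analyse it:

```bash
refstab simulate --fixture paper_design --seed 7 --out sim
```

```python
from refstab import *

table, meta = read_cq_table("sim/cq_long.csv", layout="long")
qc = qc_filter_samples(meta)                      # RQI > 7, 1.9 <= A260/280 <= 2.1
agg, bio_meta = aggregate_technical_replicates(table, meta)
q = cq_to_quantities(agg)                         # 2^(-dCq), calibrator = min Cq
res = genorm_analysis(q)
nf = ungrouped_stability(log_transform(q))
cons = consensus_rank({"genorm": [res.final_pair] + list(reversed(res.exclusion_order)),
                       "normfinder": nf.stability_order})
```

With seed 7 this prints (10 genes × 144 technical-replicate wells, all 144
passing QC, averaged to 72 biological samples):

```
geNorm best pair: ('alpha_tub', 'CAC') shared M = 0.147
V series: [(2, 0.113), (3, 0.119), (4, 0.118), (5, 0.144), (6, 0.165), ...]
recommended n: 2
NormFinder: alpha_tub 0.000, CAC 0.000, UBQ 0.293, ...
consensus:  ['alpha_tub', 'CAC', 'UBQ', 'PP2a', 'GAPDH', 'beta_actin',
             'RUBISCO', '18S_rRNA', 'EF1a', 'alpha_actin']
```

The generator planted log₂ noise SDs of 0.05 (CAC) and 0.1 (alpha_tub) at
the quiet end and 1.7 (alpha_actin) at the noisy end; both algorithms
recover the pair, V₂/₃ = 0.113 ≤ 0.15 says two reference genes suffice, and
the consensus reproduces the planted order. (The NormFinder zeros are the
documented floor: variance estimates at or below sampling noise clip to 0.)

The same pipeline runs end to end from a YAML config over named sample
panels (`refstab analyze --config cfg.yaml`), and `refstab curves` fits
standard curves, e.g. a slope of −3.3219 cycles per log₁₀ dilution gives
100% efficiency. A quick abundance comparison:
`fold_abundance(9.42, 27.31)` → `2.429e5`, i.e. a transcript reaching
threshold at Cq 9.42 is about 2.4 × 10⁵-fold more abundant than one at the
panel average of 27.31.

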
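# paragi

Genetic-interaction scoring for multiplex CRISPR paralog knockout
screens.

Paralogs buffer each other's loss, so single-gene knockout screens
systematically miss them; combinatorial screens knock out gene pairs and
their member singles and look for pairs whose joint knockout is worse
than additive. `paragi` implements the three standard scores for this
design, the Gaussian null models behind them, hit calling, cross-screen
consistency evaluation, and a synthetic screen generator with planted
ground truth so the whole chain is testable without any external data.

## Scores

For pair (A, B) in screen j, with gene-level log2 fold changes (LFC)
aggregated from guide constructs:

- **dLFC** = LFC(AB) − (LFC(A) + LFC(B)) — the additive-model residual;
  strongly negative values indicate synthetic lethality.
- **ZdLFC** = (dLFC − μ_j) / σ_j, where μ_j, σ_j come from a Gaussian
  fit to the screen's dLFC distribution after Tukey-fence outlier
  removal (Q1 − 1.5·IQR, Q3 + 1.5·IQR).
- **RdLFC** = (dLFC − μ_j) / (μ_j − median{dLFC of reference SL pairs}),
  an affine rescaling pinning the null mean to 0 and the
  positive-control median to −1.

Hits require the interaction score below its cut **and** the pair itself
to drop out: ZLFC (the pair LFC standardized against the higher-weight
component of a two-component Gaussian mixture over all guide LFCs)
below −2, or raw pair LFC below −1 for the raw method. Defaults:
dLFC < −1 & LFC < −1; ZdLFC < −2 & ZLFC < −2; RdLFC < −0.7 & ZLFC < −2.

Methods are compared by hit reproducibility across screens: the median
pairwise Jaccard coefficient |A∩B|/|A∪B| of their hit sets.

## Worked example

```python
from paragi import SimConfig, simulate_screens, score_screens, \
    method_consistency, truth_metrics

sim = simulate_screens(SimConfig(seed=1))          # 4 screens, 500 pairs
res = score_screens(sim.counts, sim.annotation,
                    references=sim.references, seed=1)

for screen, nm in res.nulls.items():
    print(screen, f"null mu={nm.mu:+.3f} sigma={nm.sigma:.3f}")
m = truth_metrics(res.hit_sets("zdlfc"), sim.truth)
print({s: round(v.recall_common, 2) for s, v in m.items()})
print("median Jaccard zdlfc:",
      round(method_consistency(res, "zdlfc").median_jaccard, 3))
print("median Jaccard dlfc:",
      round(method_consistency(res, "dlfc").median_jaccard, 3))
```

prints

```
screen1 null mu=-0.174 sigma=0.308
screen2 null mu=-0.214 sigma=0.324
screen3 null mu=-0.146 sigma=0.343
screen4 null mu=-0.220 sigma=0.327
{'screen1': 1.0, 'screen2': 1.0, 'screen3': 0.8, 'screen4': 1.0}
median Jaccard zdlfc: 0.725
median Jaccard dlfc: 0.477
```

The fitted dLFC nulls sit near zero with sigma ≈ 0.3 (measurement
noise); ZdLFC hit calling recovers 80–100% of the planted
synthetic-lethal pairs per screen, and its hit sets agree across screens
substantially better (median Jaccard 0.73) than a fixed raw-dLFC
threshold (0.48), because Z-scoring adapts to each screen's effect
scale.

The scripts in `examples/` walk through each capability: simulate +
score, the file-based pipeline with provenance manifests, cross-screen
consistency, and the sequence-identity / expression evaluations.

## Real data

Inputs are plain TSVs: a read-count table per screen (arrays × samples,
one T0 column), a library annotation (`array_id, gene1, gene2,
control_class`), gene-set files (one symbol per line), an optional
two-column reference SL pair file, optional percent-identity and
expression tables. `paragi.pipeline.run_pipeline` reads them, writes the
long-format score table plus fitted model parameters, and records a
manifest (parameters, input SHA-256 digests, seed) so runs are
reproducible bit-for-bit.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full computation from scratch — simulates the default
four-screen world at the given seed, scores it with all three methods,
and prints planted-truth recovery and the per-method median Jaccard —
then writes the JSON report to `--out`.
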
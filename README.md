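# mycoflow

Tools for studying how fungal communities move between plant organs and
the air of the surrounding canopy.  Starting from a clustered OTU count
table (taxa × samples) with per-sample environment labels — e.g. air,
leaf, flower and fruit samples from a vineyard — the package answers
three questions:

1. **Where does each community come from?**  A collapsed-Gibbs Bayesian
   source tracker estimates, for each sink environment, the fraction of
   its community contributed by every other environment plus an Unknown
   source, using a rotation design in which each environment takes the
   sink role in turn.
2. **How much of a community cycles back to its own environment?**  For
   a pair of environments with reciprocal attribution fractions
   x = f[A][B] and y = f[B][A], the exchange statistic **z = x·y** is
   the fraction of a community that leaves for the partner environment
   and returns; the sum of z over all partners of an environment is its
   **index of conservation** — higher values mean a more stable, shared
   community.
3. **Which taxa co-occur or exclude one another?**  An ensemble network
   procedure scores every OTU pair with five measures (Spearman,
   Pearson, Bray-Curtis, Kullback-Leibler, mutual information), tests
   them against a row-shuffling permutation null, removes
   bootstrap-unstable edges, merges the per-measure p-values with
   Brown's method, applies Benjamini-Hochberg, and clusters the signed
   graph into connected components.

Around these sit the standard community-statistics stages (rarefaction,
cumulative sum scaling, Shannon/observed species, Bray-Curtis + PCoA,
ANOSIM, permutation Kruskal-Wallis and t tests, BH correction) and a
synthetic-community generator with known attribution truth, so the
whole pipeline is testable end to end without sequencing data.

The estimators follow scikit-learn conventions (`GibbsSourceTracker`
with `fit`/`predict_proba`, `CSSNormalizer`/`Rarefier` transformers,
`EnsembleAssociationNetwork` with fitted `graph_`/`summary_`); the
module-level functions used below are thin wrappers over them.

## Worked example

Load a published-style attribution table and compute all pairwise
exchange fractions and conservation indices:

```python
import mycoflow as mf
from mycoflow.sourcetracker import AttributionMatrix

f = AttributionMatrix.from_nested_dict(
    mf.VINEYARD_ATTRIBUTION,
    environments=["air", "fruit", "leaf", "flower"])
rep = mf.exchange_report(f)
print(rep.pair_frame().to_string(index=False))
print(rep.conservation_frame().to_string(index=False))
```

prints

```
env_a  env_b      z  z_percent
  air  fruit 0.1890       18.9
  air   leaf 0.0450        4.5
  air flower 0.0032        0.3
fruit   leaf 0.1504       15.0
fruit flower 0.0204        2.0
 leaf flower 0.4212       42.1

environment  index  index_percent
        air 0.2372           23.7
      fruit 0.3598           36.0
       leaf 0.6166           61.7
     flower 0.4448           44.5
```

Reading: 18.9% of the fruit community is estimated to travel to the air
and return (0.54 of air comes from fruit × 0.35 of fruit comes from
air); 23.7% of the air community cycles back through the three plant
organs, making air the least conserved of the four environments, while
leaf (61.7%) is the most conserved.

Source tracking on synthetic data with planted truth:

```python
from mycoflow import make_paper_like_model, simulate, rotation_runs
from mycoflow.sourcetracker import GibbsParams

model = make_paper_like_model(seed=0, sink_env="air")  # air is the mixed sink
dataset = simulate(model)
attribution = rotation_runs(dataset.table, GibbsParams(seed=0))
print(attribution.fractions.loc["air"].round(3))
# fruit 0.493, leaf 0.298, flower 0.098, Unknown 0.112
# (truth after row renormalization: 0.54 / 0.30 / 0.08 / 0.08)
```

## Command-line pipeline

```bash
mycoflow all --seed 3 --outdir run/            # simulate → … → network
mycoflow exchange --config cfg.yaml --seed 0   # one stage, from files
```

Stages communicate through TSV/JSON files in the output directory, each
carrying a provenance header (config hash, seed, stage, version), and a
`run_report.json` records timings and headline numbers.  Any stage can
be re-run alone once its inputs exist.

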
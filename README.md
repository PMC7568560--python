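# trialnet

Temporal co-authorship network analysis for clinical-trial publication
corpora: who publishes chemotherapy trials, how the collaboration network
grows and fragments into disease subspecialties over seven decades, and how
impact, centrality and career length differ by gender.

The package is aimed at scientometrics and health-services researchers who
have (or want to emulate) a curated corpus of trial manuscripts — one record
per publication with its ordered author list, design flags, citation count,
update lineage and disease-subspecialty mapping — and want a reproducible
pipeline from raw records to network metrics and disparity statistics.

## The model

**Author impact.** Each author earns, per manuscript, the product of four
coefficients:

    score = role x trial x citation x update

* *role* = 3 for first/last authors (and flagged equal contributors), 1 for
  middle authors;
* *trial* = 2 if the manuscript reports any randomized trial, else 1;
* *citation* = citations / max-citations over the whole corpus; manuscripts
  from 2009–2018 use a blended count that linearly phases in the journal-tier
  median, compensating for citations not yet accrued;
* *update* = 0.5^k for the k-th update of a trial (primary publication k = 0);
  pooled updates take the most favourable generation.

The score is split across disease subspecialties by the record's weights, and
an author's cumulative impact is the sum over their manuscripts.

**Network.** Nodes are disambiguated authors; every manuscript adds one edge
per author pair with weight `score_i * score_j / n_authors` (parallel edges
from different manuscripts are kept). Networks are cumulative and
discretized by year. On the weight-summed simple-graph view the pipeline
computes density, weighted Newman modularity and categorical assortativity
over the primary-subspecialty partition, weighted betweenness (distance =
1/weight), weighted PageRank, per-author subspecialty/gender homophily, and
concentration of links and impact in the top decile.

**Careers and statistics.** Authors are assigned a yearly primary
subspecialty (first/last authorship, or cumulative impact no more than one
standard deviation below the subspecialty mean, majority of impact wins);
longevity is the first-to-last publication interval with right-truncation
adjustment. Group comparisons use the two-sided Wilcoxon rank-sum test
(exact by permutation enumeration for small groups), gender trends are
smoothed with LOESS (degree 2, span 0.75) and extrapolated to a parity year,
and a sensitivity analysis perturbs the role (±67%) and trial (±50%)
coefficients and correlates the temporal metric series against baseline.

A seeded synthetic-corpus generator reproduces the structural conditions the
analysis assumes (log-linear growth, team sizes 6→20, 13 subspecialties with
~88% within-subspecialty co-authorship, a 15%→40% women's entry share,
heavy-tailed citations, update chains, preferential attachment), with full
ground truth for recovery testing.

## Worked example

```python
import trialnet as tn
from trialnet import identity, impact, network, stats

records, truth = tn.simulate_corpus(tn.SimulationConfig(seed=1))
key_map = identity.canonicalize_authors([a.raw_name for r in records for a in r.authors])
tiers = {int(k): v for k, v in truth["tier_median_table"].items()}

series = network.yearly_metric_series(records, key_map, tiers)
print(series.loc[[1946, 1980, 2018],
                 ["n_authors", "n_pairs", "density", "modularity", "assortativity"]].round(4))

genders = identity.gender_census(
    key_map, freq_table={k: tuple(v) for k, v in truth["name_frequency_table"].items()})
totals = impact.cumulative_impact(records, key_map, None, tiers).total_by_author()
res = stats.compare_groups(
    [totals.get(a, 0.0) for a, g in genders.items() if g == "man"],
    [totals.get(a, 0.0) for a, g in genders.items() if g == "woman"], "man", "woman")
print(f"median impact: men {res.median_a:.3f} (n={res.n_a}) "
      f"vs women {res.median_b:.3f} (n={res.n_b}), p={res.format_p()}")
```

prints

```
      n_authors  n_pairs  density  modularity  assortativity
year
1946          7       21   1.0000     -0.0000            NaN
1980        112      611   0.0983      0.5881         0.9518
2018        777    12422   0.0412      0.2502         0.9877
median impact: men 0.023 (n=491) vs women 0.018 (n=202), p=0.0289
```

Read: the cumulative network starts as a single fully connected author team
in 1946, then grows to 777 authors by 2018 while its density falls to ~4%
(the real-scale corpus falls far lower); co-authorship is strongly
assortative by subspecialty; and on this synthetic draw — whose generator
gives men a higher chance of first/last authorship but identical citation
behaviour — men's median cumulative impact is higher than women's at p < 0.05.

The same pipeline is available from the shell:

```sh
trialnet simulate --seed 1 --out run/sim
trialnet analyze run/sim/corpus.jsonl --out run/report \
    --freq-table run/sim/freq_table.tsv --tier-medians run/sim/tier_medians.tsv
trialnet sensitivity run/sim/corpus.jsonl --out run/sens \
    --tier-medians run/sim/tier_medians.tsv
```

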
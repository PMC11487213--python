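# comorbnet

Phenotypic comorbidity network (PCN) analysis of hospital discharge diagnoses
for thyroid-disease cohorts.

Patients hospitalized with a thyroid disease — benign thyroid disease (ICD-10
E00–E07) or thyroid cancer (C73) — typically carry several other diagnoses.
`comorbnet` turns a long-format table of encounter diagnoses into a weighted
disease co-occurrence network and a set of reproducible epidemiological
tables: which comorbidities are common, which differ between sexes / age
groups / thyroid-disease types, and which diseases sit at the center of the
co-occurrence structure.

## Method

All diagnoses are standardized to 3-character ICD-10 codes. After cleaning
(adults ≥ 18 years with a thyroid code; codes from chapters XV–XXII removed;
records with < 2 codes removed; diseases with prevalence < 2% removed), every
unordered disease pair (a, b) over N records is summarized by its 2×2 counts
n_a, n_b, n_ab and

- **cosine index** — comorbidity strength: `cos(a,b) = n_ab / sqrt(n_a · n_b)`;
- **phi coefficient** — Pearson correlation of the two binary indicators:
  `phi = (N·n_ab − n_a·n_b) / sqrt(n_a·n_b·(N−n_a)·(N−n_b))`, tested with
  `t = phi·sqrt((N−2)/(1−phi²))` against Student t with N−2 df (two-tailed).

The network keeps the K strongest cosine edges, where K is the number of
pairs with positive, significant phi — so the cosine-weighted network has as
many edges as there are significantly correlated pairs (ties at the cutoff
included). Node importance is weighted PageRank (damping 0.85); structure is
summarized by density, degree, average neighbor degree and unnormalized
betweenness centrality. Subgroup networks (sex, thyroid cancer vs benign
disease, age bins) are compared through *abundant connections*: edges unique
to one subgroup or with cosine weight ≥ 0.05 higher there.

Prevalence contrasts between subgroups use the symmetric relative difference
`d = 2(p_a − p_b)/(p_a + p_b)` with a pooled two-proportion z-test; a
comorbidity is *different* when |d| > 0.1 and p < .05, and *enriched* when its
prevalence ratio additionally reaches 1.5.

Because real hospital extracts of this kind are access-restricted, the package
ships a synthetic-EMR generator with known ground truth (configured marginal
prevalences, sex/age effects, planted pairwise co-occurrence at target cosine
values) so the whole pipeline is testable end to end.

## Worked example

```python
import comorbnet as cn

cohort = cn.simulate_cohort(cn.default_study_config(20_000, seed=1))
filtered = cn.filter_cohort(cohort)                 # cleaning pipeline
universe = cn.comorbidity_universe(filtered)        # thyroid codes excluded
net = cn.build_pcn(filtered)                        # calibrated cosine network
s = cn.summarize_network(net)
top, _ = cn.pagerank_importance(net, top_k=5)

print(len(filtered.records), len(universe))
print(len(net.nodes), len(net.edges), round(net.cutoff, 3))
print(round(s.density, 3), round(s.mean_degree, 1))
print(top)
```

Output:

```
19679 70
75 282 0.118
0.102 7.5
[('E04', 0.1570...), ('I10', 0.0973...), ('K76', 0.0497...),
 ('N40', 0.0421...), ('I70', 0.0384...)]
```

19,679 of 20,000 simulated encounters survive cleaning, leaving 70
comorbidities (plus the thyroid codes as network nodes, 75 in total). Cutoff
calibration keeps 282 edges — exactly the number of significantly correlated
pairs. Nontoxic goiter (E04, the most common thyroid indication) and
hypertension (I10, the planted co-occurrence hub) dominate the PageRank
ranking, as expected from the generator's ground truth.

The same pipeline runs from the shell:

```bash
comorbnet simulate --out cohort.csv --seed 1
comorbnet report --in cohort.csv --out report/ --seed 1
```

which writes cohort characteristics, prevalence and subgroup-difference
tables, per-subgroup network summaries, top-PageRank tables,
abundant-connection lists, and a JSON manifest.

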
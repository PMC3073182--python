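# pdsenet — process–drug–side-effect networks

`pdsenet` builds a tripartite **ABC network** that links biological
processes (A) to drug side effects (C) through the drugs (B) that connect
them: drugs perturb biological processes, and processes shape phenotype, so
the processes shared by drugs that cause the same side effect are candidate
mechanisms for that side effect. The package is aimed at systems-biology
analyses that combine drug-perturbation expression compendia
(connectivity-map-style rank matrices) with side-effect resources
(SIDER-style frequency tables) and drug-synonym references
(DrugBank-style).

## The method

**Drug → process layer.** Each treatment instance is a ranked list *L* of
the *N*-gene universe (rank 1 = most up-regulated by the drug). For a gene
set *S* of size *N<sub>s</sub>* the list is walked with a zero-sum running
sum: members add `sqrt((N − N_s)/N_s)`, non-members subtract
`sqrt(N_s/(N − N_s))`. The enrichment score **ES** is the maximum deviation
from zero reached by the walk; down-regulation is scored by walking the
reversed list. Across instances *j* the scores of process *i* are
standardized robustly,

```
t_ij = (ES_ij − MED_i) / (1.4826 · MAD_i)
```

with the per-process median and median absolute deviation (1.4826·MAD
estimates σ under normality). Edges keep instances with *t* > 3.0 (≈ p =
0.001) for sets with at most 30 genes.

**Drug → side-effect layer.** Side-effect records carry frequency
annotations ("26%", "10–20%", "rare", "infrequent", "postmarketing");
these are resolved to scores and relations at or above 20% are kept. Drug
labels are normalized to canonical drugs via a synonym table (primary
names, synonyms, brands; exact match after trimming/lowercasing).

**ABC merge and scoring.** Both layers are restricted to the drugs present
in each. For a side effect *j* caused by *TD<sub>j</sub>* drugs, a process
*i* hit by *CD<sub>ij</sub>* of them scores

```
Score_ij = CD_ij / TD_j ,
```

and effects with fewer than 2 drugs are excluded. Significance thresholds
come from a permutation null: drawing *TD* drugs at random from the bridge
pool (1,000 times per observed *TD*), recomputing per-process counts
against the real drug→process layer, and taking the smallest count whose
null tail probability is below α = 0.05 — one threshold per *TD*,
non-decreasing in *TD*.

A literature-evaluation harness matches candidate noun phrases to GO term
names by normalized edit-distance similarity (threshold 0.55) and reports
how many predicted processes fall in the top 10–50% of the resulting
literature ranking.

Because the real compendia are not bundled, the package ships a
first-class synthetic generator (`pdsenet.synthetic`) that emulates all
four inputs with planted drug→process perturbations and process→side-effect
links, so the whole pipeline is testable offline against a known ground
truth.

## Worked example

```python
from pdsenet import (GeneSet, RankedInstance, compute_es,
                     EnrichmentScore, median_mad_tscores)

genes = [f"g{i}" for i in range(1, 11)]
inst = RankedInstance("inst1", "drugA", tuple(genes))
top_pair = GeneSet("GO:0000001", "toy process", frozenset(genes[:2]))
print(compute_es(inst, top_pair, "up").es)   # 4.0  (= 2 * sqrt(8/2))

row = [EnrichmentScore("GO:0000001", f"i{k}", "up", v)
       for k, v in enumerate([1, 2, 3, 4, 100])]
ts, _ = median_mad_tscores(row)
print(round(ts[-1].t, 2))                    # 65.43 (= 97 / 1.4826; MED=3, MAD=1)
```

A set whose two members sit at the very top of a 10-gene list reaches the
maximal running sum 4.0; in a row of enrichment scores {1,2,3,4,100} the
outlier instance stands 65 robust standard deviations above the row median,
far past the edge threshold of 3.

The numbered drivers under `analysis/` run the full study on the default
synthetic scenario (2,000 genes × 74 instances, 200 gene sets, 30 planted
side effects, planted strength 0.8):

```sh
python analysis/01_simulate.py      # scenario + ground truth
python analysis/02_enrichment.py    # 377 drug-process edges (t > 3.0)
python analysis/03_side_effects.py  # 120 of 150 records pass the 20% cutoff
python analysis/04_abc_network.py   # 30/30 planted associations significant
python analysis/05_literature_eval.py
```

Step 04 prints, for example, `up: 344 candidate pairs, 16 significant;
thresholds {4: 3}` — with each planted effect caused by 4 drugs, the
permutation null puts the significance cutoff at 3 co-occurring drugs, and
every planted process–effect association clears it. Tables land under
`results/`; bulky regenerable inputs under `scratch/`.

The same pipeline is available as a CLI (`pdsenet simulate|enrich|sider|
merge|permute|evaluate|run-all`), every constant a flag.

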
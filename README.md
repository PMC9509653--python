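# coexorder

Weighted gene co-expression network analysis (WGCNA) with a built-in,
testable comparison of the two ways differential expression and network
construction are commonly combined:

* **method #3 (DEGs → WGCNA)** — filter the expression matrix down to
  differentially expressed genes (DEGs) first, then build the
  co-expression network on the filtered matrix;
* **method #4 (WGCNA → DEGs)** — build the network on the *full* matrix,
  select trait-associated modules and hub genes, and only then intersect
  with the DEG list.

The package is for transcriptomics practitioners who use co-expression
modules to nominate trait-associated genes (the motivating application is
gonadal sex differentiation: a binary sex trait over two developmental
stages) and want a principled answer to "should I pre-filter?". It
implements the full pipeline — soft-threshold selection, topological
overlap, module detection, module–trait association, hub-gene filters,
moderated-t differential expression with FDR control, network topology
statistics and Cytoscape export — plus a seeded synthetic-data generator
with planted ground truth, so every stage and the #3-vs-#4 contrast itself
are measurable without any external download.

## The model in brief

For genes *m*, *n* with Pearson correlation cor<sub>mn</sub> across
samples, the unsigned network adjacency is

&nbsp;&nbsp;a<sub>mn</sub> = |cor<sub>mn</sub>|<sup>β</sup>,

with the integer power β ∈ {1..20} chosen so the network approximates
scale-free topology: the signed fit index −sign(slope)·R² of the
regression of log₁₀ p(k) on log₁₀ k (k = connectivity Σ<sub>j≠i</sub>
a<sub>ij</sub>) should reach 0.8, with high mean connectivity and a slope
near −1. The adjacency is transformed to the topological overlap matrix
TOM<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>)/(min(k<sub>i</sub>,
k<sub>j</sub>) + 1 − a<sub>ij</sub>); modules are branches of the
average-linkage tree of 1 − TOM (minimum size 30, refined by module
membership kME, merged at eigengene correlation > 0.75); a module is
trait-associated when its eigengene–trait correlation passes |r| > 0.5 at
the configured p, and its genes are kept when |GS| > 0.2 and |kME| > 0.8.
DEGs come from a moderated two-group t (empirical-Bayes variance
shrinkage) with Benjamini–Hochberg adjusted p < 0.05. Full details and
defaults: [docs/methods.md](docs/methods.md).

## Worked example

```python
import coexorder as cx

# a seeded dataset with planted modules: 2,000 genes, 2 sexes x 2 stages
em, traits, truth = cx.generate(cx.default_paper_like_spec(seed=11))

results = cx.run_all_methods(em, traits, cx.small_sample_config())
report = cx.compare(results, key=cx.KeyGeneList(truth.key_genes))

cols = ["n_genes", "beta", "signed_r2", "module_count", "key_gene_recall"]
print(report.summary[cols].to_string(float_format=lambda v: f"{v:.2f}"))
print(f"Jaccard #3 vs #4: {report.jaccard.loc['method3', 'method4']:.1f}%")
print("winners:", report.winners)
```

prints

```
        n_genes beta signed_r2 module_count key_gene_recall
method1  233.00  NaN       NaN         0.00          100.00
method2     214    7      0.84            3          100.00
method3     209   20      0.47            1          100.00
method4     214    7      0.84            3          100.00
Jaccard #3 vs #4: 97.7%
winners: {'signed_r2': 'method4', 'module_count': 'method4', 'key_gene_recall': 'method4'}
```

Reading this: method #1 (DEGs alone) keeps 233 genes with no network
structure at all. Pre-filtering before networking (#3) forces the soft
threshold to the top of the scan (β = 20) yet still fits scale-free
topology poorly (signed R² 0.47 vs 0.84) and collapses the module
structure to a single module, because the DEG list is dominated by one
tight co-expressed block; the full-matrix network (#2/#4) recovers the
planted modules at a lower power with a far better fit. On this seed both
orderings recover all 10 planted key genes; across seeds method #3 loses
them whenever its impoverished network fails the module-selection cascade,
while #4 also retains all 30 planted "connector" genes in its network —
genes co-expressed with the trait module but individually not
differentially expressed, which pre-filtering removes before the network
ever sees them.

The same pipeline runs from the shell:

```bash
coexorder simulate --seed 11 --out data/
coexorder run --expr data/expression.tsv --traits data/traits.tsv --method 4 --out runs/m4
coexorder run --expr data/expression.tsv --traits data/traits.tsv --method 3 --out runs/m3
coexorder compare --results runs/m3 --results runs/m4 \
    --key-genes data/key_genes.txt --out report/
```

`coexorder --help` lists the remaining commands (`io validate`,
`io outliers`, `degs`, `network scan/build`, `modules`, `netstats`).

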
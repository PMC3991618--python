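# tsnba

Three-step network-based discovery of disease **molecular signatures** and
**key transcriptional regulators** from a protein–protein interaction (PPI)
network plus condition-contrast gene expression data.

A molecular signature is a set of genes prognostic of a phenotype and
indicative of the underlying pathology. The premise of this approach is that
signature components interact and share expression patterns, so combining
the interaction network with perturbation-responsive expression finds more
relevant genes than either source alone. The package also implements five
classical prioritization baselines, a hypergeometric enrichment-evaluation
harness, and a seeded synthetic benchmark generator with planted ground
truth, so the whole pipeline is exercisable and testable without any
external database.

## The method

**Step 1 — interaction-activity ranking.** Each PPI edge {i, t} gets an
*activity* from the log2 fold changes of its endpoints,

    A_it = C·s(K f_i)·C·s(K f_t) + C·s(−K f_i)·C·s(−K f_t) − T,

where s(x) = 1/(1+e^(−x)) is the logistic function, C = 1 and K = 5 shape
the two bivariate logistic terms (co-activation and co-suppression), and the
shift T = 0.5 makes the activity exactly zero when neither gene responds.
These activities replace the 1-entries of the adjacency matrix; each gene is
scored by the total activity it receives from its partners, P_i = Σ_t A_it,
and genes are ranked by descending P_i. An edge with one silent endpoint
contributes essentially nothing, so activity flows only through interactions
whose *both* partners respond to the perturbation.

**Step 2 — co-expression signature.** Pairwise Pearson correlation is
computed over all samples for the top-K ranked genes (K = 300 by default).
Pairs with ρ ≥ τ form a co-expression network; genes incident to at least
one retained edge are the signature. τ is tuned on the grid
0.600, 0.605, …, 0.945 to the largest value whose signature still holds at
least 50 genes.

**Step 3 — key regulators.** Mutual information between top-K genes is
taken from the Gaussian closed form MI = −½·ln(1 − ρ²) and
background-corrected per gene in the CLR (context likelihood of
relatedness) manner: z_t = max(0, (MI − μ_t)/σ_t) against the TF's MI
background, z_g likewise for the target, combined z = √(z_t² + z_g²). A TF
is a key regulator when, among its z ≥ 3 interactions, it has more than 3
benchmark-pathology targets and those make up more than 60% of its targets.
Per-condition regulator sets are unioned across contrasts.

**Baselines and evaluation.** Fold-change ranking, degree (hub) ranking,
neighborhood scoring, interconnectivity, and network propagation
(F ← α·Â·F + (1−α)·F⁰ on the degree-normalized adjacency, α = 0.1, L1
convergence < 10⁻⁶) all emit the same ranked-list contract. Selections are
scored by the enrichment ratio |selection ∩ benchmark| / |selection| with an
exact upper-tail hypergeometric p-value against the network universe, and
methods are compared by a paired t-test over per-dataset ratios.

## Worked example

Generate a synthetic study with a planted pathology module and run the
three steps:

```sh
tsnba simulate --preset signal --seed 1 --outdir study/
tsnba rank --network study/network.tsv --expr study/expression.tsv \
    --contrasts study/contrasts.yaml --contrast treated_vs_control \
    --out study/ranked.tsv
tsnba signature --network study/network.tsv --expr study/expression.tsv \
    --contrasts study/contrasts.yaml --contrast treated_vs_control \
    --ranked study/ranked.tsv --top-k 300 --target-size 50 \
    --out-genes study/signature.tsv --out-edges study/edges.tsv
```

The same run through the Python API:

```python
from tsnba import *
from tsnba.pipeline import run_condition

params = signal_preset(seed=1)          # 2000 genes, 200 planted pathology
net = generate_network(params)
truth = plant_truth(net, params)
expr, contrast = simulate_expression(truth)
res = run_condition(net, expr, contrast,
                    tf_genes=truth.tf_genes, benchmark=truth.pathology_genes)
bench = truth.pathology_genes
print("step-1 top-50 enrichment:",
      enrichment_ratio(res.ranking.top(50), bench, net).percent, "%")
print("signature:", res.signature.size, "genes at tau", res.signature.threshold)
print("signature enrichment:",
      enrichment_ratio(res.signature.signature, bench, net).percent, "%")
print("key regulators:", sorted(res.regulators.members))
```

which prints (seed 1):

```
step-1 top-50 enrichment: 70.0 %
signature: 51 genes at tau 0.935
signature enrichment: 94.1 %
key regulators: ['G0012', 'G0015']
```

Against a 10% background, the activity ranking concentrates planted
pathology genes in its top 50 (70% vs 10%), the co-expression filter
refines them further (94.1%), and the CLR screen recovers planted module
regulators.

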
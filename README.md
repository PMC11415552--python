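# spotdecon

Reference-free deconvolution of sequencing-based spatial transcriptomics.

Capture spots on platforms like 10x Visium mix transcripts from several
cells, so the count vector of a spot is a blend of cell states.
`spotdecon` infers the per-spot cell-state proportions **without a paired
single-cell reference**, for computational biologists who have a spot ×
gene count matrix, spot coordinates, marker gene sets (or none at all),
and optionally the H&E image.

## The model

For spot *i* with *K* cell states, the generative model is

- *u_k* ~ Normal(0, 10 *I*) — a latent embedding per state, heterogeneity σ_k,
- *c_i* ~ Dirichlet(α · A(x_i, s_k)) — proportions with an **empirical
  prior**: the signature enrichment score of each state's marker set
  (bin-matched control genes), ReLU + ε, row-normalized; α = 50,
- *z_i* | *c_i*, *u* ~ Normal(Σ_k c_ik u_k, Σ_k c_ik σ_k),
- *l_i* ~ logNormal(log l̃_i, 1) with l̃ the spatially smoothed library size,
- *x_ig* ~ NegativeBinomial(l_i · f(z_i)_g, θ_g), *f* a linear-softmax decoder.

Inference is stochastic variational with a structured family: q(c|x) =
Dirichlet(α γ(x)) and the mixture posterior q(z|c,x) = N(Σ_k c_ik
ζ_μ(k,x), Σ_k c_ik ζ_σ(k,x)). The inferred proportions are the
variational mean γ(x). An optional histology branch encodes per-spot
image patches into a second Gaussian view on *z* and fuses the views by a
product of experts (precision weighting), trained with a joint-plus-
marginal information-bottleneck objective.

Around the model the package provides:

- **Archetypal analysis** (principal convex hull / PCHA): fits a convex
  polytope to the spots in PC space, estimates the archetype count from
  the intrinsic dimension, finds each archetype's nearest-spot community
  and its rank-sum marker genes, aligns communities to known states by
  stable-marriage matching to refine signatures — or defines the states
  outright when no signatures exist.
- **A spatially structured simulator** (GP proportion fields, gamma
  library sizes, cells drawn from a synthetic single-cell reference,
  parametric pseudo-histology) with full ground truth.
- **Downstream analyses**: multi-sample integration, spatial hubs
  (kNN + Jaccard + Leiden on inferred compositions), intratumoral /
  peritumoral / stromal region calls, sample-mixing entropy, a spatial
  cross-correlation index, distance-binned expression profiles.
- **Benchmark metrics**: per-spot RMSE and Jensen–Shannon divergence
  against ground truth; signature-correlation Frobenius distances when no
  truth exists.

The variational model runs on a compact reverse-mode autodiff core
(`spotdecon._autodiff`) written for this package — dense layers, closed
form KLs, pathwise Gaussian and implicit-gradient Dirichlet sampling, and
Adam — so the whole pipeline needs only the scientific Python stack.

## Worked example

Simulate a 15×15-spot tissue with 3 cell types, retrieve marker sets from
an independent synthetic reference (top-30 fold-change genes, as one
would from an external scRNA-seq cohort), and deconvolve:

```python
import numpy as np
from spotdecon import simulate, priors, model, evalmetrics

ss = np.random.SeedSequence(1).generate_state(6) % (2**31)
ref = simulate.make_synthetic_reference(3, 300, 200, 5.0, int(ss[0]))
fields = simulate.simulate_proportion_fields(15, 3, None, int(ss[1]))
libs = simulate.sample_library_sizes(225, seed=int(ss[2]))
sim = simulate.simulate_spots(ref, fields, libs, seed=int(ss[3]), grid_side=15)
sigs = simulate.retrieve_de_signatures(
    simulate.make_synthetic_reference(3, 300, 200, 5.0, int(ss[4])))

bundle = priors.build_priors(sim.data, sigs, seed=int(ss[5]))
state = model.train(sim.data, bundle,
                    cfg=model.GenerativeConfig(seed=int(ss[5])))
result = model.infer(sim.data, None, state)

_, _, rmse, jsd = evalmetrics.deconvolution_error(sim.truth_proportions, result.c)
_, _, rmse_prior, _ = evalmetrics.deconvolution_error(sim.truth_proportions, bundle.A)
print(f"mean RMSE  model {rmse:.4f} | prior baseline {rmse_prior:.4f}")
print(f"mean JSD   {jsd:.4f} nats")
for k, name in enumerate(result.state_names):
    r = np.corrcoef(sim.truth_proportions[:, k], result.c[:, k])[0, 1]
    print(f"Pearson(truth, inferred) {name}: {r:.3f}")
```

Output (about a minute on one CPU core):

```
mean RMSE  model 0.1846 | prior baseline 0.1869
mean JSD   0.0840 nats
Pearson(truth, inferred) type0: 0.862
Pearson(truth, inferred) type1: 0.840
Pearson(truth, inferred) type2: 0.874
```

Each inferred proportion column tracks its true spatial field (Pearson
0.84–0.87), and the trained model's per-spot error is below the
score-based prior it started from — the count likelihood sharpened the
signature evidence. `result` also carries the latent embedding `z` (input
to hub/entropy analyses), library estimates `l`, and per-state expression
profiles.

The same pipeline is available from a shell:

```bash
spotdecon simulate --mode major --grid 50 --seed 1 --outdir sim/
spotdecon run --counts sim/counts.csv --coords sim/coords.csv \
    --signatures sim/signatures.json --seed 1 --outdir out/
spotdecon hubs --proportions out/proportions.csv --coords sim/coords.csv \
    --outdir hubs/
spotdecon eval --truth sim/truth.csv --pred out/proportions.csv
```

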
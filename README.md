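# pandm

Joint modeling of differential DNA methylation (DM) across cancer types from
per-cancer summary statistics.

## The problem

Pan-cancer methylation studies usually call DM CpG sites separately for each
cancer type and then intersect the hit lists. Separate analyses waste the
correlation between cancers: a site that is clearly DM in several cancers
carries evidence about its status in the others, and weak signals get lost.
`pandm` implements a joint latent-class model over the full CpG-by-cancer
matrix of DM p-values that pools this evidence, clusters CpG sites by their
pan-cancer DM patterns, and improves DM detection power — for anyone with a
G×C table of p-values from any upstream single-cancer DM caller
(tumor-purity-adjusted callers included; the tool is agnostic to how the
p-values were produced).

## The model

P-values are transformed to z-values, z_gc = Φ⁻¹(p_gc), so per cancer *c* the
z-values follow a two-component normal mixture: an empirical null 𝒩(μ_c0,
σ²_c0) for non-DM sites and an alternative 𝒩(μ_c1, σ²_c1) (on the negative
side, since small p ↦ negative z) for DM sites. Each CpG site *g* carries a
latent cluster label a_g ∈ {1..K} with proportions π; given a_g = k, the DM
indicator in cancer c is H_gc ~ Bernoulli(q_kc), independently across
cancers. The rows of the K×C matrix **Q** = (q_kc) are the *pan-cancer DM
patterns*. All parameters Θ = {π, Q, μ, Σ} are estimated by EM on the
observed z-matrix (missing entries are marginalized out); the number of
patterns K is chosen by BIC,

    BIC(K) = −2 ln L̂_obs + (K − 1 + KC + 4C) ln G.

A site's local fdr in cancer c is fdr_gc = Pr(H_gc = 0 | Z, Θ̂); DM is called
at the largest local-fdr cutoff whose estimated global FDR (the mean local
fdr of the called set) stays within the target level.

## Worked example

```python
import numpy as np
from pandm import (default_scenario, simulate_dataset, select_k,
                   e_step, local_fdr, call_dm)

params, G = default_scenario("fast")          # C=9 cancers, K=5 patterns
z, truth = simulate_dataset(params, G, seed=1)  # G=20,000 sites

best, records = select_k(z, range(2, 11), seed=1)
print("selected K:", best.params.K)
print("BIC trace:", {r.params.K: round(r.bic) for r in records})

post = e_step(z, best.params)
calls = call_dm(local_fdr(post), level=0.01)
print("DM calls:", calls.calls.sum(), "achieved FDR estimate:",
      round(calls.achieved_fdr, 4))
```

Output:

```
selected K: 5
BIC trace: {2: 605294, 3: 599360, 4: 594972, 5: 592288, 6: 592386,
            7: 592470, 8: 592567, 9: 592662, 10: 592751}
DM calls: 27111 achieved FDR estimate: 0.01
```

BIC reaches its minimum at the generating K = 5, and the fitted pattern
matrix Q̂ reproduces the five simulated patterns (an all-non-DM background,
an all-DM pattern, and three blockwise patterns) within a few hundredths per
entry. The ~27k called entries are site-cancer pairs declared DM at a 1%
global FDR; against the simulation's ground truth the realized FDR is ≈0.01.

The same pipeline is available from the shell:

```bash
pandm simulate --g 20000 --seed 1 --out sim/
pandm fit --input sim/z_values.tsv --z-values --kmin 2 --kmax 10 \
      --seed 1 --fdr 0.01 --out results/
pandm baseline --input sim/z_values.tsv --z-values --method type1 --out base/
```

`fit` writes the per-site membership table, the Q̂ pattern matrix, local-fdr
and binary call matrices, and a JSON model descriptor (all parameters, BIC
trace, log-likelihood trace, seed).

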
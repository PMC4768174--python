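# netinfer

Sparse inference of direct-influence networks from noisy, transient dynamical
data.

## The problem

A dynamical network — a gene regulatory circuit, a signalling pathway, any
coupled ODE system x' = f(x, p) — has a *direct-influence* matrix
S, with S<sub>ij</sub> = ∂f<sub>i</sub>/∂x<sub>j</sub>: a nonzero entry is a
directed arc j → i. What experiments measure, however, is *total* influence:
direct effects plus everything accumulated along indirect paths. The two are
linked by the closure

&nbsp;&nbsp;&nbsp;&nbsp;G = S + S·G &nbsp;&nbsp;⇔&nbsp;&nbsp; G = (I − S)<sup>−1</sup>S,

so in the noise-free case S can be recovered in closed form
(*network deconvolution*, ND): S = G(I + G)<sup>−1</sup>. Real measurements
of G are noisy, and real networks are sparse — which ND ignores. This
package recovers each row of S by basis-pursuit denoising,

&nbsp;&nbsp;&nbsp;&nbsp;min ‖s<sub>i</sub>‖₁ subject to ‖B<sup>T</sup>s<sub>i</sub> − c<sub>i</sub>‖₂ ≤ ε<sub>i</sub>,&nbsp;&nbsp;&nbsp; B = I + G, c<sub>i</sub> = G<sub>i</sub>,

where ε<sub>i</sub> — the *total perturbation* budget — is derived from the
noise level rather than hand-tuned: the package provides the oracle ("true")
budget, a plug-in approximation that needs no ground truth, and a loose
Frobenius upper bound, plus the standard restricted-isometry recovery-error
bound as a diagnostic.

When no total-influence matrix is measurable — only ensembles of noisy
transient time series from parameter-perturbation experiments — the same
row-wise program is applied to the modular-response system
s<sub>i</sub>R = d built from trajectory differences at a time point. The
classic response design leaves one experiment with only indirect,
noise-level responses, making the inversion orders of magnitude more
noise-sensitive (a column of R sits at the noise floor); the robust design
here also perturbs the degradation parameter of the target node and moves
its known linear self-term to the right-hand side, restoring column balance.
Averaging estimates over noise realizations or over random time points
drives truly absent couplings toward zero, which is what the
absence-detection error e (fraction of truly absent arcs whose estimate
exceeds a threshold) measures.

Everything needed to study the method end to end ships with the package:
scale-free network generators, the influence closure, both noise models,
a Michaelis–Menten transient simulator with one-parameter-at-a-time
perturbation ensembles, and the evaluation suite (relative Frobenius error
ρ, absence error e, Hoyer sparsity, AUROC/AUPR and a permutation-null
ξ score for gold-standard edge lists).

## Worked example

```python
import numpy as np
from netinfer import (sample_scale_free, assign_weights, total_influence_closure,
                      add_noise, NoiseSpec, build_linear_system, nd_closed_form,
                      solve_matrix, approx_bound, hoyer, inference_error)

adj = sample_scale_free(n=50, degree_exponent=2.2, edge_budget=70, seed=1)
S0 = assign_weights(adj, seed=2)
G0 = total_influence_closure(S0)
G, dG = add_noise(G0, NoiseSpec("independent", sigma=0.01, seed=3))

form = build_linear_system(G)            # B = I + G, C = G
S_nd = nd_closed_form(G)                 # dense closed-form baseline
S_l1 = solve_matrix(form, approx_bound(G, dG)).S_hat

print(f"rho(ND)  = {inference_error(S_nd.S, S0.S):.3f}   hoyer(ND)  = {hoyer(S_nd.S):.3f}")
print(f"rho(l1)  = {inference_error(S_l1.S, S0.S):.3f}   hoyer(l1)  = {hoyer(S_l1.S):.3f}")
print(f"true nonzeros: {np.count_nonzero(S0.S)}   l1 nonzeros: {np.count_nonzero(np.abs(S_l1.S) > 1e-8)}")
```

prints

```
rho(ND)  = 0.153   hoyer(ND)  = 0.757
rho(l1)  = 0.096   hoyer(l1)  = 0.860
true nonzeros: 70   l1 nonzeros: 231
```

The sparse solution recovers the 50-node, 70-arc network with a 37% lower
relative error than closed-form deconvolution and a much sparser matrix
(Hoyer 0.86 vs 0.76; 231 surviving entries against ND's dense 2500), using
a residual budget computed from the realized noise alone — no ground truth,
no tuning.

The same workflow is available from a shell:

```bash
netinfer simulate -n 50 -e 70 --sigma 0.01 --noise-mode independent -o simdata
netinfer infer simdata/G.tsv --dg-tsv simdata/dG.tsv -o S_l1.tsv --report rows.json
netinfer evaluate S_l1.tsv simdata/gold.tsv
netinfer experiment case1        # or: eps-sweep | averaging | mm
```

Matrices travel as dense TSV (rows = target node i, columns = source node
j), trajectory ensembles as long-format TSV, gold standards as 3-column
edge lists.

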
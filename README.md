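# tfglasso — time-fused graphical lasso

Inference of **slowly-changing dynamic gene-regulatory networks** from
replicated time-course expression data.

Time-course experiments are run to see how a regulatory network *changes*;
analyzing them with a static network model throws that information away,
while fitting an independent network per time point ignores that biological
interactions persist. `tfglasso` estimates a dynamic Gaussian graphical
model over the vertices (gene, time point): a panel of `n` replicates of
`p` genes at `T` time points is modelled as draws from a `pT`-dimensional
multivariate normal whose precision matrix `Θ` encodes conditional
(in)dependence — `θ_ij = 0` exactly when two (gene, time) vertices are
conditionally independent given everything else.

The estimate solves a penalized maximum-likelihood problem

```
Θ̂ = argmin_{Θ ≻ 0}  −log|Θ| + Tr(SΘ)
                     + λ1 Σ_{i≠j} |θ_ij|                      (sparsity)
                     + λ2 Σ_{l≤k} Σ_s ‖N_l^s − N_l^{s+1}‖₁    (persistence)
      subject to     N_l = S_l = 0 for all lags l > k          (AR(k))
```

where `S` is the sample covariance, `N_l^s` are the gene–gene network
blocks of `Θ` between times `s` and `s+l`, `S_l` the same-gene persistence
entries, and `k` the autoregressive order (typically 1). The ℓ1 penalty
gives a sparse network, the fused penalty makes consecutive networks
change slowly, and the AR(k) constraint zeroes all blocks beyond lag `k`.
The solver is an operator-splitting (ADMM) scheme with an exact
eigendecomposition step for the log-det term and an exact 1-D
total-variation prox along each network entry's time chain, so zeros and
fused ties in `Θ̂` are exact. Tuning parameters are selected by AIC / AICc
/ BIC over a heuristic grid (with support-constrained refits for
unbiased scoring) and can be stabilized by half-sample stability
selection. A simulator for slowly-changing dynamic networks with optional
regime changes, edge-recovery metrics (FP/FN/FD/FnD and the aggregate
`F1 = (2−2FN)/(2−FN+FP)`), panel/graph IO (TSV, GraphML) and a CLI round
out the package. See `docs/methods.md` for the full model account.

## Worked example

Simulate a slowly-changing 10-gene, 3-time-point network, select the
penalties by BIC, and score the recovered dynamic graph:

```python
from tfglasso import (DynamicGraphSpec, SimulationConfig, make_truth,
                      sample_panel, heuristic_search, extract_edges,
                      confusion_rates, standardized)

spec = DynamicGraphSpec(p=10, T=3, k=1)
config = SimulationConfig(spec=spec, n=50, base_density=0.1, seed=7)
theta_true, truth = make_truth(config)
panel = sample_panel(theta_true, n=50, seed=8, spec=spec)

sel = heuristic_search(standardized(panel), criterion="bic")
est = sel.best_estimate("bic")
edges = extract_edges(est)
report = confusion_rates(truth, edges, spec)

lam1, lam2 = sel.best["bic"]
print(f"selected lambda1={lam1:.3f}, lambda2={lam2:.3f}")
print(f"estimated edges: {len(edges)} (truth: {len(truth)})")
print(f"FP={report.fp:.4f} FN={report.fn:.4f} FD={report.fd:.4f} "
      f"FnD={report.fnd:.4f} F1={report.f1:.4f}")
print("lag-0 network at t1:", sorted(edges.block_edges(0, 1)))
print("edge changes per transition:", edges.transition_counts())
```

prints

```
selected lambda1=0.490, lambda2=0.091
estimated edges: 40 (truth: 32)
FP=0.0264 FN=0.0000 FD=0.2000 FnD=0.0000 F1=0.9870
lag-0 network at t1: [(3, 9), (4, 9), (5, 6)]
edge changes per transition: [1, 1]
```

Every true edge is recovered (FN = 0); the false-positive rate over the
~1,300 candidate non-edges is 2.6%, for an aggregate F1 of 0.987. The
lag-0 view lists gene–gene interactions within time point 1, and the
transition counts show the estimated network changing by one edge per
step — the slow drift the fused penalty is designed to track.

The same pipeline is available from the shell:

```sh
tfglasso simulate --p 20 --t 3 --n 50 --seed 1 --out-dir sim/
tfglasso select --input sim/panel.tsv --criterion bic --stability --out-dir out/
tfglasso evaluate --truth sim/truth_edges.tsv --estimate out/edges_ic.tsv --p 20 --t 3
```

Each run writes a manifest (seed, parameters, input digests) sufficient to
reproduce it.

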
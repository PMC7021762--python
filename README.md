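# netfrail

Frailness and resilience of networks under simultaneous multi-node
alterations, via a perturbed master equation (pME) — with a genomics layer
that scores patient-specific somatic-mutation configurations on pathway
subnetworks of a protein–protein interaction (PPI) network.

## The model

Information exchange on an undirected, unweighted, connected network with
`M` nodes is modelled as a random-walk master equation

```
dp/dt + L p = 0,      L = D − Π,
```

where `Π` is the column-stochastic transition matrix obtained by
column-normalizing the adjacency matrix, `D = I` its diagonal of column
outflows, and the stationary state `p_s` is the degree distribution.  The
walk satisfies detailed balance, so `L` is self-adjoint under the metric
`G = diag(1/p_s)` and has a real spectrum `0 = λ₁ < λ₂ = λ_F ≤ … ≤ λ_M`
(`λ_F` the Fiedler number).

An alteration of a set `S` of *query nodes* (`|S| = Q`) is modelled by an
extra *environment* node (index 0) exchanging information only with the
query nodes at intensity `ε`:

```
dp/dt + (L₀ + ΔL_ε) p = 0,
```

`L₀` embedding `L` with the environment decoupled and `ΔL_ε` a symmetric
Laplacian perturbation supported on `{0} ∪ S`.  Writing the perturbed
stationary state as `p* = p̂ + α p_s + e₀` and expanding `p̂` in the
G-orthonormal eigenbasis yields a fixed-point iteration whose convergence
breaks down at a critical intensity `μ` — a macroscopic transition at which
the stationary probability currents `J_ik = π*_ik p*_k − π*_ki p*_i` step up
sharply.  The transformed perturbation

```
ΔL′_kj = ΔL̄_kj − (ΔL̄_k1 / ΔL̄_11) ΔL̄_1j,     ΔL̄_kj = v_k · ΔL v_j,
```

defines the **frailness** of the configuration,

```
ρ = ‖ΔL′_ε‖ / λ_F,      μ = ε / ρ(ε),
```

which is zero for any single alteration (at least two co-occurring
alterations are needed to perturb the flow macroscopically), never decreases
when a query node is added, and is largest for configurations that combine
central (hub) and marginal (degree-1) nodes.

The cohort layer maps a binary genes-by-samples mutation matrix
(`a_ij = 1` iff sample `j` has ≥ 1 mutation in gene `i`) onto
pathway-induced PPI subnetworks (largest connected component, 10–500 genes),
scores every sample's mutated-gene set, and summarizes per gene `g` on
network `W` with the **Gene Frailness Index**

```
GFI(W, g) = (σ_{W,g},  ρ̃_{W,g} / max_i ρ̃_{W,i}),
```

the co-occurring-mutation fraction paired with the normalized median
frailness.  A hypergeometric test asks whether the least resilient samples
are enriched for *marginal* mutations (genes of degree 1 in `W`).

## Worked example

```python
import netfrail as nf

net = nf.make_complete_network(20)          # the K20 toy network
ts = nf.build_transition_system(net)
print(f"lambda_F = {ts.lambda_F:.4f}")

res = nf.frailness(ts, ["n0", "n1", "n2"])  # three co-occurring alterations
print(f"rho = {res.rho:.4f}, mu_analytic = {res.mu_analytic:.4f}")

bis = nf.critical_threshold_bisection(ts, ["n0", "n1", "n2"])
print(f"mu_bisection = {bis.mu:.4f}")

print(f"rho(single) = {nf.frailness(ts, ['n0']).rho}")
```

prints

```
lambda_F = 1.0526
rho = 0.9500, mu_analytic = 1.0526
mu_bisection = 1.0526
rho(single) = 0.0
```

The three-node alteration at unit intensity sits just below the critical
regime (`ρ = 0.95 < 1`); its critical intensity coincides with the Fiedler
number — on a complete graph every multi-node configuration destabilizes the
walk exactly at `λ_F`, and below `λ_F` no configuration can.  The single
alteration registers exactly null frailness.

The same analysis over a mutation cohort, from the shell:

```
netfrail --seed 1 simulate --outdir sim            # synthetic PPI + GMT + mutations
netfrail cohort --ppi sim/network.tsv --gmt sim/pathways.gmt \
    --mutations sim/mutations.tsv --outdir out --min-patients 10
```

writes per-pathway `sample_rho.tsv`, `pair_table.tsv` and `gfi.tsv` tables
plus a cohort `summary.json` with the marginal-mutation enrichment p-values.

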
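# bwcrn — Baum–Welch reaction networks

Learning hidden Markov model (HMM) parameters with chemistry: this package
implements a mass-action reaction-network scheme whose ODE dynamics carry
out Baum–Welch (expectation–maximization) learning, alongside the classical
discrete algorithm it mirrors. It is aimed at people working on molecular
programming, distributed/federated inference, and the dynamics of reaction
networks that compute.

## The model

An HMM over hidden states H and visible symbols V is parameterized by an
initial distribution π on H, a row-stochastic transition matrix θ : H → H and
an emission matrix ψ : H → V. The likelihood of an observed word
v₁…v_L is

    P(v | θ, ψ) = Σ_{h₁..h_L} π_{h₁} ψ_{h₁v₁} ∏_{ℓ≥2} θ_{h_{ℓ-1}h_ℓ} ψ_{h_ℓ v_ℓ}.

Classical Baum–Welch alternates the forward recursion (α), the backward
recursion (β), the E-step (posteriors γ, ξ) and the M-step (re-estimated
θ′, ψ′) until the parameters stop moving.

The reaction-network scheme represents every one of these variables by a
chemical species. Each reaction converts exactly one molecule of one species
into one molecule of another from the same family, driven by catalyst
species that appear unchanged on both sides — the futile-cycle motif of
phosphorylation/dephosphorylation pairs. Flow within each family is routed
through a designated hub species (a reference hidden state h\* and visible
symbol v\*), with rate constants 1, so that at steady state the
concentration ratios equal the Baum–Welch ratios. The observed sequence
enters only through fixed indicator catalysts E\[ℓ,w\] (1 iff symbol w is
observed at position ℓ): one network serves every sequence of a given
length.

The network can be run three ways:

* **BW1** — equilibrate the subnetworks one at a time in the classical
  order; iterate-for-iterate identical to discrete Baum–Welch.
* **BW2** — alternate an inference module (α, β, γ, ξ jointly) and a
  learning module (θ′, ψ′, π′ jointly); same per-iteration equilibria, with
  exponentially fast convergence inside each module.
* **BW3** — identify θ with θ′ and ψ with ψ′ and integrate everything
  simultaneously as one autonomous ODE. Its positive equilibria are exactly
  the positive fixed points of the discrete algorithm; on the boundary of
  the parameter simplex the two dynamics can genuinely part ways, and this
  package reproduces those boundary phenomena.

Multiple sequences and an unknown π are supported (per-sequence trellis and
E species share the parameter species; π′ is learned from the
position-1 posteriors).

## Worked example

The boundary case that separates the continuous from the discrete dynamics
is the five-symbol word `v2 v1 v2 v1 v2`:

```python
import numpy as np
from bwcrn.experiments import run_length5_example

rep = run_length5_example()
print(np.round(rep.fitted["bw"].theta, 3))   # discrete Baum-Welch limit
print(np.round(rep.fitted["bw3"].theta, 3))  # autonomous (BW3) limit
print(np.round(rep.fitted["bw3"].psi, 3))
```

prints

```
[[0. 1.]
 [1. 0.]]
[[0.171 0.829]
 [1.    0.   ]]
[[0. 1.]
 [1. 0.]]
```

Both routes learn the same deterministic emissions (state 1 ↔ v2,
state 2 ↔ v1) and the same pinned second transition row, but the discrete
algorithm drives θ₁₁ all the way to 0 while the autonomous flow freezes at
an interior value — the reaction rates feeding that species vanish along the
trajectory, so the limit depends on where the dynamics started. Restarted
at the continuous limit, the discrete algorithm falls back to its own
equilibrium (`rep.fitted["bw_from_bw3_limit"]`). The log-likelihood is
non-decreasing along both routes.

The same machinery is exposed on the command line:

```
bwcrn sample --counts 49 51 --seed 7 --out seq.txt
bwcrn build -H 2 -V 2 -L 5 --format both --out-dir net/
bwcrn fit --mode bw3 --params init.json --sequences seq.txt --out-dir run/
bwcrn experiment casino --seed 1 --out-dir casino/
```

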
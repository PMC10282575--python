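# Methods

## Discrete Baum–Welch core

`bwcrn.hmm` implements the standard recursions. Forward and backward tables
are computed with per-position scaling by default: each α row is divided by
its sum c_ℓ and the log-likelihood is recovered as Σ log c_ℓ. Raw
(unscaled) recursions underflow around L ≈ 100 for typical parameters;
every E-step quantity is a ratio of α·β products within one position, so
scaling is exactly neutral for γ, ξ and for all parameter updates. The
brute-force likelihood (`brute_force_likelihood`) enumerates all |H|^L
hidden paths and is the package's independent oracle; it refuses instances
with more than 10⁶ paths.

Domain handling. The valid region Θ is where no Baum–Welch step divides by
zero; `check_theta_region` evaluates the printed condition
Σ_ℓ α_ℓh β_ℓh > 0 for every h, and additionally reports the
positivity-preservation precondition (all symbols observed; π > 0, L ≥ 2,
or coverage by v₂…v_L with L ≥ 3). Because that region condition does not
by itself rule out a vanishing θ′-row denominator (a sum over ℓ ≤ L−1
rather than ℓ ≤ L), the E-step and the M-step each guard their own
denominators independently and raise `OutOfDomainError` naming the
offending position or row. A likelihood of exactly zero returns −∞ rather
than raising, so boundary experiments can proceed.

Conventions: symbols are indexed by order of appearance in the declared
alphabet; ties in any argmax (posterior decoding) resolve to the lowest
index; `bw_fit` stops when the max-abs parameter change falls below `tol`
(default 1e-10, `max_iter` 10 000).

## Network construction

`bwcrn.network` emits one species per Baum–Welch variable and one reaction
pair per balance relation (hub-and-spokes within each family). Design
points:

* **Hub reactions.** Conversion of a non-hub species into the hub is
  catalysed by the hub's own defining product (e.g. π_{h\*} ψ_{h\* v₁} for
  the first forward row); the reverse conversion by the non-hub species'
  product. At steady state this enforces exactly the forward/backward/
  E-step/M-step ratio. For the ξ family the out-of-hub catalyst on the
  backward side is β_{ℓ+1,h} (the destination state of the transition); the
  choice is pinned down by requiring the subnetwork equilibrium to equal
  the posterior transition probabilities, which the test suite checks
  directly.
* **No-op reactions** (hub onto itself) are omitted: they have zero net
  effect, and dropping them only shrinks the ODE.
* **Rate constants** are fixed at 1; the `Reaction` type carries a rate
  field for generality.
* **E species** are implemented as fixed catalyst parameters, never state
  variables; their concentrations are the 0/1 sequence indicators and stay
  constant by construction. Reactions whose E catalyst is zero are pruned
  before compilation, which shrinks the active ODE by a factor |V| without
  changing the dynamics.
* **Reference states.** h\* defaults to the first hidden state; v\* to the
  first symbol that actually occurs in the data (an unobserved v\* would
  leave the ψ′ hub with no inflow and freeze that subnetwork). All
  equilibria of positive runs are independent of these choices (tested);
  at boundary equilibria the hub choice determines which θ′ row pins, see
  the length-5 discussion below.
* **β_L.** The last backward row has no reactions (its value 1 is an
  initial condition of the recursion); the schemes initialize it uniformly
  (B_L/|H|) so its ratios encode β_L ∝ 1. A deliberately non-uniform β_L
  initialization would corrupt the position-L posterior — this is an
  implicit assumption of the scheme, not enforced chemistry.
* Zero parameters are built as-is (no clipping); an ε-floor is available in
  principle but off by default, because the boundary dynamics are part of
  what the package studies.

`export_text` round-trips through `import_text`; SBML level-3 documents are
written directly (write-only) with species, modifiers and mass-action
kinetic laws.

## Subnetwork equilibria and the closed form

With catalysts frozen, every subnetwork is a linear (mono-molecular) flow
on one conserved class, a star graph through its hub. `linear_network_limit`
computes the exact t → ∞ limit of such a flow:

* Strongly connected graph: the unique stationary distribution scaled to
  the conserved total. Because the graph is a tree when viewed undirected,
  the stationary state satisfies detailed balance edge by edge, and is
  computed by ratio propagation along a spanning tree. This is numerically
  exact in a relative sense even when rates span hundreds of orders of
  magnitude — important near the boundary, where an SVD null space (or a
  generic linear solve) degrades catastrophically and was observed to
  derail late Baum–Welch iterates.
* Not strongly connected (some zero rates): transient mass is absorbed
  into the terminal strongly connected components according to the embedded
  jump chain, reproducing the drained-component and dead-end phenomenology
  of degenerate parameters; such calls set a boundary flag.

BW1 and BW2 default to this closed form (`equilibration="closed_form"`),
which makes "run to equilibrium" exact and fast; an `integrate` mode
(LSODA on the module ODE, chunked with doubling horizons until the vector
field drops below `eq_tol`) is retained and tested against the closed form.
Consequently the BW1-vs-discrete agreement is exact by construction up to
floating point — the substantive numerical checks are the integrate-mode
agreement, the BW3 equilibria, and the conservation/balance properties of
the assembled ODE.

## BW3 (autonomous) integration

`run_bw3` rewires catalysts so θ ≡ θ′, ψ ≡ ψ′ (and π ≡ π′ when learning π)
and integrates the full mass-action ODE with LSODA (stiff-capable,
automatic switching) using an analytic Jacobian assembled from the reaction
list. Defaults: rtol 1e-8, atol 1e-10, t_max 10⁴ time units. Convergence is
declared when the max-abs vector-field component on the parameter species
falls below `eq_tol` (1e-8); trellis species equilibrate implicitly.
Trajectories record (θ′, ψ′, π′) and the log-likelihood on a thinned grid.
Negative concentrations from integrator drift are clamped to zero only when
evaluating the residual, never in the reported state, and clamp events are
counted. Trellis species start uniform within each conserved class
(totals A_ℓ = B_ℓ = 1; results are invariant under rescaling these totals,
which is tested); `init_trellis="equilibrium"` warm-starts them at their
inference equilibria, which makes the state exactly stationary when the
parameters are a fixed point.

The equilibrium report carries two residuals: the scheme residual (vector
field at the final state) and the Baum–Welch residual (max-abs change under
one discrete update), plus a boundary flag (any parameter below 1e-6, or
non-convergence by t_max).

## Boundary behaviour and the worked examples

On the interior the three semantics and the discrete algorithm agree — this
is the content of the randomized agreement suite. On the boundary they may
not, and the package treats that as a result rather than a defect:

* **Symmetric fixed point.** For any binary sequence, uniform
  initialization is closed under the update: one M-step already yields
  θ uniform and ψ rows equal to the empirical symbol frequencies, and both
  the discrete algorithm and BW3 stay on that point (checked exactly for
  the 49/51 length-100 sequence). These symmetric points are also the
  supply of guaranteed-positive fixed points used in the fixed-point
  stationarity checks, since generic short random sequences almost always
  have boundary maximum-likelihood estimates.
* **Length-5 example** (`v2 v1 v2 v1 v2`). The discrete algorithm reaches
  the alternating deterministic point θ = [[0,1],[1,0]], ψ = [[0,1],[1,0]]
  from a wide range of positive starts. BW3 reaches a *different* boundary
  point with the same ψ, the same pinned θ row for the v1-emitting state,
  and an interior entry in the other θ row: the ξ species feeding that row
  lose their own inflow along the trajectory, so the row's relaxation rate
  decays roughly exponentially in time and the row freezes at a
  trajectory-dependent value (the same mechanism as a reaction with rate
  e^{-t}, which transports only a finite amount of mass). The frozen value
  therefore depends on the initialization; the structure of the limit does
  not. The packaged default initialization (θ₀ = [[0.5,0.5],[0.6,0.4]],
  ψ₀ = [[0.3,0.7],[0.6,0.4]], π = (0.5,0.5)) is a fixed, documented choice;
  the experiment accepts any explicit initialization. The hub is placed at
  the second hidden state for this experiment so the limit appears in the
  conventional orientation (interior first row); at boundary limits the hub
  determines which row pins, an observed and reproducible asymmetry that
  disappears in the interior.
* The BW3 limit lies in Θ, and the discrete algorithm restarted there
  returns to its own equilibrium — so boundary equilibria of the flow need
  not be fixed points of the discrete map.

Log-likelihood monotonicity along BW3 trajectories holds to ~1e-6 on the
worked examples. It is not guaranteed during the initial transient of an
arbitrary run: with trellis species started uniform, the parameters can dip
briefly while the inference species relax toward their posteriors.

## Synthetic data

`sample_sequence` draws exact joint samples (hidden path + emissions) from
any HMM with a seeded generator. The casino experiment uses the two-state
(Honest/Dishonest) three-symbol generator π = (1,0),
θ = [[0.95,0.05],[0.25,0.75]], ψ = [[0.34,0.33,0.33],[0.01,0.01,0.98]],
300 rolls, training on the first 150 and decoding the last 150 — the
stated conditions of that example. Initialization is a seeded row-wise flat
Dirichlet draw. The generator emulates i.i.d.-conditional categorical
emissions only; it does not model duration structure, emission drift, or
observation noise beyond the HMM itself, so passing tests speak to the
algorithms, not to robustness on real sequence data. When deposited roll
sequences/initializations are supplied as files the experiment uses them;
otherwise it runs on locally sampled stand-ins and flags in its notes that
comparisons against externally printed log-likelihood values are not
applicable. Decoded hidden-state tracks are compared both raw and after the
best relabeling of hidden states (training identifies states only up to
permutation).

## Problem sizes and tolerances in the shipped checks

The test suite and the acceptance script use: the full 50-instance
randomized agreement suite (|H|, |V| ∈ {2,3}, L ∈ 3..10) with 5 iterations
per instance; BW2 and the integrate-mode cross-checks on subsets; BW3
equilibrium checks on lengths 12–30 (interior direction) and 6–15 (reverse
direction); the length-100 symmetric example and the 150-roll casino
training in full. These sizes keep a complete run around a minute while
exercising every code path; all tolerances above are the defaults the
package ships with.

## Known limitations

* Stochastic (discrete-molecule-count) semantics are out of scope; the
  dynamics here are deterministic mass-action ODEs.
* SBML export is write-only; round-tripping uses the text format.
* Near-boundary BW3 runs can take long to freeze (rates decay with the
  state); `t_max` caps the integration and such runs are flagged rather
  than polished.
* The casino experiment's printed-value comparisons require the original
  deposited sample and initialization; without them only qualitative and
  magnitude-level statements are reproduced.
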
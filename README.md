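# crnlyap

Kinetics-independent stability certification for biochemical reaction
networks.

Most models of cellular processes — post-translational modification (PTM)
cycles, phosphorelays, kinetic proofreading, translation — are chemical
reaction networks whose *stoichiometry* is well known but whose *kinetics*
(rate laws and constants) are not. `crnlyap` answers a question that does
not require the kinetics: **given only the reaction list, can the network
exhibit multistability, oscillation, or chaos at all?** Networks for which
the answer is provably "no" are *structurally attractive*: every admissible
monotone kinetics drives each stoichiometric class to a unique steady
state. The package is for modelers who want to rule competing mechanisms in
or out (e.g. processive vs. distributive phosphorylation) before fitting a
single rate constant.

## The certificate

A network with reactant/product coefficient matrices A, B and stoichiometry
Γ = B − A evolves as ẋ = Γ R(x). For any admissible kinetics (each rate R_j
smooth, zero without its reactants, strictly increasing in them), the rate
vector r = R(x) obeys ṙ = ρ(t) Γ r where ρ = ∂R/∂x is unknown but has a
known sign pattern. Consequently ṙ lives in the convex cone spanned by the
rank-one extremals

    Q_ℓ = e_{j_ℓ} γ_{i_ℓ}ᵀ,   one per reaction–reactant pair (j, i),

where γ_i is row i of Γ. A **Robust Lyapunov Function** (RLF) is a function
V(r) ≥ 0 with V(r) = 0 iff r ∈ ker Γ that is a common Lyapunov function for
all the linear systems ṙ = Q_ℓ r; its existence certifies structural
attractivity. `crnlyap` constructs RLFs four ways:

* **Graphical (max–min)** — for "M-networks" (reversible reactions can be
  oriented so ker Γ̃ of the irreversible subnetwork is one-dimensional),
  V = max R − min R over the normalized forward-minus-backward rate
  differences, read off the graph.
* **Sum of currents** — V = Σᵢ ξᵢ |ẋᵢ| = ‖diag(ξ) Γ r‖₁ with weights ξ
  found by a single linear program.
* **Piecewise linear over a conic partition** — a joint LP over regions
  W_k = {r : Σ_k H r ≥ 0} (default H = Γ) for V = |c_kᵀ r| on ±W_k, with
  Farkas multipliers as the certificate.
* **Piecewise quadratic (semidefinite relaxation)** — V = rᵀP_k r region-
  wise, via a copositive relaxation; when a PWL certificate exists the
  rank-one point P_k = c_k c_kᵀ is written down in closed form.

Two necessary conditions cheaply rule certificates out: the negative
species-space Jacobian must be a P0 matrix (all principal minors ≥ 0 as
polynomials in the pair weights ρ), and — for conservative M-networks or
robustly non-degenerate networks — no *critical siphon* (a species set
that, once extinct, stays extinct and supports no conservation law) may
exist. Every certificate is re-verified by independent region-wise LPs,
randomized decrease sampling, and Dini-derivative checks along simulated
trajectories.

## Worked example

The full PTM cycle (kinase E phosphorylates substrate S to S⁺ through the
complex SE; phosphatase F reverts it through S⁺F):

```sh
$ crnlyap analyze fixture:ptm_full
network: ptm_full
  species 6, reactions 6, deficiency 1
  conservative=True AS1=True autocatalytic=False M-network=True
  P0: pass
  minimal siphons: [('E', 'SE'), ('F', 'S+F'), ('S', 'SE', 'S+', 'S+F')]
  robustly nondegenerate (rho=1): True
  graphical: success: V = max R - min R, R = {R1-R-1, R2, R3-R-3, R4}
verdict: attractive
```

The network is conservative with three conservation laws (total substrate,
kinase, phosphatase), has deficiency one (so classical deficiency theory is
silent), every minimal siphon contains a conservation-law support, and the
graphical criterion delivers the certificate V = max R − min R over
{R₁−R₋₁, R₂, R₃−R₋₃, R₄}: with any admissible kinetics, each stoichiometric
class has a unique, globally attracting steady state. The same library
calls are available in Python, where the certificate supports quantitative
use:

```python
>>> from crnlyap import fixture, mass_action, steady_state, construct_soc
>>> net = fixture("ptm_full")
>>> soc = construct_soc(net)               # V = sum xi_i |xdot_i|
>>> [int(x) for x in soc.xi]
[2, 1, 1, 2, 1, 1]
>>> ss = steady_state(net, mass_action(net, 1.0),
...                   x0=[10., 10., 0., 0., 10., 0.])
>>> round(float(ss.x[0]), 6)               # free substrate at steady state
1.216991
```

With unit rate constants and totals [S]ₜ = [E]ₜ = [F]ₜ = 10, the free
substrate settles at (−7 + √89)/2 ≈ 1.216991 and each free enzyme at that
value + 5 — computed by solving Γ R(x) = 0 in the class, and guaranteed
unique by the certificate above. The same machinery computes safety level
sets (`safety_level`) and kinetics-free flux bounds (`flux_bound`), and the
distributive double-phosphorylation cycle is correctly *excluded* (its
negative Jacobian is not P0; a random parameter search exhibits
bistability):

```sh
$ crnlyap analyze fixture:distributive_double ; echo "exit $?"
...
  P0: fail (witness minor on ('X0', 'E', 'X1', 'FX1', 'EX1'))
verdict: excluded
exit 1
```

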
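# Methods

## Model and scope

A chemical reaction network is a species set {X₁..X_n} and reaction set
{R₁..R_ν} with nonnegative integer reactant coefficients α_ij (matrix A),
product coefficients β_ij (matrix B) and stoichiometry Γ = B − A; a
reversible reaction is stored as two adjacent columns (forward, then
reverse). Concentrations evolve as ẋ = Γ R(x). Kinetics are never assumed
beyond admissibility: R_j is C¹, depends only on its reactants, vanishes
when a reactant is absent, and is nondecreasing in each reactant (strictly
at positive concentrations). Mass-action, Michaelis–Menten and Hill laws
are admissible instances.

Because ∂R/∂x has a known zero/sign pattern, the rate dynamics
ṙ = (∂R/∂x) Γ r are embedded in the cone spanned by the rank-one extremals
Q_ℓ = e_{j_ℓ} γ_{i_ℓ}ᵀ, one per reaction–reactant pair, enumerated
column-major (by reaction, then species). A Robust Lyapunov Function (RLF)
is a locally Lipschitz V(r) ≥ 0 with V = 0 exactly on ker Γ whose Dini
derivative along every ṙ = Q_ℓ r is nonpositive; its existence makes the
network structurally attractive (unique steady state per stoichiometric
class, no oscillation or chaos, for every admissible kinetics). All
structural linear algebra (kernels, ranks, minors, flux vectors) is done in
exact rational arithmetic (sympy / fractions); floating point appears only
inside optimization and ODE integration.

## Conic partitions

Piecewise candidates live on the partition of rate space by sign patterns
of H r with ker H = ker Γ (default H = Γ; optional extra rows from the row
space, typically γ_i ± γ_j). Signatures are enumerated depth-first with
pruning; a region is kept iff {Σ H r ≥ ε·1, |r|_∞ ≤ 1} is feasible with
ε = 10⁻⁶ (strict interior), and one representative per ± pair is stored.
The enumeration is capped at p ≤ 20 rows; beyond that the LP/SDP routes
refuse and the iterative or graphical routes (which need no partition)
apply.

## Constructions

**Joint LP.** Variables per kept region: coefficients c_k, positivity
multipliers ξ_k ≥ 0 with c_kᵀ = ξ_kᵀ Σ_k H and the normalization
1ᵀξ_k = 1 (the LP-representable form of strict positivity); per region and
extremal: λ_kℓ with c_kᵀ Q_ℓ = −λ_kℓᵀ H, Σ_k λ_kℓ ≥ 0 (a Farkas
certificate of decrease on W_k). Two choices were genuinely open and are
resolved as follows:

* *Facet continuity.* The region-wise constraint set alone admits solutions
  whose pieces disagree on shared facets — such a "V" is not a function and
  demonstrably increases along trajectories. We therefore always add
  c_k − sign·c_j = η h_s across every neighboring pair (signatures at
  Hamming distance one whose shared facet has relative interior). This is
  sufficient for well-definedness and may be mildly conservative (the
  pairing with +c_j is fixed); sum-of-currents solutions satisfy it
  automatically.
* *Degeneracy.* After solving, ker C = ker Γ is checked (rank comparison);
  a feasible but rank-deficient solution is reported as "feasible but
  degenerate", not as a certificate.

When the network has no strictly positive steady-state flux (no v ≫ 0 in
ker Γ), the same LP runs with the continuity constraints and is labeled
"AS1-fallback"; its products are additionally screened by the sampling
oracle. Infeasibility always means "no PWL RLF over this H", never
nonexistence over all partitions.

**Sum of currents (SoC).** For H = Γ the decrease condition on a region
with signature σ reduces exactly, pair by pair, to
σ_i (Σ_{i'} ξ_{i'} σ_{i'} Γ_{i'j}) ≤ 0: one LP in the n species weights.
We minimize 1ᵀξ subject to ξ ≥ 1 (scale-invariant normalization of ξ ≫ 0)
and integer-scale the optimizer. The minimizer is a canonical
representative; other feasible weightings are equally valid certificates
and can be verified with `verify_pwl`.

**Iterative algorithm.** Rows grow from C = Γ: for each processed row c_k,
each reaction j in its support and each reactant X_i of R_j, the row
c* = c_k + sgn(c_kj) γ_i is appended unless it equals an existing row or
zero; iteration order is reaction index ascending, then species index
ascending; success when a full pass adds nothing. Rows are exact integers;
the result is the convex function V = max(0, max_k c_kᵀ r). The row set
depends on the (documented) iteration order, so equality tests in the suite
are up to closure under negation, and every result is order-independently
re-verified. The cap default (60–100 passes) returns "not converged",
which is inconclusive, not a refutation.

**Graphical max–min.** For non-autocatalytic networks whose reversible
pairs can be oriented so the irreversible subnetwork Γ̃ has
dim ker Γ̃ ≤ 1. Flipping an orientation only negates a column, so the
kernel dimension is orientation-invariant; for dim = 1 the orientation with
nonnegative kernel vector w (normalized so its smallest positive entry is
1) is unique up to zero entries, and for dim = 0 ("zero-flux") the
orientation is searched lexicographically (forward-as-written first) for
one meeting the graphical conditions. Conditions on the oriented
subnetwork: (i) every species is a reactant of exactly one subnetwork
reaction — relaxed to *at most one* in the zero-flux case, where complexes
such as XE in simple binding are reactants of no oriented reaction; and
(ii) no product of an oriented-forward reversible reaction is produced by
any other subnetwork reaction. The certificate is
V = max R − min R over R = {(R_j − R_{−j})/w_j} ∪ {R_j/w_j}, with the
constant 0 appended in the zero-flux case (so simple binding yields
V = |R₁ − R₋₁|). These two conventions (the "reactant-of" reading and the
zero-flux embedding) are our documented resolutions of genuinely ambiguous
statements; they reproduce every worked example in the catalog.

**Piecewise quadratic relaxation.** Exact copositive programming is
NP-hard, so copositivity on a region is relaxed to "PSD plus entrywise
nonnegative". When a PWL certificate over the same partition exists, the
rank-one point P_k = c_k c_kᵀ is feasible with closed-form relaxation
certificates (positivity: A = 0; decrease: B_kℓ2 = λξᵀ + ξλᵀ built from the
LP multipliers; continuity: λ_kj = η c_j + η²/2 h), so no numerical
semidefinite solve is needed. Otherwise a Dykstra alternating-projection
feasibility search runs over the affine constraint set and the
PSD/nonnegative cones (with c_k = 0 and a trace normalization excluding the
trivial point), capped at 3000 sweeps with tolerance 10⁻⁷; non-convergence
is reported as "no certificate under this relaxation" (a relaxation gap is
possible). All quadratic candidates are screened by sampled positivity and
decrease on ~10⁴ region points.

## Verification

`verify_pwl` is independent of every construction route: per piece
(c_k on {G_k r ≥ 0}) and extremal Q_ℓ it solves
max c_kᵀ Q_ℓ r s.t. G_k r ≥ 0, |r|_∞ ≤ 1 and requires every optimum
≤ 10⁻⁸; partition-form candidates are additionally checked for facet
continuity and ker C = ker Γ, max-form candidates for
{r : C r ≤ 0} = ker Γ (a set of small LPs on the complement of the
kernel). Orthogonal to the LPs, `sampled_decrease_check` draws ~10⁴ random
(ρ ≥ 0, r) pairs and evaluates the Dini derivative of V along
Σ ρ_ℓ Q_ℓ r, and `dini_decrease_check` evaluates forward difference
quotients of V(R(x(t))) along stiff-integrated trajectories with threshold
10⁻⁶ (1 + max V).

## Necessary conditions

**P0.** Each principal minor of −Γ M(ρ) (M(ρ) carrying one variable per
reaction–reactant pair) is a polynomial whose monomials biject with partial
matchings of the pair graph; the coefficient of matching L is
(−1)^{|L|} det Γ[S_L, T_L] sgn(π_L), computed exactly. All coefficients
≥ 0 certify "pass". A negative coefficient is converted into a numeric
witness by unit weights on the matching and 10⁻⁶ elsewhere (the matching
monomial then dominates the minor); random restarts are a backstop, and
"undetermined" is returned when suspicion cannot be confirmed — a negative
coefficient alone does not prove polynomial negativity on ρ ≥ 0. Size cap
n ≤ 12.

**Siphons.** A species set P is a siphon iff every reaction producing a
member has a reactant in P. Minimal siphons are enumerated over the subset
lattice in increasing size with superset pruning (cap n ≤ 20; a partial
report is flagged). A siphon is trivial iff a nonnegative conservation law
is supported inside it (an LP); critical otherwise. Certificate preclusion
applies only under a positive steady-state flux and fires when (a) a
critical siphon is a deadlock (every reaction has a reactant in it), (b)
the network is a conservative M-network, or (c) it is conservative and the
reduced Jacobian at unit pair weights is nonsingular — clause (c)
instantiates "some admissible kinetics" at ρ = 1, the same sufficient
instantiation used for robust non-degeneracy, and is flagged as such.

**Robust non-degeneracy.** The species-space Jacobian at ρ = 1 restricted
to Im Γ via an exact rational basis; the determinant is exact, so the
verdict has no numerical tolerance in practice.

**Coordinates.** A verified rate-space pair (C, H) converts to a
concentration-space pair (B, G) by least-norm solves of C = BΓ, H = GΓ
(consistent because ker C = ker Γ), with rows snapped to exact rationals
when possible and round-trip checked; the left-kernel basis D is returned
because B is only determined modulo Y Dᵀ.

## Simulation and quantitative use

Integration uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰; states are clipped to
the nonnegative orthant (the raw excursion is monitored and stays below
10⁻⁹) and conservation drift is reported. Steady states are solved by
bounded least squares on [Γ R(x); L x − class values] warm-started from a
simulation; residual tolerance 10⁻¹⁰.

Safety levels: α is the minimum of V(R(x)) over the slice of a
stoichiometric class where one species sits at its bound, found by
multi-start (20) SLSQP; since the optimization is local, α is reported as
an upper-bound certificate and the suite falsification-tests it with
trajectories started below 0.95 α. The slice-minimum definition of α is a
design choice; trajectories with V < α provably cannot reach the slice.

Flux bounds: `flux_bound` maximizes one flux subject to r ≥ 0,
‖C r‖_∞ ≤ ‖C r_init‖_∞ and a cap on the inflow flux. Two C matrices are
relevant for a sum-of-currents certificate: `soc_to_infnorm` performs the
exact 1-norm → ∞-norm conversion by sign enumeration over the support of ξ
(capped at 2¹⁵ rows) and is the right choice when the level set must be a
true safety set; the weighted-currents matrix C = diag(ξ) Γ gives the
looser ∞-norm-of-currents constraint used in the proofreading flux
analysis, whose N = 2 optimum is exactly 3 r₁*. Flux bounds translate to
concentration bounds by inverting a monotone rate law (`invert_rate_law`;
closed forms for linear and Michaelis–Menten laws, bisection otherwise,
with "unreachable" reported beyond the law's range).

## Fixtures and synthetic inputs

Every catalog network is built from its reaction-list text with a frozen
species ordering (weight vectors are order-dependent). Parameterized
families (cascades, phosphorelays, proofreading chains, ribosome flow)
construct any size n ≥ 1 and the suite re-verifies certificates at n + 2 to
guard off-by-one bugs. `random_network` draws small networks (n, ν ≤ 6,
coefficients ≤ 2, no empty reaction) for property tests of the deficiency
formula and the siphon enumerator.

The multistability witness for the distributive double cycle is a seeded
random search: mass-action constants log-uniform in [0.1, 10], substrate
total 100 against enzyme totals 1 (the strongly saturated regime in which
distributive cycles are known to switch), trajectories from the two extreme
substrate distributions, and a witness requires both limits to be steady
(residual < 10⁻⁶) and separated by more than 5 concentration units. These
are defaults of the search, not fitted values; typical seeds produce a
witness within a handful of trials.

What passing tests show — and do not. The suite validates certificates
against admissible kinetics drawn from the three built-in law families at
random parameters, and mono-attractivity by sampled initializations at a
finite horizon. It does not sample the full space of admissible kinetics
(the LP verification covers that exhaustively at the level of the extremal
cone), and simulation-based checks inherit integrator tolerances; exact
claims always rest on the rational-arithmetic certificates, with simulation
as falsification.

## Known limitations

* LP/SoC/SDP infeasibility is relative to the chosen partition H; only the
  P0 and siphon conditions rule out PWL RLFs over all partitions.
* The enforced facet-continuity pairing may exclude exotic continuous
  solutions whose adjacent pieces match with opposite sign.
* The quadratic route's Dykstra search is a feasibility heuristic: failure
  to converge is not infeasibility of the relaxation.
* The iterative algorithm's termination is input-dependent and its row set
  order-dependent; only verified outputs are reported.
* Networks larger than the partition cap (p > 20) or the P0/siphon caps
  (n > 12 / 20) receive partial reports, flagged as such.
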
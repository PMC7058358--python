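"""Concrete admissible kinetics, ODE simulation, and quantitative use of
Lyapunov certificates (steady states, safety levels, flux bounds).

Admissible rate laws are smooth, vanish when a reactant is absent, and are
monotone nondecreasing in each reactant (strictly, at positive
concentrations). Mass-action, Michaelis-Menten and Hill laws are provided;
a custom monotone law can be supplied as a callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, linprog, minimize

from . import _exact
from .core import Network, conservation_analysis


# ---------------------------------------------------------------------------
# rate laws


@dataclass
class RateLaw:
    """One reaction's rate law. kinds: "mass_action" (k prod x_i^alpha),
    "michaelis_menten" (k prod (x_i/(K_i + x_i))^alpha),
    "hill" (k prod (x_i^h/(K_i^h + x_i^h))), "custom" (callable f(x_sub)
    over the reactant concentrations, declared monotone)."""
    kind: str = "mass_action"
    k: float = 1.0
    K: dict[str, float] = field(default_factory=dict)
    hill: float = 2.0
    func: object = None

    def validate(self):
        if self.kind != "custom" and self.k <= 0:
            raise ValueError("kinetic constant must be positive")
        if self.kind == "hill" and self.hill < 1:
            raise ValueError("Hill coefficient must be >= 1")
        if any(v <= 0 for v in self.K.values()):
            raise ValueError("half-saturation constants must be positive")


class Kinetics:
    """Evaluable rate map R(x) with analytic Jacobian whose sparsity is
    locked to the reaction-reactant pair set."""

    def __init__(self, net: Network, laws: list[RateLaw]):
        if len(laws) != net.n_reactions:
            raise ValueError("one law per reaction column required")
        for law in laws:
            law.validate()
        self.net = net
        self.laws = laws

    def __call__(self, x) -> np.ndarray:
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        A = self.net.A
        out = np.zeros(self.net.n_reactions)
        for j, law in enumerate(self.laws):
            reactants = np.nonzero(A[:, j])[0]
            if law.kind == "custom":
                out[j] = law.func(x[reactants])
                continue
            val = law.k
            for i in reactants:
                a = A[i, j]
                xi = x[i]
                name = self.net.species[i]
                if law.kind == "mass_action":
                    val *= xi ** a
                elif law.kind == "michaelis_menten":
                    Km = law.K.get(name, 1.0)
                    val *= (xi / (Km + xi)) ** a
                elif law.kind == "hill":
                    Km = law.K.get(name, 1.0)
                    h = law.hill
                    val *= xi ** h / (Km ** h + xi ** h)
                else:
                    raise ValueError(f"unknown law kind {law.kind!r}")
            out[j] = val
        return out

    def jacobian(self, x, eps: float = 1e-7) -> np.ndarray:
        """dR/dx; analytic for mass-action, finite differences otherwise
        (sparsity locked to the pair set either way)."""
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        A = self.net.A
        J = np.zeros((self.net.n_reactions, self.net.n_species))
        base = self(x)
        for j, law in enumerate(self.laws):
            for i in np.nonzero(A[:, j])[0]:
                if law.kind == "mass_action":
                    a = A[i, j]
                    if x[i] > 0:
                        J[j, i] = a * base[j] / x[i]
                    else:
                        xx = x.copy()
                        xx[i] = eps
                        J[j, i] = a * self(xx)[j] / eps
                else:
                    xp = x.copy()
                    xp[i] += eps
                    J[j, i] = (self(xp)[j] - base[j]) / eps
        return J

    def rhs(self, t, x):
        return self.net.Gamma.astype(float) @ self(x)


def make_kinetics(net: Network, spec="mass_action", params=None) -> Kinetics:
    """Build admissible kinetics for a network.

    ``spec`` may be a single law kind applied to all reactions, a list of
    :class:`RateLaw`, or a list of (kind, param-dict) tuples. ``params`` may
    carry a vector of kinetic constants ``k`` for the uniform case.
    """
    nu = net.n_reactions
    if isinstance(spec, str):
        ks = np.asarray((params or {}).get("k", np.ones(nu)), dtype=float)
        if ks.size == 1 and nu != 1:
            ks = np.full(nu, ks.item())
        laws = [RateLaw(kind=spec, k=float(ks[j])) for j in range(nu)]
    else:
        laws = []
        for entry in spec:
            if isinstance(entry, RateLaw):
                laws.append(entry)
            else:
                kind, p = entry
                laws.append(RateLaw(kind=kind, **p))
    return Kinetics(net, laws)


def mass_action(net: Network, k=1.0) -> Kinetics:
    ks = np.asarray(k, dtype=float)
    if ks.ndim == 0:
        ks = np.full(net.n_reactions, float(ks))
    return make_kinetics(net, "mass_action", {"k": ks})


# ---------------------------------------------------------------------------
# simulation


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray                     # n x T
    r: np.ndarray                     # nu x T
    kinetics: Kinetics
    success: bool
    message: str = ""
    min_state: float = 0.0            # most negative raw state (projection)
    conservation_drift: float = 0.0

    def to_table(self, species: list[str] | None = None,
                 sep: str = "\t") -> str:
        """Delimited time-series table (time, states, fluxes)."""
        n, nu = self.x.shape[0], self.r.shape[0]
        head = ["t"] + (list(species) if species
                        else [f"x{i+1}" for i in range(n)]) \
            + [f"R{j+1}" for j in range(nu)]
        lines = [sep.join(head)]
        for q in range(len(self.t)):
            row = [f"{self.t[q]:.6g}"] + [f"{v:.8g}" for v in self.x[:, q]] \
                + [f"{v:.8g}" for v in self.r[:, q]]
            lines.append(sep.join(row))
        return "\n".join(lines)

    def plot(self, path: str, species: list[str] | None = None):
        """Time-series plot written to an image file."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        labels = species or [f"x{i+1}" for i in range(self.x.shape[0])]
        for i, lab in enumerate(labels):
            ax.plot(self.t, self.x[i], label=lab)
        ax.set_xlabel("time")
        ax.set_ylabel("concentration")
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def simulate(net: Network, kinetics: Kinetics, x0, horizon: float,
             n_points: int = 1000, rtol: float = 1e-8,
             atol: float = 1e-10) -> Trajectory:
    """Integrate xdot = Gamma R(x) with a stiff-capable solver; states are
    projected to the nonnegative orthant (projection size is monitored) and
    conservation drift is reported."""
    x0 = np.asarray(x0, dtype=float)
    if (x0 < 0).any():
        raise ValueError("x0 must be nonnegative")
    sol = solve_ivp(kinetics.rhs, (0.0, float(horizon)), x0, method="LSODA",
                    rtol=rtol, atol=atol, dense_output=True)
    ts = np.linspace(0.0, float(horizon), n_points)
    X = sol.sol(ts)
    min_state = float(X.min(initial=0.0))
    X = np.maximum(X, 0.0)
    R = np.column_stack([kinetics(X[:, q]) for q in range(X.shape[1])])
    cons = conservation_analysis(net)
    drift = 0.0
    for d in cons.nonneg_laws:
        vals = _exact.as_float(d) @ X
        scale = max(1.0, float(np.abs(vals).max()))
        drift = max(drift, float(np.ptp(vals)) / scale)
    return Trajectory(ts, X, R, kinetics, sol.success, sol.message,
                      min_state, drift)


# ---------------------------------------------------------------------------
# steady states


@dataclass
class SteadyState:
    x: np.ndarray
    residual: float
    class_values: np.ndarray
    laws: list[np.ndarray]
    converged: bool


def steady_state(net: Network, kinetics: Kinetics, x0=None,
                 class_values=None, warm_horizon: float = 500.0,
                 tol: float = 1e-10) -> SteadyState:
    """Solve Gamma R(x) = 0 within a stoichiometric class.

    The class is fixed either by a starting point ``x0`` (whose conserved
    quantities define it; a simulation from x0 provides the warm start) or
    by explicit ``class_values`` for the nonnegative conservation laws.
    """
    cons = conservation_analysis(net)
    laws = [(_exact.as_float(d)) for d in cons.nonneg_laws]
    L = np.vstack(laws) if laws else np.zeros((0, net.n_species))
    if x0 is None and class_values is None:
        raise ValueError("provide x0 or class_values")
    if x0 is None:
        class_values = np.asarray(class_values, dtype=float)
        # a feasible point of the class for the warm start
        res = linprog(c=np.zeros(net.n_species), A_eq=L, b_eq=class_values,
                      bounds=[(0, None)] * net.n_species, method="highs")
        if not res.success:
            raise ValueError("empty stoichiometric class")
        x0 = res.x
    x0 = np.asarray(x0, dtype=float)
    if class_values is None:
        class_values = L @ x0 if L.size else np.zeros(0)
    traj = simulate(net, kinetics, x0, warm_horizon, n_points=50)
    xw = traj.x[:, -1]
    G = net.Gamma.astype(float)

    def fun(x):
        return np.concatenate([G @ kinetics(x), L @ x - class_values])

    sol = least_squares(fun, xw, bounds=(0.0, np.inf), xtol=3e-16,
                        ftol=3e-16, gtol=3e-16)
    resid = float(np.max(np.abs(G @ kinetics(sol.x))))
    return SteadyState(sol.x, resid, class_values, laws, resid <= tol)


# ---------------------------------------------------------------------------
# Lyapunov decrease along trajectories (Dini)


def dini_decrease_check(traj: Trajectory, rlf) -> float:
    """Maximal forward difference quotient of V(t) = V~(R(x(t))) over the
    trajectory grid (Dini-style decrease check for nonsmooth V). Values
    <= ~1e-6 * (1 + max V) are consistent with a decreasing certificate."""
    V = rlf.values(traj.r)
    dt = np.diff(traj.t)
    quot = np.diff(V) / np.where(dt > 0, dt, 1.0)
    return float(quot.max(initial=-np.inf))


def dini_threshold(traj: Trajectory, rlf, tol: float = 1e-6) -> float:
    V = rlf.values(traj.r)
    return tol * (1.0 + float(V.max(initial=0.0)))


# ---------------------------------------------------------------------------
# safety level sets


@dataclass
class SafetyLevel:
    alpha: float | None
    unbounded_safe: bool
    argmin: np.ndarray | None
    species: str
    bound: float


def safety_level(rlf, net: Network, kinetics: Kinetics, species: str,
                 bound: float, class_values, n_starts: int = 20,
                 seed: int = 0) -> SafetyLevel:
    """Largest certified sublevel set keeping ``species`` below ``bound``.

    alpha is the minimum of V(R(x)) over the slice of the stoichiometric
    class where x_species = bound; trajectories starting with V < alpha
    cannot reach the slice, hence never exceed the bound. Multi-start local
    minimization (alpha is an upper-bound certificate on the true minimum).
    """
    cons = conservation_analysis(net)
    laws = [(_exact.as_float(d)) for d in cons.nonneg_laws]
    L = np.vstack(laws) if laws else np.zeros((0, net.n_species))
    class_values = np.asarray(class_values, dtype=float)
    i_sp = net.species_index(species)
    n = net.n_species
    A_eq = np.vstack([L, np.eye(n)[i_sp:i_sp + 1]])
    b_eq = np.concatenate([class_values, [float(bound)]])
    probe = linprog(c=np.zeros(n), A_eq=A_eq, b_eq=b_eq,
                    bounds=[(0, None)] * n, method="highs")
    if not probe.success:
        return SafetyLevel(None, True, None, species, bound)
    rng = np.random.default_rng(seed)
    best, best_x = np.inf, None

    def obj(x):
        return rlf.value(kinetics(np.maximum(x, 0.0)))

    cons_spec = [{"type": "eq", "fun": lambda x, A=A_eq, b=b_eq: A @ x - b}]
    for s in range(n_starts):
        c = rng.standard_normal(n)
        start = linprog(c=c, A_eq=A_eq, b_eq=b_eq,
                        bounds=[(0, None)] * n, method="highs")
        x_start = start.x if start.success else probe.x
        res = minimize(obj, x_start, method="SLSQP", constraints=cons_spec,
                       bounds=[(0, None)] * n,
                       options={"maxiter": 200, "ftol": 1e-12})
        if res.fun < best:
            best, best_x = float(res.fun), res.x
    return SafetyLevel(best, False, best_x, species, bound)


# ---------------------------------------------------------------------------
# flux bounds


def soc_to_infnorm(xi, net: Network, cap: int = 2 ** 15) -> np.ndarray:
    """Convert a sum-of-currents certificate || diag(xi) Gamma r ||_1 to
    infinity-norm rows by enumerating sign vectors over the support of xi
    (one row per sign vector, up to global sign)."""
    xi_f = _exact.as_float(np.asarray(xi, dtype=object)) \
        if np.asarray(xi).dtype == object else np.asarray(xi, dtype=float)
    sup = np.nonzero(xi_f)[0]
    if 2 ** (len(sup) - 1) > cap:
        raise ValueError("sign enumeration exceeds the row cap")
    G = net.Gamma.astype(float)
    rows = []
    import itertools
    for signs in itertools.product((1.0, -1.0), repeat=len(sup) - 1):
        sigma = np.zeros(net.n_species)
        sigma[sup[0]] = 1.0
        for s, i in zip(signs, sup[1:]):
            sigma[i] = s
        rows.append((sigma * xi_f) @ G)
    return np.array(rows)


@dataclass
class FluxBound:
    optimum: float | None
    argmax: np.ndarray | None
    level: float
    unbounded: bool = False


def flux_bound(net: Network, C_inf: np.ndarray, r_init, objective: int,
               cap_index: int, cap_value: float) -> FluxBound:
    """Kinetics-free flux bound from an infinity-norm certificate:
    maximize r_objective subject to r >= 0, ||C r||_inf <= ||C r_init||_inf
    and r_cap <= cap_value."""
    C = np.asarray(C_inf, dtype=float)
    r_init = np.asarray(r_init, dtype=float)
    level = float(np.max(np.abs(C @ r_init))) if C.size else 0.0
    nu = net.n_reactions
    c = np.zeros(nu)
    c[objective] = -1.0
    A_ub = np.vstack([C, -C, np.eye(nu)[cap_index:cap_index + 1]])
    b_ub = np.concatenate([np.full(C.shape[0], level),
                           np.full(C.shape[0], level), [float(cap_value)]])
    res = linprog(c=c, A_ub=A_ub, b_ub=b_ub, bounds=[(0, None)] * nu,
                  method="highs")
    if res.status == 3:
        return FluxBound(None, None, level, unbounded=True)
    if not res.success:
        return FluxBound(None, None, level, unbounded=False)
    return FluxBound(float(-res.fun), res.x, level)


# ---------------------------------------------------------------------------
# multistability witness search


@dataclass
class BistabilityWitness:
    k: np.ndarray
    totals: dict
    x0_a: np.ndarray
    x0_b: np.ndarray
    limit_a: np.ndarray
    limit_b: np.ndarray
    residuals: tuple[float, float]

    @property
    def separation(self) -> float:
        return float(np.max(np.abs(self.limit_a - self.limit_b)))


def find_bistability(net: Network, substrate_species: list[str],
                     enzyme_species: list[str], seed: int = 0,
                     n_trials: int = 40, substrate_total: float = 100.0,
                     enzyme_total: float = 1.0, horizon: float = 5000.0,
                     separation: float = 5.0,
                     resid_tol: float = 1e-6) -> BistabilityWitness | None:
    """Random search for two distinct stable steady states in one
    stoichiometric class (mass-action constants log-uniform in [0.1, 10],
    substrate in large excess so the converting enzymes saturate).

    Trajectories start from the extreme substrate distributions (all mass in
    the first or the last substrate form); a trial is a witness when two
    limits are steady (residual below ``resid_tol``) and separated by more
    than ``separation`` in the max norm.
    """
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(net.species)}
    G = net.Gamma.astype(float)
    sub = [idx[s] for s in substrate_species]
    enz = [idx[s] for s in enzyme_species]
    for _ in range(n_trials):
        k = 10 ** rng.uniform(-1, 1, net.n_reactions)
        K = Kinetics(net, [RateLaw("mass_action", k=float(kj)) for kj in k])
        limits = []
        starts = []
        for target in (sub[0], sub[-1]):
            x0 = np.zeros(net.n_species)
            x0[target] = substrate_total
            for e in enz:
                x0[e] = enzyme_total
            traj = simulate(net, K, x0, horizon, n_points=50,
                            rtol=1e-8, atol=1e-10)
            xf = traj.x[:, -1]
            limits.append(xf)
            starts.append(x0)
        r = [float(np.max(np.abs(G @ K(xf)))) for xf in limits]
        sep = float(np.max(np.abs(limits[0] - limits[1])))
        if max(r) < resid_tol and sep > separation:
            return BistabilityWitness(k, {"substrate": substrate_total,
                                          "enzyme": enzyme_total},
                                      starts[0], starts[1],
                                      limits[0], limits[1], (r[0], r[1]))
    return None


# ---------------------------------------------------------------------------
# converting flux bounds to concentration bounds


def invert_rate_law(law, bound: float):
    """Translate a flux bound into a concentration bound by inverting a
    monotone single-substrate rate law.

    ``law`` is a RateLaw ("mass_action": R = k c, "michaelis_menten" with
    R = a c / (1 + b c) given as k=a, K carrying b under key "b") or a pair
    (f, bracket) for generic monotone laws (bisection). Returns the
    concentration bound, or None when the bound exceeds the law's range
    ("unreachable").
    """
    if isinstance(law, RateLaw):
        if law.kind == "mass_action":
            return bound / law.k
        if law.kind == "michaelis_menten":
            a = law.k
            b = law.K.get("b", 1.0)
            sup = a / b
            if bound >= sup:
                return None
            return bound / (a - b * bound)
        raise ValueError(f"no closed-form inverse for {law.kind!r}")
    f, bracket = law
    lo, hi = bracket
    if f(hi) < bound or f(lo) > bound:
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < bound:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
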
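"""Necessary conditions and structural properties of attractive networks.

A network admitting a piecewise linear-in-rates RLF has a negative Jacobian
that is P0 (all principal minors nonnegative) for every admissible kinetics,
and — under mild side conditions — cannot have a critical siphon. These
tests cheaply *rule out* certificates. Robust non-degeneracy of the reduced
Jacobian (checked at unit pair weights) upgrades a certificate to
uniqueness/exponential stability of positive steady states, and rate-space
certificates convert to concentration-space ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from . import _exact
from .core import Network, extremals, conservation_analysis, m_decomposition


# ---------------------------------------------------------------------------
# Jacobians in rate and concentration coordinates


def jacobian_at(net: Network, rho) -> tuple[np.ndarray, np.ndarray]:
    """Rate-space and species-space Jacobians at pair weights rho >= 0.

    rho assigns a weight to each reaction-reactant pair (column-major order
    of :meth:`Network.reactant_pairs`); rho_l plays the role of the partial
    derivative dR_j/dx_i. Returns (J_r, J_x) with J_r = sum rho_l Q_l
    (nu x nu) and J_x = Gamma M(rho) (n x n), M(rho)_{j,i} = rho_l.
    """
    ex = extremals(net)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (ex.s,):
        raise ValueError(f"rho must have length {ex.s}")
    if (rho < 0).any():
        raise ValueError("rho must be nonnegative")
    nu, n = net.n_reactions, net.n_species
    M = np.zeros((nu, n))
    for rl, (j, i) in zip(rho, ex.pairs):
        M[j, i] = rl
    G = net.Gamma.astype(float)
    J_r = sum(rl * Q.astype(float) for rl, Q in zip(rho, ex.Qs))
    if isinstance(J_r, int):
        J_r = np.zeros((nu, nu))
    J_x = G @ M
    return J_r, J_x


# ---------------------------------------------------------------------------
# P0 property of the negative Jacobian


@dataclass
class P0Report:
    verdict: str                      # "pass" | "fail" | "undetermined"
    witnesses: list = field(default_factory=list)
    # each witness: (species index tuple, rho vector, minor value)
    negative_monomials: list = field(default_factory=list)
    note: str = ""

    @property
    def witness(self):
        return self.witnesses[0] if self.witnesses else None


def check_p0(net: Network, size_cap: int = 12) -> P0Report:
    """Is -J_x(rho) a P0 matrix for all rho >= 0?

    Each principal minor of -Gamma M(rho) is a polynomial in rho whose
    monomials correspond to partial matchings of the reaction-reactant
    bipartite graph: for a matching L with reaction set T and species set S,
    the coefficient of prod_{l in L} rho_l in the minor on S is
    (-1)^{|S|} det(Gamma[S, T]) sgn(pi_L). All-nonnegative coefficients
    certify P0 ("pass"); a negative coefficient is turned into a numeric
    witness by putting unit weight on the matching and epsilon elsewhere
    ("fail"), and "undetermined" is returned when suspicion cannot be
    confirmed or the size cap is exceeded.
    """
    ex = extremals(net)
    n = net.n_species
    if n > size_cap:
        return P0Report("undetermined", note=f"n={n} exceeds cap {size_cap}")
    pairs = ex.pairs
    G = net.Gamma

    negatives = []

    # enumerate partial matchings by recursion over pairs
    def rec(start: int, used_j: set, used_i: set, edges: list):
        if edges:
            T = sorted(j for j, _ in edges)
            S = sorted(i for _, i in edges)
            perm = []
            for j in T:
                i = next(ii for jj, ii in edges if jj == j)
                perm.append(S.index(i))
            sgn = 1
            seen = [False] * len(perm)
            for a in range(len(perm)):
                if seen[a]:
                    continue
                ln = 0
                b = a
                while not seen[b]:
                    seen[b] = True
                    b = perm[b]
                    ln += 1
                if ln % 2 == 0:
                    sgn = -sgn
            sub = G[np.ix_(S, T)]
            coeff = ((-1) ** len(S)) * _exact.int_det(sub) * sgn
            if coeff < 0:
                negatives.append((tuple(edges), tuple(S), coeff))
        if len(edges) >= min(n, net.n_reactions):
            return
        for idx in range(start, len(pairs)):
            j, i = pairs[idx]
            if j in used_j or i in used_i:
                continue
            rec(idx + 1, used_j | {j}, used_i | {i}, edges + [(j, i)])

    rec(0, set(), set(), [])

    if not negatives:
        return P0Report("pass")

    witnesses = []
    pair_index = {pr: l for l, pr in enumerate(pairs)}
    for edges, S, coeff in negatives:
        rho = np.full(ex.s, 1e-6)
        for e in edges:
            rho[pair_index[e]] = 1.0
        _, J_x = jacobian_at(net, rho)
        sub = (-J_x)[np.ix_(S, S)]
        val = float(np.linalg.det(sub))
        if val < -1e-9:
            witnesses.append((S, rho, val))
    if witnesses:
        return P0Report("fail", witnesses=witnesses,
                        negative_monomials=negatives)
    # targeted construction failed; random search as backstop
    rng = np.random.default_rng(0)
    for edges, S, coeff in negatives:
        for _ in range(1000):
            rho = rng.exponential(1.0, size=ex.s)
            _, J_x = jacobian_at(net, rho)
            val = float(np.linalg.det((-J_x)[np.ix_(S, S)]))
            if val < -1e-9:
                witnesses.append((S, rho, val))
                break
    if witnesses:
        return P0Report("fail", witnesses=witnesses,
                        negative_monomials=negatives)
    return P0Report("undetermined", negative_monomials=negatives,
                    note="negative minor coefficients found but no numeric "
                         "witness")


# ---------------------------------------------------------------------------
# robust non-degeneracy


@dataclass
class NondegeneracyReport:
    nondegenerate: bool
    det: Fraction | None
    vacuous: bool = False


def check_robust_nondegeneracy(net: Network) -> NondegeneracyReport:
    """Non-singularity of the reduced Jacobian at unit pair weights.

    The species-space Jacobian at rho = 1 is restricted to Im Gamma via an
    exact-rational basis S: M = (S^T S)^{-1} S^T J_x S. For networks with a
    PWL RLF, non-singularity at this single point implies non-singularity
    for all admissible kinetics at all interior points.
    """
    S_basis = _exact.column_space(net.Gamma)
    if not S_basis:
        return NondegeneracyReport(True, None, vacuous=True)
    import sympy as sp
    S = sp.Matrix([list(map(sp.Rational, b)) for b in S_basis]).T
    M1 = sp.zeros(net.n_reactions, net.n_species)
    for (j, i) in net.reactant_pairs():
        M1[j, i] = 1
    G = sp.Matrix(net.Gamma.tolist())
    J = G * M1
    red = (S.T * S).inv() * S.T * J * S
    d = red.det()
    frac = Fraction(int(d.p), int(d.q))
    return NondegeneracyReport(abs(frac) > Fraction(1, 10**9), frac)


# ---------------------------------------------------------------------------
# siphons


@dataclass
class SiphonReport:
    minimal_siphons: list[tuple[int, ...]]
    critical: list[tuple[int, ...]]       # subset of minimal_siphons
    trivial: list[tuple[int, ...]]
    preclusion: str | None                # "a" | "b" | "c" | None
    preclusion_detail: str = ""
    complete: bool = True

    def siphon_species(self, net: Network):
        return [tuple(net.species[i] for i in P) for P in self.minimal_siphons]


def _is_siphon(mask: int, produced_by: list[int], reactant_masks: list[int],
               nu: int) -> bool:
    # P is a siphon iff every reaction producing a member has a reactant in P
    for j in range(nu):
        if produced_by[j] & mask and not (reactant_masks[j] & mask):
            return False
    return True


def minimal_siphons(net: Network, cap: int = 20) -> tuple[list[tuple[int, ...]], bool]:
    """Brute-force enumeration of minimal siphons over the subset lattice
    (popcount-increasing, with superset pruning); capped at ``cap`` species."""
    n = net.n_species
    if n > cap:
        return [], False
    nu = net.n_reactions
    produced_by = [int(sum(1 << i for i in range(n) if net.B[i, j] > 0))
                   for j in range(nu)]
    reactant_masks = [int(sum(1 << i for i in range(n) if net.A[i, j] > 0))
                      for j in range(nu)]
    found: list[int] = []
    by_size: dict[int, list[int]] = {}
    for mask in range(1, 1 << n):
        by_size.setdefault(bin(mask).count("1"), []).append(mask)
    for size in sorted(by_size):
        for mask in by_size[size]:
            if any((mask & f) == f for f in found):
                continue
            if _is_siphon(mask, produced_by, reactant_masks, nu):
                found.append(mask)
    out = [tuple(i for i in range(n) if m >> i & 1) for m in found]
    return out, True


def siphon_analysis(net: Network, cap: int = 20) -> SiphonReport:
    """Enumerate minimal siphons, classify them as trivial (containing the
    support of a nonnegative conservation law) or critical, and evaluate the
    certificate-preclusion clauses: (a) a critical deadlock (every reaction
    has a reactant in the siphon), (b) conservative M-network, (c)
    conservative with robustly non-degenerate reduced Jacobian at unit
    weights. The clauses apply only under AS1."""
    sips, complete = minimal_siphons(net, cap)
    G = net.Gamma.astype(float)
    n, nu = G.shape
    trivial, critical = [], []
    for P in sips:
        # exists d >= 0, d != 0, d^T Gamma = 0, supp(d) subset of P?
        idx = list(P)
        if idx:
            A_eq = np.vstack([G[idx, :].T, np.ones((1, len(idx)))])
            b_eq = np.concatenate([np.zeros(nu), [1.0]])
            res = linprog(c=np.zeros(len(idx)), A_eq=A_eq, b_eq=b_eq,
                          bounds=[(0, None)] * len(idx), method="highs")
            (trivial if res.success else critical).append(P)
    preclusion = None
    detail = ""
    if critical:
        cons = conservation_analysis(net)
        if not cons.as1:
            detail = "critical siphon present but AS1 fails; preclusion " \
                     "clauses not applicable"
        else:
            for P in critical:
                lam = {j for j in range(nu)
                       if any(net.A[i, j] > 0 for i in P)}
                if lam == set(range(nu)):
                    preclusion = "a"
                    detail = f"critical deadlock {tuple(net.species[i] for i in P)}"
                    break
            if preclusion is None and cons.is_conservative:
                if m_decomposition(net) is not None:
                    preclusion = "b"
                    detail = "conservative M-network with a critical siphon"
                elif check_robust_nondegeneracy(net).nondegenerate:
                    preclusion = "c"
                    detail = ("conservative, robustly non-degenerate at unit "
                              "weights, with a critical siphon")
    return SiphonReport(sips, critical, trivial, preclusion, detail, complete)


# ---------------------------------------------------------------------------
# rate- to concentration-coordinates conversion


@dataclass
class ConcentrationRLF:
    """Concentration-space PWL RLF (B, G) with C = B Gamma, H = G Gamma; the
    function V(x) = Vhat(x - x_e) decreases within the stoichiometric class
    of the steady state x_e. D spans ker Gamma^T: adding rows of Y D^T to B
    leaves the function unchanged on the class (the solution is least-norm,
    not unique)."""
    B: np.ndarray
    G: np.ndarray | None
    D: np.ndarray
    form: str = "abs"

    def value(self, z) -> float:
        z = np.asarray(z, dtype=float)
        vals = np.abs(_exact.as_float(self.B) @ z)
        return float(vals.max())


def rate_to_concentration(cand, net: Network) -> ConcentrationRLF:
    """Solve C = B Gamma (and H = G Gamma) row-wise by least-norm least
    squares, then snap to exact rationals when possible and round-trip check.
    Consistent whenever ker C contains ker Gamma (true for verified
    candidates)."""
    Gm = net.Gamma.astype(float)
    C = _exact.as_float(cand.C)
    Bt, *_ = np.linalg.lstsq(Gm.T, C.T, rcond=None)
    B = Bt.T
    resid = np.max(np.abs(B @ Gm - C))
    if resid > 1e-7 * (1 + np.abs(C).max()):
        raise ValueError("inconsistent conversion: C not in the row space "
                         "of Gamma (candidate not verified?)")
    # exact snap: rows of B modulo ker Gamma^T; try rationalization
    Bex = np.empty(B.shape, dtype=object)
    ok = True
    for r in range(B.shape[0]):
        row = np.array([Fraction(x).limit_denominator(10**6) for x in B[r]],
                       dtype=object)
        if np.max(np.abs(_exact.as_float(row) - B[r])) < 1e-9 and \
           np.max(np.abs(_exact.as_float(row @ net.Gamma.astype(object))
                         - C[r])) < 1e-9:
            Bex[r] = row
        else:
            ok = False
            break
    Bout = Bex if ok else B
    Gout = None
    part = getattr(cand, "partition", None)
    if part is not None:
        Hf = _exact.as_float(part.H)
        Gt, *_ = np.linalg.lstsq(Gm.T, Hf.T, rcond=None)
        Gout = Gt.T
    D = np.array([list(map(float, d)) for d in _exact.left_nullspace(net.Gamma)])
    if D.size == 0:
        D = np.zeros((0, net.n_species))
    form = getattr(cand, "form", "abs")
    return ConcentrationRLF(Bout, Gout, D, form)
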
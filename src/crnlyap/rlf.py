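"""Construction and verification of Robust Lyapunov Functions (RLFs).

An RLF is a function V~ of the reaction-rate vector r = R(x) that decreases
along trajectories of xdot = Gamma R(x) for *every* admissible monotone
kinetics and vanishes exactly on ker Gamma. By the extremal decomposition
(see :mod:`crnlyap.core`), this is equivalent to V~ being a common Lyapunov
function for the rank-one linear systems rdot = Q_l r.

Four constructions are implemented:

* a joint linear program over a conic partition of rate space
  (piecewise linear-in-rates candidates, with the sum-of-currents form
  V = || diag(xi) xdot ||_1 as a special case),
* a light-weight iterative row-growing algorithm for convex PWL candidates,
* a purely graphical max-min criterion for "M-networks"
  (V = max R - min R over forward-minus-backward rate differences),
* a semidefinite (copositive-relaxation) feasibility problem for piecewise
  quadratic-in-rates candidates (:mod:`crnlyap._sdp`).

Every candidate can be re-verified independently by region-wise linear
programs (:func:`verify_pwl`) and by randomized decrease sampling
(:func:`sampled_decrease_check`).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.sparse as sps
from scipy.optimize import linprog

from . import _exact
from .core import (Network, MDecomposition, extremals,
                   conservation_analysis, m_decomposition)

LP_TOL = 1e-8


# ---------------------------------------------------------------------------
# conic partitions of rate space


@dataclass
class Partition:
    """Conic partition of rate space by sign patterns of H r, ker H = ker Gamma.

    ``signatures`` holds one representative per +/- pair of full-dimensional
    regions W_k = {r : Sigma_k H r >= 0} (the negation -Sigma_k is implied).
    """
    H: np.ndarray                      # p x nu
    signatures: list[np.ndarray]       # each length p, entries +/-1

    @property
    def p(self) -> int:
        return self.H.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.signatures)

    def region_matrix(self, k: int) -> np.ndarray:
        """Inequality rows g of W_k = {r : g r >= 0}."""
        return self.signatures[k][:, None] * _exact.as_float(self.H)

    def containing_regions(self, r: np.ndarray, tol: float = 1e-9):
        """Indices (k, sign) of all regions containing r (within tol)."""
        y = _exact.as_float(self.H) @ np.asarray(r, dtype=float)
        scale = tol * (1.0 + np.abs(y).max(initial=0.0))
        out = []
        for k, sig in enumerate(self.signatures):
            if np.all(sig * y >= -scale):
                out.append((k, 1))
            if np.all(-sig * y >= -scale):
                out.append((k, -1))
        return out

    def locate(self, r: np.ndarray) -> tuple[int, int]:
        """First region containing r; nearest region if r is slightly outside
        all of them (numerical round-off)."""
        hits = self.containing_regions(r)
        if hits:
            return hits[0]
        y = _exact.as_float(self.H) @ np.asarray(r, dtype=float)
        best = (0, 1)
        best_viol = np.inf
        for k, sig in enumerate(self.signatures):
            for s in (1, -1):
                viol = float(np.maximum(-(s * sig) * y, 0.0).sum())
                if viol < best_viol:
                    best, best_viol = (k, s), viol
        return best


def _strictly_feasible(rows: np.ndarray, eps: float) -> bool:
    """Is {r : rows @ r >= eps, |r|_inf <= 1} nonempty?"""
    if rows.shape[0] == 0:
        return True
    nu = rows.shape[1]
    res = linprog(c=np.zeros(nu), A_ub=-rows, b_ub=-eps * np.ones(rows.shape[0]),
                  bounds=[(-1, 1)] * nu, method="highs")
    return bool(res.success)


def build_partition(net: Network, extra_rows=None, H=None,
                    eps: float = 1e-6, max_p: int = 20) -> Partition:
    """Build the conic partition of rate space induced by H (default Gamma).

    ``extra_rows`` are appended to Gamma and must lie in its row space (so
    ker H = ker Gamma is preserved); rows gamma_i +/- gamma_j are the usual
    refinement. Signatures are enumerated depth-first with strict-feasibility
    pruning; only regions with nonempty interior are kept, one per +/- pair
    (the first sign is pinned to +1, the negated twin being implied).
    """
    G = net.Gamma
    if H is None:
        H = G.astype(int)
        if extra_rows is not None:
            extra = np.atleast_2d(np.asarray(extra_rows))
            for row in extra:
                if not _exact.in_row_space(row, G):
                    raise ValueError("extra partition row outside the row "
                                     "space of Gamma (would change ker H)")
            H = np.vstack([H, extra.astype(H.dtype)])
    else:
        H = np.asarray(H)
        stacked = np.vstack([_exact.as_float(H), G.astype(float)])
        if _exact.rank(H) != _exact.rank(G) or _exact.rank(stacked) != _exact.rank(G):
            raise ValueError("ker H must equal ker Gamma")
    p = H.shape[0]
    if p > max_p:
        raise ValueError(f"partition has {p} rows > cap {max_p}; use a "
                         "smaller H or a non-enumerative method")
    Hf = _exact.as_float(H)
    signatures: list[np.ndarray] = []

    def recurse(prefix: list[int]):
        rows = np.array(prefix, dtype=float)[:, None] * Hf[:len(prefix)]
        if not _strictly_feasible(rows, eps):
            return
        if len(prefix) == p:
            signatures.append(np.array(prefix, dtype=int))
            return
        recurse(prefix + [1])
        recurse(prefix + [-1])

    recurse([1])
    return Partition(H, signatures)


# ---------------------------------------------------------------------------
# candidates


@dataclass
class PWLCandidate:
    """Piecewise linear-in-rates Lyapunov candidate.

    Two forms:

    * ``"abs"``: V(r) = |c_k^T r| on +/- W_k over a signature partition
      (rows of C indexed like ``partition.signatures``);
    * ``"max"``: V(r) = max(0, max_k c_k^T r), convex, the zero row implicit
      (iterative-algorithm and max-min certificates).
    """
    C: np.ndarray
    form: str = "abs"
    partition: Partition | None = None
    xi: np.ndarray | None = None          # species weights for SoC candidates
    convex: bool = False
    kernel_ok: bool | None = None
    label: str = ""

    @property
    def Cf(self) -> np.ndarray:
        return _exact.as_float(self.C)

    def value(self, r) -> float:
        r = np.asarray(r, dtype=float)
        if self.form == "max":
            vals = self.Cf @ r
            return float(max(0.0, vals.max())) if vals.size else 0.0
        k, _ = self.partition.locate(r)
        return abs(float(self.Cf[k] @ r))

    def values(self, R) -> np.ndarray:
        """Evaluate on each column of R."""
        R = np.atleast_2d(np.asarray(R, dtype=float))
        if self.form == "max":
            vals = self.Cf @ R
            return np.maximum(vals.max(axis=0), 0.0)
        return np.array([self.value(R[:, t]) for t in range(R.shape[1])])

    def pieces(self):
        """(c_k, G_k) pairs with V = c_k^T r on {G_k r >= 0}, for the
        verification LPs."""
        C = self.Cf
        out = []
        if self.form == "abs":
            for k in range(C.shape[0]):
                out.append((C[k], self.partition.region_matrix(k)))
        else:
            m = C.shape[0]
            for k in range(m):
                rows = [C[k] - C[j] for j in range(m) if j != k]
                rows.append(C[k])          # dominates the implicit zero row
                out.append((C[k], np.array(rows)))
        return out

    def to_text(self) -> str:
        """Structured-text serialization (for archival and re-verification)."""
        lines = [f"# PWL certificate ({self.form}"
                 + (", convex" if self.convex else "") + ")",
                 "C ="]
        for row in np.asarray(self.C):
            lines.append("  " + " ".join(str(v) for v in row))
        if self.xi is not None:
            lines.append("xi = " + " ".join(str(v) for v in self.xi))
        if self.partition is not None:
            lines.append("H =")
            for row in np.asarray(self.partition.H):
                lines.append("  " + " ".join(str(v) for v in row))
            lines.append("signatures =")
            for sig in self.partition.signatures:
                lines.append("  " + " ".join("+" if s > 0 else "-"
                                             for s in sig))
        return "\n".join(lines)

    def directional_derivative(self, r, v, tol: float = 1e-9) -> float:
        """Upper Dini derivative of V at r along v."""
        r = np.asarray(r, dtype=float)
        v = np.asarray(v, dtype=float)
        C = self.Cf
        if self.form == "max":
            vals = np.concatenate([[0.0], C @ r])
            grads = np.vstack([np.zeros(len(r)), C])
            Vr = vals.max()
            active = np.abs(vals - Vr) <= tol * (1.0 + abs(Vr))
            return float((grads[active] @ v).max())
        best = -np.inf
        for k, _ in self.partition.containing_regions(r, tol):
            val = float(C[k] @ r)
            if abs(val) <= tol * (1.0 + np.abs(r).max(initial=0.0)):
                d = abs(float(C[k] @ v))
            else:
                d = float(np.sign(val) * (C[k] @ v))
            best = max(best, d)
        if best == -np.inf:   # r numerically outside all regions
            k, _ = self.partition.locate(r)
            val = float(C[k] @ r)
            best = abs(float(C[k] @ v)) if abs(val) <= tol else \
                float(np.sign(val) * (C[k] @ v))
        return best


@dataclass
class MaxMinRLF:
    """Max-min certificate V(r) = max_q a_q^T r - min_q a_q^T r over the
    normalized forward-minus-backward rate differences of an oriented
    M-network (with the constant 0 term for zero-flux decompositions)."""
    decomposition: MDecomposition
    terms: np.ndarray                  # q x nu coefficient rows a_q
    labels: list[str]
    include_zero: bool = False

    def _vals(self, R):
        vals = _exact.as_float(self.terms) @ np.asarray(R, dtype=float)
        if self.include_zero:
            pad = np.zeros(vals.shape[1:]) if vals.ndim > 1 else 0.0
            vals = np.vstack([vals, np.atleast_1d(pad)]) if vals.ndim > 1 \
                else np.concatenate([vals, [0.0]])
        return vals

    def value(self, r) -> float:
        vals = self._vals(np.asarray(r, dtype=float))
        return float(vals.max() - vals.min())

    def values(self, R) -> np.ndarray:
        vals = self._vals(np.atleast_2d(np.asarray(R, dtype=float)))
        return vals.max(axis=0) - vals.min(axis=0)

    def to_text(self) -> str:
        lines = ["# max-min certificate",
                 "R = {" + ", ".join(self.labels) + "}",
                 "w = " + (" ".join(str(x) for x in self.decomposition.w)
                           if self.decomposition.w is not None else "1 (zero-flux)")]
        return "\n".join(lines)

    def to_pwl(self) -> PWLCandidate:
        """Equivalent convex max-form candidate with rows a_q - a_p."""
        T = _exact.as_float(self.terms)
        if self.include_zero:
            T = np.vstack([T, np.zeros(T.shape[1])])
        rows = [T[q] - T[p]
                for q in range(T.shape[0]) for p in range(T.shape[0]) if q != p]
        return PWLCandidate(np.array(rows), form="max", convex=True,
                            label="max-min")

    def directional_derivative(self, r, v, tol: float = 1e-9) -> float:
        return self.to_pwl().directional_derivative(r, v, tol)


# ---------------------------------------------------------------------------
# verification


@dataclass
class Verification:
    passed: bool
    reason: str = ""
    witness: tuple | None = None       # (piece index, extremal index, r)
    max_violation: float = 0.0


def _kernel_rank_ok(C, net: Network) -> bool:
    Cf = _exact.as_float(C)
    for v in _exact.nullspace(net.Gamma):
        if np.max(np.abs(Cf @ _exact.as_float(v))) > 1e-9 * (1 + np.abs(Cf).max()):
            return False
    return np.linalg.matrix_rank(Cf, tol=1e-9) == _exact.rank(net.Gamma)


def _max_form_vanishing_ok(C, net: Network) -> bool:
    """For V = max(0, C r): check {r : C r <= 0} = ker Gamma by LP."""
    Cf = _exact.as_float(C)
    for v in _exact.nullspace(net.Gamma):
        if np.max(np.abs(Cf @ _exact.as_float(v))) > 1e-9 * (1 + np.abs(Cf).max()):
            return False
    U = [_exact.as_float(u) for u in _exact.column_space(net.Gamma.T)]
    if not U:
        return True
    U = np.column_stack(U)
    d = U.shape[1]
    # the cone {w : C U w <= 0} in the complement of ker Gamma must be {0}
    for q in range(d):
        for s in (1.0, -1.0):
            A_eq = np.zeros((1, d))
            A_eq[0, q] = 1.0
            res = linprog(c=np.zeros(d), A_ub=Cf @ U, b_ub=np.zeros(Cf.shape[0]),
                          A_eq=A_eq, b_eq=[s], bounds=[(-1, 1)] * d,
                          method="highs")
            if res.success:
                return False
    return True


def _facet_discontinuity(cand: PWLCandidate, tol: float = 1e-7):
    """For partition-form candidates: |c_k r| and |c_j r| must agree on every
    shared facet, i.e. c_k -/+ sign*c_j must be a multiple of the differing
    row h_s. Returns an offending region pair, or None."""
    part = cand.partition
    Cf = cand.Cf
    Hf = _exact.as_float(part.H)
    scale = 1.0 + float(np.abs(Cf).max())
    for (k, j, s, sign) in neighbor_pairs(part):
        h = Hf[s]
        hn = h / float(h @ h)
        ok = False
        for pairing in (1.0, -1.0):
            d = Cf[k] - pairing * sign * Cf[j]
            if np.max(np.abs(d - float(d @ hn) * h)) <= tol * scale:
                ok = True
                break
        if not ok:
            return (k, j)
    return None


def verify_pwl(net: Network, cand, tol: float = LP_TOL) -> Verification:
    """Region-wise LP verification that a PWL candidate is an RLF.

    For every piece (c_k on {G_k r >= 0}) and every extremal Q_l, solve
    max c_k^T Q_l r subject to the region and |r|_inf <= 1; pass iff every
    optimum is <= tol and the zero set of V equals ker Gamma.
    """
    if isinstance(cand, MaxMinRLF):
        cand = cand.to_pwl()
    ex = extremals(net)
    if cand.form == "abs":
        if not _kernel_rank_ok(cand.C, net):
            return Verification(False, "kernel mismatch: ker C != ker Gamma")
        bad = _facet_discontinuity(cand)
        if bad is not None:
            return Verification(False, f"discontinuous across facet of "
                                       f"regions {bad}")
    else:
        if not _max_form_vanishing_ok(cand.C, net):
            return Verification(False, "kernel mismatch: zero set of V "
                                       "differs from ker Gamma")
    worst = 0.0
    for k, (c, Grows) in enumerate(cand.pieces()):
        nu = len(c)
        for l, Q in enumerate(ex.Qs):
            obj = -(c @ Q)               # linprog minimizes
            if not np.any(obj):
                continue
            res = linprog(c=obj, A_ub=-Grows, b_ub=np.zeros(Grows.shape[0]),
                          bounds=[(-1, 1)] * nu, method="highs")
            if not res.success:
                continue
            opt = -res.fun
            worst = max(worst, opt)
            if opt > tol:
                return Verification(False, "decrease violated",
                                    witness=(k, l, res.x), max_violation=opt)
    return Verification(True, max_violation=worst)


def sampled_decrease_check(net: Network, cand, n_samples: int = 10_000,
                           seed: int = 0) -> float:
    """Randomized decrease oracle, independent of the LP route: sample
    rho >= 0 supported on the reactant pairs and random r, and return the
    largest normalized directional derivative of V along rdot = sum rho_l
    Q_l r. For an RLF this is <= 0 up to round-off."""
    rng = np.random.default_rng(seed)
    ex = extremals(net)
    nu = net.n_reactions
    worst = -np.inf
    Qstack = np.stack([Q.astype(float) for Q in ex.Qs])
    for _ in range(n_samples):
        rho = rng.exponential(1.0, size=ex.s)
        r = rng.standard_normal(nu)
        v = np.einsum("l,lab,b->a", rho, Qstack, r)
        d = cand.directional_derivative(r, v) / (1.0 + float(np.linalg.norm(r)))
        worst = max(worst, d)
    return worst


# ---------------------------------------------------------------------------
# construction: joint linear program over a partition


@dataclass
class LPCertificate:
    """Farkas multipliers for a partition-form PWL RLF: per region k,
    xi_k >= 0 with c_k^T = xi_k^T Sigma_k H, and per (region k, extremal l)
    lambda_kl with c_k^T Q_l = -lambda_kl^T H and Sigma_k lambda_kl >= 0."""
    xi: list[np.ndarray]
    lam: dict[tuple[int, int], np.ndarray]
    residual: float
    as1_fallback: bool = False


def neighbor_pairs(part: Partition, eps: float = 1e-7):
    """Region pairs (k, j, differing row s, relative sign) whose signatures
    differ at exactly one index and whose shared facet has relative
    interior."""
    Hf = _exact.as_float(part.H)
    p, nu = Hf.shape
    out = []
    sigs = part.signatures
    for k in range(len(sigs)):
        for j in range(k + 1, len(sigs)):
            for sign_j, sj in ((1, sigs[j]), (-1, -sigs[j])):
                diff = np.nonzero(sigs[k] != sj)[0]
                if len(diff) != 1:
                    continue
                s = int(diff[0])
                others = [q for q in range(p) if q != s]
                strict = sigs[k][others, None] * Hf[others] if others else \
                    np.zeros((0, nu))
                res = linprog(c=np.zeros(nu), A_ub=-strict,
                              b_ub=-eps * np.ones(strict.shape[0]),
                              A_eq=Hf[s:s + 1], b_eq=[0.0],
                              bounds=[(-1, 1)] * nu, method="highs")
                if res.success:
                    out.append((k, j, s, sign_j))
                break
    return out


def construct_pwl_lp(net: Network, part: Partition | None = None,
                     force_convex: bool = False, tol: float = 1e-9):
    """Joint LP for a piecewise linear-in-rates RLF over a conic partition.

    Variables: region coefficients c_k, positivity multipliers xi_k >= 0
    (normalized 1^T xi_k = 1, the LP-representable form of strict
    positivity) and decrease multipliers lambda_kl. Infeasibility rules out
    a PWL RLF over *this* partition only. When no strictly positive
    steady-state flux exists (AS1 fails) the same region LP is solved with
    facet-continuity constraints added and the result labeled
    "AS1-fallback"; such candidates are always re-checked by sampling.

    Returns (PWLCandidate, LPCertificate), or None if infeasible.
    """
    if part is None:
        part = build_partition(net)
    ex = extremals(net)
    cons = conservation_analysis(net)
    fallback = not cons.as1
    H = _exact.as_float(part.H)
    p, nu = H.shape
    K = part.n_regions
    s_ex = ex.s

    n_c, n_xi, n_lam = K * nu, K * p, K * s_ex * p

    def c_off(k):
        return k * nu

    def xi_off(k):
        return n_c + k * p

    def lam_off(k, l):
        return n_c + n_xi + (k * s_ex + l) * p

    n_var = n_c + n_xi + n_lam
    rows_eq, cols_eq, vals_eq, b_eq = [], [], [], []

    def add_eq(entries, rhs=0.0):
        i = len(b_eq)
        for col, val in entries:
            rows_eq.append(i)
            cols_eq.append(col)
            vals_eq.append(val)
        b_eq.append(rhs)

    for k in range(K):
        SkH = part.signatures[k][:, None] * H
        for a in range(nu):
            entries = [(c_off(k) + a, 1.0)]
            entries += [(xi_off(k) + q, -SkH[q, a]) for q in range(p)
                        if SkH[q, a] != 0.0]
            add_eq(entries)
        add_eq([(xi_off(k) + q, 1.0) for q in range(p)], rhs=1.0)
        for l, Q in enumerate(ex.Qs):
            Qf = Q.astype(float)
            for a in range(nu):
                entries = [(c_off(k) + b, Qf[b, a])
                           for b in range(nu) if Qf[b, a] != 0.0]
                entries += [(lam_off(k, l) + q, H[q, a]) for q in range(p)
                            if H[q, a] != 0.0]
                add_eq(entries)

    bounds = [(None, None)] * n_c + [(0.0, None)] * n_xi
    for k in range(K):
        sig = part.signatures[k]
        for l in range(s_ex):
            bounds += [((0.0, None) if sig[q] > 0 else (None, 0.0))
                       for q in range(p)]

    # facet continuity c_k - sign * c_j = eta * h_s across every neighboring
    # pair: without it the region-wise LP admits solutions whose pieces do
    # not agree on shared facets, i.e. V is not a (Lipschitz) function
    extra_vars = 0
    for (k, j, srow, sign) in neighbor_pairs(part):
        eta_col = n_var + extra_vars
        extra_vars += 1
        for a in range(nu):
            entries = [(c_off(k) + a, 1.0), (c_off(j) + a, -float(sign))]
            if H[srow, a] != 0.0:
                entries.append((eta_col, -H[srow, a]))
            add_eq(entries)
    bounds += [(None, None)] * extra_vars

    if force_convex:
        # c_k dominates +/- c_j on W_k: c_k -/+ c_j = (Sigma_k H)^T mu, mu >= 0
        for k in range(K):
            SkH = part.signatures[k][:, None] * H
            for j in range(K):
                if j == k:
                    continue
                for sgn in (1.0, -1.0):
                    mu0 = n_var + extra_vars
                    extra_vars += p
                    for a in range(nu):
                        entries = [(c_off(k) + a, 1.0), (c_off(j) + a, -sgn)]
                        entries += [(mu0 + q, -SkH[q, a]) for q in range(p)
                                    if SkH[q, a] != 0.0]
                        add_eq(entries)
                    bounds += [(0.0, None)] * p

    n_total = n_var + extra_vars
    A_eq = sps.coo_matrix((vals_eq, (rows_eq, cols_eq)),
                          shape=(len(b_eq), n_total)).tocsr()
    res = linprog(c=np.zeros(n_total), A_eq=A_eq, b_eq=np.array(b_eq),
                  bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": tol})
    if not res.success:
        return None
    C = res.x[:n_c].reshape(K, nu)
    xi = [res.x[xi_off(k):xi_off(k) + p] for k in range(K)]
    lam = {(k, l): res.x[lam_off(k, l):lam_off(k, l) + p]
           for k in range(K) for l in range(s_ex)}
    resid = float(np.max(np.abs(A_eq @ res.x - np.array(b_eq))))
    cand = PWLCandidate(C, form="abs", partition=part, convex=force_convex,
                        label="lp" + ("-as1-fallback" if fallback else ""))
    cand.kernel_ok = _kernel_rank_ok(C, net)
    return cand, LPCertificate(xi, lam, resid, as1_fallback=fallback)


# ---------------------------------------------------------------------------
# construction: sum-of-currents special case


def construct_soc(net: Network, part: Partition | None = None):
    """Find species weights xi > 0 making V = sum_i xi_i |xdot_i| an RLF.

    Over the default partition H = Gamma the region-wise decrease condition
    reduces, pair by pair, to the sign condition
    sigma_i * (sum_i' xi_i' sigma_i' Gamma_i'j) <= 0 on every kept region
    with signature sigma -- one LP in the n species weights (minimize
    1^T xi, xi >= 1; the result is integer-scaled). Requires AS1.
    """
    cons = conservation_analysis(net)
    if not cons.as1:
        return None
    if part is None:
        part = build_partition(net)
    if not np.array_equal(_exact.as_float(part.H), net.Gamma.astype(float)):
        raise ValueError("construct_soc needs the default partition H = Gamma")
    G = net.Gamma.astype(float)
    n, nu = G.shape
    pairs = net.reactant_pairs()
    A_ub = []
    for sig in part.signatures:
        for (j, i) in pairs:
            A_ub.append(sig[i] * (sig * G[:, j]))
    res = linprog(c=np.ones(n), A_ub=np.array(A_ub),
                  b_ub=np.zeros(len(A_ub)), bounds=[(1, None)] * n,
                  method="highs")
    if not res.success:
        return None
    xi = np.array([Fraction(x).limit_denominator(10**6) for x in res.x],
                  dtype=object)
    xi = _exact.integer_primitive(xi)
    C = np.array([[sum(Fraction(xi[i]) * int(sig[i]) * int(net.Gamma[i, j])
                       for i in range(n)) for j in range(nu)]
                  for sig in part.signatures], dtype=object)
    cand = PWLCandidate(C, form="abs", partition=part, xi=xi, convex=True,
                        label="soc")
    cand.kernel_ok = _kernel_rank_ok(C, net)
    return cand


# ---------------------------------------------------------------------------
# construction: iterative algorithm for convex PWL RLFs


def iterate_convex(net: Network, n_max: int = 100):
    """Row-growing iteration for a convex PWL RLF V(r) = max_k c_k^T r.

    Start from C = Gamma; for each processed row c_k, each reaction j in its
    support and each reactant X_i of R_j, propose c* = c_k + sgn(c_kj)
    gamma_i and append it unless it equals an existing row (or zero). The
    iteration succeeds when every row has been processed without growth;
    rows stay integer throughout. Neither AS1 nor non-autocatalysis is
    assumed. Returns a max-form :class:`PWLCandidate` (zero row implicit) or
    None when the cap is reached (inconclusive, not a refutation).
    """
    G = net.Gamma
    n, nu = G.shape
    rows: list[tuple[int, ...]] = []
    seen = {tuple([0] * nu)}
    for i in range(n):
        t = tuple(int(v) for v in G[i])
        if t not in seen:
            rows.append(t)
            seen.add(t)
    reactants = {j: [i for i in range(n) if net.A[i, j] > 0]
                 for j in range(nu)}
    k = 0
    for _ in range(n_max):
        if k >= len(rows):
            break
        ck = rows[k]
        for j in range(nu):
            if ck[j] == 0:
                continue
            sgn = 1 if ck[j] > 0 else -1
            for i in reactants[j]:
                cstar = tuple(ck[q] + sgn * int(G[i, q]) for q in range(nu))
                if cstar not in seen:
                    rows.append(cstar)
                    seen.add(cstar)
        k += 1
    if k < len(rows):
        return None
    return PWLCandidate(np.array(rows, dtype=int), form="max", convex=True,
                        label="iterate")


# ---------------------------------------------------------------------------
# construction: graphical max-min criterion


@dataclass
class MaxMinFailure:
    reason: str
    detail: str = ""

    def __bool__(self):
        return False


def graphical_maxmin(net: Network):
    """Graphical construction of a max-min RLF for M-networks.

    Conditions on the oriented irreversible subnetwork: (i) every species is
    a reactant of exactly one subnetwork reaction (at most one in the
    zero-flux case), and (ii) no product of an oriented-forward reversible
    reaction is a product of any other subnetwork reaction. On success,
    V = max R - min R over R = {(R_j - R_-j)/w_j} u {R_j/w_j}, with the
    constant 0 appended for zero-flux decompositions.
    """
    if net.is_autocatalytic:
        return MaxMinFailure("autocatalytic", "graphical criterion requires "
                                             "a non-autocatalytic network")
    md = m_decomposition(net)
    if md is None:
        return MaxMinFailure("not-an-M-network", "no orientation gives "
                             "dim ker(Gamma~) <= 1 with nonnegative flux")
    if md.zero_flux:
        # orientation is free when ker(Gamma~) = {0}: search for one that
        # meets the graphical conditions (lexicographic, forward first)
        import itertools
        pairs = net.reversible_pairs
        irr = net.irreversible_columns
        for mask in itertools.product((0, 1), repeat=len(pairs)):
            orientation = [jr if bit else jf
                           for (jf, jr), bit in zip(pairs, mask)]
            cols = sorted(irr + orientation)
            cand_md = MDecomposition(orientation, cols,
                                     net.Gamma[:, cols], None, zero_flux=True)
            fail = _maxmin_conditions(net, cand_md)
            if fail is None:
                return _maxmin_build(net, cand_md)
        return _maxmin_conditions(net, md)
    fail = _maxmin_conditions(net, md)
    if fail is not None:
        return fail
    return _maxmin_build(net, md)


def _maxmin_conditions(net: Network, md: MDecomposition):
    cols = md.columns
    A, B = net.A, net.B
    for i in range(net.n_species):
        cnt = sum(1 for j in cols if A[i, j] > 0)
        if cnt > 1 or (cnt == 0 and not md.zero_flux):
            return MaxMinFailure("species-multiplicity",
                                 f"species {net.species[i]} is a reactant of "
                                 f"{cnt} subnetwork reactions")
    rev_cols = {j for j in md.orientation}
    for j in cols:
        if j not in rev_cols:
            continue
        for i in range(net.n_species):
            if B[i, j] > 0:
                for j2 in cols:
                    if j2 != j and B[i, j2] > 0:
                        return MaxMinFailure(
                            "shared-product",
                            f"product {net.species[i]} of reversible "
                            f"{net.labels[j]} also produced by "
                            f"{net.labels[j2]}")
    if md.w is not None and any(x == 0 for x in md.w):
        return MaxMinFailure("zero-weight", "flux vector vanishes on a "
                                            "subnetwork reaction")
    return None


def _maxmin_build(net: Network, md: MDecomposition) -> MaxMinRLF:
    nu = net.n_reactions
    partner = {}
    for jf, jr in net.reversible_pairs:
        partner[jf] = jr
        partner[jr] = jf
    terms, labels = [], []
    for pos, j in enumerate(md.columns):
        w = Fraction(md.w[pos]) if md.w is not None else Fraction(1)
        a = np.array([Fraction(0)] * nu, dtype=object)
        a[j] = Fraction(1) / w
        lab = net.labels[j]
        if j in partner:
            a[partner[j]] = Fraction(-1) / w
            lab = f"{net.labels[j]}-{net.labels[partner[j]]}"
        if w != 1:
            lab = f"({lab})/{w}"
        terms.append(a)
        labels.append(lab)
    if md.zero_flux:
        labels = labels + ["0"]
    return MaxMinRLF(md, np.array(terms, dtype=object), labels,
                     include_zero=md.zero_flux)


# re-export the SDP construction (separate module for focus)
from ._sdp import PWQCandidate, construct_pwq_sdp  # noqa: E402,F401
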
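"""Piecewise quadratic-in-rates Lyapunov candidates via a copositive
relaxation.

On each partition region W_k the candidate is V(r) = r^T P_k r + 2 c_k^T r.
Exact copositive programming is NP-hard, so copositivity on a region is
relaxed to "PSD part plus entrywise-nonnegative part": matrices are
certified through A_k1, B_kl1 >= 0 (PSD) and A_k2, B_kl2 >= 0 (entrywise),
with continuity multipliers across neighboring regions and vanishing on
ker Gamma.

Two routes are used to produce a feasible point:

* when a piecewise linear certificate with the same partition exists, the
  rank-one point P_k = c_k c_k^T is feasible and all certificate matrices
  can be written down in closed form from the LP multipliers (positivity:
  A = 0; decrease: B_kl2 = lam xi^T + xi lam^T), so no numerical SDP solve
  is needed;
* otherwise a Dykstra alternating-projection search runs over the product
  of the affine constraint set and the PSD/nonnegative cones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps

from . import _exact
from .core import Network, extremals, conservation_analysis


@dataclass
class PWQCandidate:
    """Piecewise quadratic-in-rates candidate V(r) = r^T P_k r + 2 c_k^T r on
    +/- W_k (P is shared by a region and its negation; c flips sign)."""
    partition: object
    Ps: list[np.ndarray]
    cs: list[np.ndarray]
    certificates: dict = field(default_factory=dict)
    residual: float = 0.0
    label: str = ""

    def value(self, r) -> float:
        r = np.asarray(r, dtype=float)
        k, s = self.partition.locate(r)
        return float(r @ self.Ps[k] @ r + 2 * s * self.cs[k] @ r)

    def values(self, R) -> np.ndarray:
        R = np.atleast_2d(np.asarray(R, dtype=float))
        return np.array([self.value(R[:, t]) for t in range(R.shape[1])])

    def directional_derivative(self, r, v, tol: float = 1e-9) -> float:
        r = np.asarray(r, dtype=float)
        v = np.asarray(v, dtype=float)
        best = -np.inf
        for k, s in self.partition.containing_regions(r, tol):
            g = 2 * self.Ps[k] @ r + 2 * s * self.cs[k]
            best = max(best, float(g @ v))
        if best == -np.inf:
            k, s = self.partition.locate(r)
            best = float((2 * self.Ps[k] @ r + 2 * s * self.cs[k]) @ v)
        return best


def _sym(M):
    return 0.5 * (M + M.T)


def _psd_project(M):
    w, V = np.linalg.eigh(_sym(M))
    w = np.maximum(w, 0.0)
    return (V * w) @ V.T


def sampled_pwq_check(net: Network, cand: PWQCandidate, n_samples: int = 10_000,
                      seed: int = 0) -> tuple[float, float]:
    """Sample r per region; return (max decrease violation, max negativity of
    V) over the samples. Decrease along extremal Q_l on W_k means
    r^T (Q_l^T P_k + P_k Q_l) r + 2 c_k^T Q_l r <= 0."""
    rng = np.random.default_rng(seed)
    ex = extremals(net)
    part = cand.partition
    Hf = _exact.as_float(part.H)
    nu = Hf.shape[1]
    worst_dec, worst_pos = -np.inf, 0.0
    per_region = max(1, n_samples // max(1, part.n_regions))
    for k, sig in enumerate(part.signatures):
        rows = sig[:, None] * Hf
        found = 0
        tries = 0
        while found < per_region and tries < 50 * per_region:
            tries += 1
            r = rng.standard_normal(nu)
            if np.all(rows @ r >= 0):
                found += 1
                v = float(r @ cand.Ps[k] @ r + 2 * cand.cs[k] @ r)
                worst_pos = min(worst_pos, v)
                for Q in ex.Qs:
                    Qf = Q.astype(float)
                    dec = float(r @ (Qf.T @ cand.Ps[k] + cand.Ps[k] @ Qf) @ r
                                + 2 * cand.cs[k] @ Qf @ r)
                    worst_dec = max(worst_dec, dec / (1 + r @ r))
    return (worst_dec if worst_dec > -np.inf else 0.0), -worst_pos


def _rank_one_point(net: Network, part, cand, cert):
    """Assemble the explicit rank-one feasible point P_k = c_k c_k^T from a
    partition-form PWL certificate (LP multipliers xi_k, lambda_kl)."""
    from .rlf import neighbor_pairs
    Hf = _exact.as_float(part.H)
    K = part.n_regions
    Cf = _exact.as_float(cand.C)
    Ps = [np.outer(Cf[k], Cf[k]) for k in range(K)]
    cs = [np.zeros(Hf.shape[1]) for _ in range(K)]
    ex = extremals(net)
    resid = 0.0
    certs = {"A": "zero", "B2": {}, "continuity": {}}
    for k in range(K):
        xi = np.maximum(cert.xi[k], 0.0)
        for l, Q in enumerate(ex.Qs):
            lam = part.signatures[k] * cert.lam[(k, l)]
            lam = np.maximum(lam, 0.0)
            B2 = np.outer(lam, xi) + np.outer(xi, lam)
            SkH = part.signatures[k][:, None] * Hf
            lhs = Q.T.astype(float) @ Ps[k] + Ps[k] @ Q.astype(float) \
                + SkH.T @ B2 @ SkH
            resid = max(resid, float(np.abs(lhs).max()) /
                        (1.0 + float(np.abs(Ps[k]).max())))
            certs["B2"][(k, l)] = B2
    # continuity across neighbors: P_k - P_j = lam h^T + h lam^T needs
    # c_k - sign*c_j parallel to the differing row h_s
    for (k, j, s, sign) in neighbor_pairs(part):
        h = Hf[s]
        d = Cf[k] - sign * Cf[j]
        hn = h / (h @ h)
        eta = float(d @ hn)
        if np.max(np.abs(d - eta * h)) > 1e-7 * (1 + np.abs(Cf).max()):
            return None
        lam_kj = eta * (sign * Cf[j]) + 0.5 * eta**2 * h
        lhs = Ps[k] - Ps[j] - (np.outer(lam_kj, h) + np.outer(h, lam_kj))
        resid = max(resid, float(np.abs(lhs).max()) /
                    (1.0 + float(np.abs(Ps[k]).max())))
        certs["continuity"][(k, j)] = lam_kj
    return PWQCandidate(part, Ps, cs, certs, resid, label="pwq-rank-one")


def construct_pwq_sdp(net: Network, part=None, max_iter: int = 3000,
                      tol: float = 1e-7):
    """Piecewise quadratic-in-rates RLF candidate over a conic partition.

    Tries the constructive rank-one route first (a PWL certificate over the
    same partition yields P_k = c_k c_k^T with closed-form relaxation
    certificates); otherwise runs a Dykstra alternating-projection
    feasibility search on the relaxed semidefinite program with c_k = 0.
    Returns a :class:`PWQCandidate`, or None when no certificate is found
    under this relaxation (a relaxation gap is possible).
    """
    from .rlf import build_partition, construct_pwl_lp, construct_soc

    from .rlf import LPCertificate

    cons = conservation_analysis(net)
    if not cons.as1:
        return None
    if part is None:
        part = build_partition(net)
    is_default = part.H.shape[0] == net.n_species and \
        np.array_equal(_exact.as_float(part.H), net.Gamma.astype(float))
    soc = construct_soc(net, part) if is_default else None
    if soc is not None and soc.kernel_ok:
        # SoC multipliers in closed form: c_k = xi^T Sigma_k Gamma and
        # c_k^T Q_l = (c_k)_j gamma_i^T = -lam^T H with lam = -(c_k)_j e_i
        Cf = _exact.as_float(soc.C)
        ex = extremals(net)
        xi_f = _exact.as_float(soc.xi)
        xis = [xi_f.copy() for _ in range(part.n_regions)]
        lam = {}
        for k in range(part.n_regions):
            for l, (j, i) in enumerate(ex.pairs):
                e = np.zeros(net.n_species)
                e[i] = -Cf[k, j]
                lam[(k, l)] = e
        cert = LPCertificate(xis, lam, 0.0)
        point = _rank_one_point(net, part, soc, cert)
        if point is not None and point.residual < 1e-6:
            return point
    out = construct_pwl_lp(net, part)
    if out is not None:
        cand_lp, cert = out
        if cand_lp.kernel_ok:
            point = _rank_one_point(net, part, cand_lp, cert)
            if point is not None and point.residual < 1e-6:
                return point
    return _dykstra_search(net, part, max_iter=max_iter, tol=tol)


def _dykstra_search(net: Network, part, max_iter: int, tol: float):
    """Alternating-projection feasibility search (c_k = 0 variant)."""
    from .rlf import neighbor_pairs

    Hf = _exact.as_float(part.H)
    p, nu = Hf.shape
    K = part.n_regions
    ex = extremals(net)
    s_ex = ex.s
    kern = [_exact.as_float(v) for v in _exact.nullspace(net.Gamma)]
    Vk = np.column_stack(kern) if kern else np.zeros((nu, 0))
    Uimg = [_exact.as_float(u) for u in _exact.column_space(net.Gamma.T)]
    U = np.column_stack(Uimg) if Uimg else np.zeros((nu, 0))

    # variable blocks: P_k (sym, free), S_k (PSD), A2_k (nonneg sym p),
    # T_kl (PSD), B2_kl (nonneg sym p), lam_kj (free)
    blocks = []          # (name, shape, cone)
    for k in range(K):
        blocks.append((f"P{k}", (nu, nu), "free"))
        blocks.append((f"S{k}", (nu, nu), "psd"))
        blocks.append((f"A{k}", (p, p), "nonneg"))
        for l in range(s_ex):
            blocks.append((f"T{k}_{l}", (nu, nu), "psd"))
            blocks.append((f"B{k}_{l}", (p, p), "nonneg"))
    nbrs = neighbor_pairs(part)
    for (k, j, s, sign) in nbrs:
        blocks.append((f"L{k}_{j}", (nu,), "free"))

    offsets, sizes = {}, {}
    off = 0
    for name, shape, cone in blocks:
        sz = int(np.prod(shape))
        offsets[name] = off
        sizes[name] = (shape, cone)
        off += sz
    n_var = off

    rows, cols, vals, rhs = [], [], [], []

    def eq_idx():
        return len(rhs)

    def add_entry(i, name, flat_index, val):
        rows.append(i)
        cols.append(offsets[name] + flat_index)
        vals.append(val)

    def mat_index(shape, a, b):
        return a * shape[1] + b

    # E1: P_k - S_k - (Sk H)^T A2_k (Sk H) = 0   (entrywise on sym part)
    for k in range(K):
        SkH = part.signatures[k][:, None] * Hf
        for a in range(nu):
            for b in range(a, nu):
                i = eq_idx()
                rhs.append(0.0)
                add_entry(i, f"P{k}", mat_index((nu, nu), a, b), 1.0)
                add_entry(i, f"S{k}", mat_index((nu, nu), a, b), -1.0)
                for q in range(p):
                    for t in range(p):
                        coef = -SkH[q, a] * SkH[t, b]
                        if coef != 0.0:
                            add_entry(i, f"A{k}", mat_index((p, p), q, t), coef)
    # E2: -(Q^T P + P Q) - T - (Sk H)^T B2 (Sk H) = 0
    for k in range(K):
        SkH = part.signatures[k][:, None] * Hf
        for l, Q in enumerate(ex.Qs):
            Qf = Q.astype(float)
            for a in range(nu):
                for b in range(a, nu):
                    i = eq_idx()
                    rhs.append(0.0)
                    for t in range(nu):
                        if Qf[t, a] != 0.0:
                            add_entry(i, f"P{k}", mat_index((nu, nu), t, b),
                                      -Qf[t, a])
                        if Qf[t, b] != 0.0:
                            add_entry(i, f"P{k}", mat_index((nu, nu), a, t),
                                      -Qf[t, b])
                    add_entry(i, f"T{k}_{l}", mat_index((nu, nu), a, b), -1.0)
                    for q in range(p):
                        for t in range(p):
                            coef = -SkH[q, a] * SkH[t, b]
                            if coef != 0.0:
                                add_entry(i, f"B{k}_{l}",
                                          mat_index((p, p), q, t), coef)
    # E3: continuity P_k - P_j = lam h^T + h lam^T
    for (k, j, s, sign) in nbrs:
        h = Hf[s]
        for a in range(nu):
            for b in range(a, nu):
                i = eq_idx()
                rhs.append(0.0)
                add_entry(i, f"P{k}", mat_index((nu, nu), a, b), 1.0)
                add_entry(i, f"P{j}", mat_index((nu, nu), a, b), -1.0)
                if h[b] != 0.0:
                    add_entry(i, f"L{k}_{j}", a, -h[b])
                if h[a] != 0.0:
                    add_entry(i, f"L{k}_{j}", b, -h[a])
    # E4: P_k annihilates ker Gamma
    for k in range(K):
        for vcol in range(Vk.shape[1]):
            for a in range(nu):
                i = eq_idx()
                rhs.append(0.0)
                for b in range(nu):
                    if Vk[b, vcol] != 0.0:
                        add_entry(i, f"P{k}", mat_index((nu, nu), a, b),
                                  Vk[b, vcol])
    # normalization to exclude the trivial zero point:
    # sum_k trace(P_k U U^T) = K
    if U.shape[1]:
        M = U @ U.T
        i = eq_idx()
        rhs.append(float(K))
        for k in range(K):
            for a in range(nu):
                for b in range(nu):
                    if M[a, b] != 0.0:
                        add_entry(i, f"P{k}", mat_index((nu, nu), a, b),
                                  M[a, b])

    A = sps.coo_matrix((vals, (rows, cols)), shape=(len(rhs), n_var)).tocsc()
    b = np.array(rhs)
    AAT = (A @ A.T).toarray()
    # least-squares projector onto {z : A z = b}
    AAT_inv = np.linalg.pinv(AAT)

    def proj_affine(z):
        return z - A.T @ (AAT_inv @ (A @ z - b))

    def proj_cones(z):
        out = z.copy()
        for name, (shape, cone) in sizes.items():
            sl = slice(offsets[name], offsets[name] + int(np.prod(shape)))
            if cone == "psd":
                out[sl] = _psd_project(z[sl].reshape(shape)).ravel()
            elif cone == "nonneg":
                M = _sym(z[sl].reshape(shape))
                out[sl] = np.maximum(M, 0.0).ravel()
            elif cone == "free" and len(shape) == 2:
                out[sl] = _sym(z[sl].reshape(shape)).ravel()
        return out

    rng = np.random.default_rng(0)
    z = 0.01 * rng.standard_normal(n_var)
    q = np.zeros(n_var)
    for it in range(max_iter):
        y = proj_affine(z)
        w = proj_cones(y + q)
        q = y + q - w
        gap = float(np.max(np.abs(w - y)))
        z = w
        if gap < tol and float(np.max(np.abs(A @ w - b))) < 10 * tol:
            break
    else:
        return None
    Ps = [_sym(z[offsets[f"P{k}"]:offsets[f"P{k}"] + nu * nu].reshape(nu, nu))
          for k in range(K)]
    cs = [np.zeros(nu) for _ in range(K)]
    resid = float(np.max(np.abs(A @ z - b)))
    return PWQCandidate(part, Ps, cs, {"route": "dykstra"}, resid,
                        label="pwq-dykstra")
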
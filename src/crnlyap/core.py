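"""Chemical reaction network structure: parsing, stoichiometry, and the
rank-one extremal decomposition of the rate-space dynamics.

A network is a species set {X_1..X_n} and a reaction set {R_1..R_nu} with
reactant coefficients alpha_ij (matrix A), product coefficients beta_ij
(matrix B) and stoichiometry matrix Gamma = B - A, so that concentrations
evolve as xdot = Gamma R(x) for any admissible rate vector R. A reversible
reaction is stored as two adjacent columns (forward, then reverse).

In rate coordinates, rdot = (dR/dx) Gamma r lies in the convex cone spanned
by the rank-one extremals Q_l = e_j gamma_i^T, one per reaction-reactant
pair (j, i) with alpha_ij > 0. All Lyapunov-function machinery in this
package consumes that extremal set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from . import _exact

SPECIES_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_+*']*)$")
TERM_RE = re.compile(r"^(?:(\d+)\s*)?([A-Za-z][A-Za-z0-9_+*']*)$")


class ParseError(ValueError):
    pass


@dataclass
class Reaction:
    """One column of the network: reactants/products as name -> coefficient."""
    reactants: dict[str, int]
    products: dict[str, int]
    label: str
    reverse_of: int | None = None   # column index of the forward partner


@dataclass
class Network:
    species: list[str]
    reactions: list[Reaction]
    A: np.ndarray                   # n x nu reactant coefficients alpha_ij
    B: np.ndarray                   # n x nu product coefficients beta_ij
    reversible_pairs: list[tuple[int, int]] = field(default_factory=list)
    name: str = ""

    # -- construction ------------------------------------------------------

    @classmethod
    def from_text(cls, text: str, name: str = "",
                  species_order: list[str] | None = None) -> "Network":
        return parse_network(text, name=name, species_order=species_order)

    @classmethod
    def from_matrices(cls, A, B, species=None,
                      reversible_pairs=None, name: str = "") -> "Network":
        A = np.asarray(A, dtype=int)
        B = np.asarray(B, dtype=int)
        if A.shape != B.shape:
            raise ValueError("A and B must have identical shapes")
        if (A < 0).any() or (B < 0).any():
            raise ValueError("stoichiometry coefficients must be nonnegative")
        n, nu = A.shape
        if species is None:
            species = [f"X{i+1}" for i in range(n)]
        species = list(species)
        for j in range(nu):
            if not A[:, j].any() and not B[:, j].any():
                raise ValueError(f"reaction column {j} is empty on both sides")
        reversible_pairs = [tuple(p) for p in (reversible_pairs or [])]
        reactions = []
        rev_lookup = {jr: jf for jf, jr in reversible_pairs}
        for j in range(nu):
            reactions.append(Reaction(
                reactants={species[i]: int(A[i, j]) for i in range(n) if A[i, j]},
                products={species[i]: int(B[i, j]) for i in range(n) if B[i, j]},
                label=f"R{j+1}",
                reverse_of=rev_lookup.get(j)))
        net = cls(species, reactions, A, B, reversible_pairs, name)
        net.validate()
        return net

    def validate(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        if self.A.shape != self.B.shape or self.A.shape[0] != len(self.species):
            raise ValueError("matrix shapes inconsistent with species list")
        for jf, jr in self.reversible_pairs:
            if not (np.array_equal(self.A[:, jr], self.B[:, jf])
                    and np.array_equal(self.B[:, jr], self.A[:, jf])):
                raise ValueError(f"columns {jf},{jr} are not a reversible pair")

    # -- basic structure ---------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return self.A.shape[1]

    @property
    def Gamma(self) -> np.ndarray:
        return self.B - self.A

    @property
    def labels(self) -> list[str]:
        return [rx.label for rx in self.reactions]

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def reaction_index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def is_autocatalytic(self) -> bool:
        """True if some species appears on both sides of one reaction."""
        return bool(((self.A > 0) & (self.B > 0)).any())

    @property
    def irreversible_columns(self) -> list[int]:
        paired = {j for p in self.reversible_pairs for j in p}
        return [j for j in range(self.n_reactions) if j not in paired]

    def reactant_pairs(self) -> list[tuple[int, int]]:
        """The set P of (reaction j, species i) pairs with alpha_ij > 0,
        enumerated column-major (by reaction, then species)."""
        return [(j, i) for j in range(self.n_reactions)
                for i in range(self.n_species) if self.A[i, j] > 0]

    def to_matrix_text(self, sep: str = "\t") -> str:
        """Delimited-text export of A, B and Gamma."""
        out = []
        for tag, M in (("A", self.A), ("B", self.B), ("Gamma", self.Gamma)):
            out.append(f"# {tag} (species x reactions)")
            out.append(sep.join(["species"] + self.labels))
            for i, sp_name in enumerate(self.species):
                out.append(sep.join([sp_name] + [str(int(v)) for v in M[i]]))
            out.append("")
        return "\n".join(out)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" {self.name!r}" if self.name else ""
        return (f"<Network{tag}: {self.n_species} species, "
                f"{self.n_reactions} reactions, "
                f"{len(self.reversible_pairs)} reversible pairs>")


# ---------------------------------------------------------------------------
# parsing


def _parse_complex(side: str, lineno: int) -> dict[str, int]:
    side = side.strip()
    if side == "0":
        return {}
    terms = re.split(r"\s+\+\s+", side)
    out: dict[str, int] = {}
    for term in terms:
        term = term.strip()
        m = TERM_RE.match(term)
        if not m:
            raise ParseError(f"line {lineno}: cannot parse term {term!r} "
                             "(coefficients must be nonnegative integers)")
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff <= 0:
            raise ParseError(f"line {lineno}: zero coefficient in {term!r}")
        name = m.group(2)
        out[name] = out.get(name, 0) + coeff
    return out


def parse_network(text: str, name: str = "",
                  species_order: list[str] | None = None) -> Network:
    """Parse a plain-text reaction list into a :class:`Network`.

    Grammar: one reaction per line, ``<complex> -> <complex>`` or
    ``<complex> <-> <complex>``; a complex is ``c1 S1 + c2 S2 + ...`` or the
    empty complex ``0`` (inflow/outflow). ``#`` starts a comment. Species
    names match ``[A-Za-z][A-Za-z0-9_+*']*`` (note ``+`` is legal inside a
    name, so the term separator is a whitespace-delimited ``+``). Species are
    ordered by first appearance unless ``species_order`` pins the order.
    """
    species: list[str] = []
    seen_lines: dict[tuple, int] = {}
    rows = []          # (reactants, products, reversible, lineno)
    rxn_counter = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "<->" in line or "<=>" in line:
            parts = re.split(r"<->|<=>", line)
            reversible = True
        elif "->" in line:
            parts = line.split("->")
            reversible = False
        else:
            raise ParseError(f"line {lineno}: no reaction arrow found")
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected exactly one arrow")
        lhs = _parse_complex(parts[0], lineno)
        rhs = _parse_complex(parts[1], lineno)
        if not lhs and not rhs:
            raise ParseError(f"line {lineno}: both complexes are empty")
        key = (tuple(sorted(lhs.items())), tuple(sorted(rhs.items())), reversible)
        if key in seen_lines:
            warnings.warn(f"line {lineno}: duplicate of reaction on line "
                          f"{seen_lines[key]}", stacklevel=2)
        else:
            seen_lines[key] = lineno
        for cx in (lhs, rhs):
            for nm in cx:
                if nm not in species:
                    species.append(nm)
        rxn_counter += 1
        rows.append((lhs, rhs, reversible, rxn_counter))

    if species_order is not None:
        missing = set(species) - set(species_order)
        if missing:
            raise ParseError(f"species_order is missing {sorted(missing)}")
        species = [s for s in species_order]

    idx = {s: i for i, s in enumerate(species)}
    n = len(species)
    cols_A, cols_B, reactions, pairs = [], [], [], []
    for lhs, rhs, reversible, k in rows:
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        for nm, c in lhs.items():
            a[idx[nm]] = c
        for nm, c in rhs.items():
            b[idx[nm]] = c
        j = len(cols_A)
        cols_A.append(a)
        cols_B.append(b)
        reactions.append(Reaction(dict(lhs), dict(rhs), f"R{k}"))
        if reversible:
            cols_A.append(b.copy())
            cols_B.append(a.copy())
            reactions.append(Reaction(dict(rhs), dict(lhs), f"R-{k}", reverse_of=j))
            pairs.append((j, j + 1))
    A = np.column_stack(cols_A) if cols_A else np.zeros((n, 0), dtype=int)
    B = np.column_stack(cols_B) if cols_B else np.zeros((n, 0), dtype=int)
    net = Network(species, reactions, A, B, pairs, name)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# extremal decomposition


@dataclass
class ExtremalSet:
    """Reaction-reactant pairs P and the rank-one matrices Q_l = e_j gamma_i^T
    whose nonnegative cone contains (dR/dx) Gamma for every admissible R."""
    pairs: list[tuple[int, int]]
    Qs: list[np.ndarray]

    @property
    def s(self) -> int:
        return len(self.pairs)


def extremals(net: Network) -> ExtremalSet:
    G = net.Gamma
    nu = net.n_reactions
    pairs = net.reactant_pairs()
    Qs = []
    for (j, i) in pairs:
        Q = np.zeros((nu, nu), dtype=int)
        Q[j, :] = G[i, :]
        Qs.append(Q)
    return ExtremalSet(pairs, Qs)


# ---------------------------------------------------------------------------
# conservation analysis


@dataclass
class ConservationBasis:
    left_kernel: list[np.ndarray]     # exact basis of {d : d^T Gamma = 0}
    nonneg_laws: list[np.ndarray]     # independent nonnegative conservation laws
    is_conservative: bool
    right_kernel: list[np.ndarray]    # exact basis of ker Gamma
    positive_flux: np.ndarray | None  # v in ker Gamma with v >= 1 (AS1), or None

    @property
    def as1(self) -> bool:
        return self.positive_flux is not None


def _rational_lp_vector(x: np.ndarray, basis: list[np.ndarray]) -> np.ndarray | None:
    return _exact.rationalize_in_span(x, basis)


def conservation_analysis(net: Network) -> ConservationBasis:
    G = net.Gamma
    n, nu = G.shape
    left = _exact.left_nullspace(G)
    right = _exact.nullspace(G)

    # nonnegative laws: for each species, try to find a nonnegative law
    # supporting it (LP with d_i >= 1), and greedily keep an independent set.
    nonneg: list[np.ndarray] = []
    supported = np.zeros(n, dtype=bool)
    for i in range(n):
        if not left:
            break
        if supported[i]:
            continue
        A_eq = np.vstack([G.T.astype(float), np.zeros((1, n))])
        A_eq[-1, i] = 1.0
        b_eq = np.zeros(nu + 1)
        b_eq[-1] = 1.0
        res = linprog(c=np.ones(n), A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * n, method="highs")
        if not res.success:
            continue
        supported[i] = True
        d = _rational_lp_vector(res.x, left)
        if d is None:
            continue
        d = _exact.integer_primitive(d)
        if any(v < 0 for v in d):
            continue
        supported |= _exact.as_float(d) > 0
        stacked = [_exact.as_float(v) for v in nonneg] + [_exact.as_float(d)]
        if _exact.rank(np.vstack(stacked)) > len(nonneg):
            nonneg.append(d)
    conservative = bool(supported.all()) if n else True

    # positive flux (AS1): v in ker Gamma, v >= 1 (scale-invariant form of v >> 0)
    positive_flux = None
    if right:
        res = linprog(c=np.ones(nu), A_eq=G.astype(float), b_eq=np.zeros(n),
                      bounds=[(1, None)] * nu, method="highs")
        if res.success:
            v = _rational_lp_vector(res.x, right)
            if v is not None:
                mn = min(v)
                if mn > 0:
                    if mn < 1:
                        v = np.array([x / mn for x in v], dtype=object)
                    positive_flux = v
    return ConservationBasis(left, nonneg, conservative, right, positive_flux)


# ---------------------------------------------------------------------------
# deficiency


@dataclass
class DeficiencyReport:
    n_complexes: int
    n_linkage: int
    rank: int

    @property
    def deficiency(self) -> int:
        return self.n_complexes - self.n_linkage - self.rank


def deficiency(net: Network) -> DeficiencyReport:
    """Complexes are deduplicated coefficient vectors; linkage classes are
    connected components of the undirected complex graph."""
    complexes: dict[tuple, int] = {}

    def cid(col: np.ndarray) -> int:
        key = tuple(int(v) for v in col)
        return complexes.setdefault(key, len(complexes))

    edges = []
    for j in range(net.n_reactions):
        edges.append((cid(net.A[:, j]), cid(net.B[:, j])))
    parent = list(range(len(complexes)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    n_link = len({find(c) for c in range(len(complexes))})
    return DeficiencyReport(len(complexes), n_link, _exact.rank(net.Gamma))


# ---------------------------------------------------------------------------
# M-decomposition (orientation of reversible pairs)


@dataclass
class MDecomposition:
    orientation: list[int]          # chosen forward column per reversible pair
    columns: list[int]              # subnetwork columns, in original order
    Gamma_tilde: np.ndarray
    w: np.ndarray | None            # nonnegative kernel vector (Fractions), or
    zero_flux: bool = False         # True when ker(Gamma_tilde) = {0}

    def column_weight(self, j: int) -> Fraction:
        return Fraction(self.w[self.columns.index(j)]) if self.w is not None else Fraction(1)


def m_decomposition(net: Network) -> MDecomposition | None:
    """Orient reversible pairs so the irreversible subnetwork's stoichiometry
    has nullspace of dimension <= 1 (an "M-network").

    Flipping an orientation only negates a column of Gamma_tilde, so the
    kernel dimension is orientation-invariant; when it is one, the orientation
    with a nonnegative kernel vector (if any) is obtained by flipping exactly
    the pairs whose kernel entry is negative.  This reproduces the first
    success of a lexicographic orientation search (forward-as-written first).
    """
    pairs = net.reversible_pairs
    fwd = [jf for jf, _ in pairs]
    irr = net.irreversible_columns
    cols = sorted(irr + fwd)
    Gt = net.Gamma[:, cols]
    kern = _exact.nullspace(Gt)
    if len(kern) > 1:
        return None
    if len(kern) == 0:
        return MDecomposition(list(fwd), cols, Gt, None, zero_flux=True)
    v = kern[0]
    irr_set = set(irr)
    candidates = []
    for sign in (1, -1):
        sv = [sign * x for x in v]
        if any(sv[pos] < 0 for pos, j in enumerate(cols) if j in irr_set):
            continue  # irreversible columns cannot be flipped
        orientation = list(fwd)
        mask = []
        for pi, (jf, jr) in enumerate(pairs):
            if sv[cols.index(jf)] < 0:
                orientation[pi] = jr
                mask.append(1)
            else:
                mask.append(0)
        candidates.append((tuple(mask), orientation))
    if not candidates:
        return None
    _, orientation = min(candidates)
    new_cols = sorted(irr + orientation)
    Gt = net.Gamma[:, new_cols]
    # kernel entry for a flipped column is the negation of the original one,
    # so the oriented kernel vector is just |v|
    w_raw = []
    pair_of = {jf: (jf, jr) for jf, jr in pairs}
    pair_of.update({jr: (jf, jr) for jf, jr in pairs})
    for j in new_cols:
        if j in irr_set:
            w_raw.append(abs(v[cols.index(j)]))
        else:
            jf = pair_of[j][0]
            w_raw.append(abs(v[cols.index(jf)]))
    positives = [x for x in w_raw if x > 0]
    mn = min(positives) if positives else Fraction(1)
    w = np.array([Fraction(x) / mn for x in w_raw], dtype=object)
    return MDecomposition(orientation, new_cols, Gt, w, zero_flux=False)
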
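"""Catalog of worked biochemical networks.

Every network is built programmatically from its reaction-list text, so the
catalog doubles as a parser exercise. Species orderings are frozen per
fixture (printed weight vectors are order-dependent).

Catalog highlights: post-translational modification (PTM) cycles and
cascades, phosphotransfer/phosphorelay motifs, T-cell kinetic proofreading,
the ERK/RKIP module, the ribosome flow model, and small binding motifs.
"""

from __future__ import annotations

import numpy as np

from .core import Network, parse_network


def ptm_reduced() -> Network:
    """Irreversible 4-reaction PTM cycle (kinase E phosphorylates S to Y via
    C1; phosphatase F reverts via C2)."""
    return parse_network("""
        S + E -> C1
        C1 -> Y + E
        Y + F -> C2
        C2 -> S + F
    """, name="ptm_reduced")


def ptm_full() -> Network:
    """Full PTM (futile) cycle with reversible substrate binding."""
    return parse_network("""
        S + E <-> SE
        SE -> S+ + E
        S+ + F <-> S+F
        S+F -> S + F
    """, name="ptm_full")


def simple_binding() -> Network:
    return parse_network("X + E <-> XE", name="simple_binding")


def binding_inflow() -> Network:
    """Binding with enzyme inflow/outflow."""
    return parse_network("""
        X + E <-> XE
        0 <-> E
    """, name="binding_inflow")


def cooperative_binding(n: int = 2) -> Network:
    if n < 1:
        raise ValueError("n >= 1")
    return parse_network(f"""
        {n} E <-> En
        En + X <-> XEn
    """, name=f"cooperative_binding({n})")


def competitive_binding() -> Network:
    return parse_network("""
        E1 + X <-> XE1
        X + E2 <-> XE2
    """, name="competitive_binding")


def three_body_binding() -> Network:
    """Ternary complex formation: X and Y bind only through the bridge E."""
    return parse_network("""
        X + E <-> XE
        Y + E <-> EY
        EY + X <-> XEY
        Y + XE <-> XEY
    """, name="three_body_binding")


def transcription() -> Network:
    """mRNA production by RNA polymerase, with polymerase not assumed
    abundant; species order RNAP, DNA, RD, mRNA."""
    return parse_network("""
        RNAP + DNA <-> RD
        RD -> RNAP + DNA + mRNA
        mRNA -> 0
    """, name="transcription")


def translation_leak() -> Network:
    """Translation with ribosome leak; P decays. The P-free core is
    :func:`translation_core`."""
    return parse_network("""
        Rib + mRNA <-> C
        C -> mRNA + P + Rib
        C -> Rib
        P -> 0
    """, name="translation_leak")


def translation_core() -> Network:
    """Ribosome/mRNA subnetwork of :func:`translation_leak` (the protein
    decouples as a downstream cascade stage)."""
    return parse_network("""
        Rib + mRNA <-> C
        C -> mRNA + Rib
        C -> Rib
    """, name="translation_core")


def enzymatic_motif() -> Network:
    return parse_network("""
        S + E <-> ES
        ES -> E + S+
    """, name="enzymatic_motif")


def enzymatic_cycle() -> Network:
    """Activation motif closed by spontaneous decay of the active form."""
    return parse_network("""
        S + E <-> SE
        SE -> E + S+
        S+ -> S
    """, name="enzymatic_cycle")


def energy_ptm_basic() -> Network:
    """Kinase-ATP phosphorylation motif with explicit ATP/ADP dynamics.
    AK = ATP:kinase, PAK = protein:ATP:kinase, PpAK = phosphoprotein still
    bound to the ADP:kinase complex, ADPK = ADP:kinase."""
    return parse_network("""
        K + ATP <-> AK
        P + AK <-> PAK
        PAK -> PpAK
        PpAK -> Pp + ADPK
        ADPK <-> K + ADP
    """, name="energy_ptm_basic")


def energy_ptm_cycle() -> Network:
    """Energy-constrained PTM cycle: the basic motif closed by ADP
    regeneration and spontaneous dephosphorylation."""
    return parse_network("""
        K + ATP <-> AK
        P + AK <-> PAK
        PAK -> PpAK
        PpAK -> Pp + ADPK
        ADPK <-> K + ADP
        ADP -> ATP
        Pp -> P
    """, name="energy_ptm_cycle")


def multisite_distinct(n: int = 2) -> Network:
    """Cascade of n PTM cycles with distinct kinases E_i and phosphatases
    F_i; species ordered X0..Xn first (the printed weights put 2 on the
    substrate forms and 1 elsewhere)."""
    if n < 1:
        raise ValueError("n >= 1")
    lines = []
    order = [f"X{i}" for i in range(n + 1)]
    for i in range(n):
        lines.append(f"X{i} + E{i} <-> E{i}X{i}")
        lines.append(f"E{i}X{i} -> X{i+1} + E{i}")
        lines.append(f"X{i+1} + F{i} <-> F{i}X{i+1}")
        lines.append(f"F{i}X{i+1} -> X{i} + F{i}")
        order += [f"E{i}", f"E{i}X{i}", f"F{i}", f"F{i}X{i+1}"]
    return parse_network("\n".join(lines), name=f"multisite_distinct({n})",
                         species_order=order)


def processive(n: int = 2) -> Network:
    """Multisite PTM with a processive mechanism (enzyme stays bound while
    modifying all n sites)."""
    if n < 1:
        raise ValueError("n >= 1")
    lines = [f"X0 + E <-> EX1"]
    for i in range(1, n):
        lines.append(f"EX{i} <-> EX{i+1}")
    lines.append(f"EX{n} -> X{n} + E")
    lines.append(f"X{n} + F <-> FX{n}")
    for i in range(n, 1, -1):
        lines.append(f"FX{i} <-> FX{i-1}")
    lines.append(f"FX1 -> X0 + F")
    return parse_network("\n".join(lines), name=f"processive({n})")


def all_encompassing(ms: tuple[int, ...] = (2, 2)) -> Network:
    """Generalized processive cycle: n substrate forms, each converted by its
    own enzyme through a chain of m_i intermediates, cyclically."""
    n = len(ms)
    if n < 1 or any(m < 1 for m in ms):
        raise ValueError("need at least one stage with m_i >= 1")
    lines = []
    for i, m in enumerate(ms, start=1):
        nxt = 1 if i == n else i + 1
        lines.append(f"X{i} + E{i} <-> C{i}_1")
        for q in range(1, m):
            lines.append(f"C{i}_{q} <-> C{i}_{q+1}")
        lines.append(f"C{i}_{m} -> X{nxt} + E{i}")
    return parse_network("\n".join(lines),
                         name=f"all_encompassing{tuple(ms)}")


def distributive_double() -> Network:
    """Double PTM cycle with a distributive mechanism (the multistable
    counterpart of processive(2))."""
    return parse_network("""
        X0 + E <-> EX0
        EX0 -> X1 + E
        X1 + F <-> FX1
        FX1 -> X0 + F
        X1 + E <-> EX1
        EX1 -> X2 + E
        X2 + F <-> FX2
        FX2 -> X1 + F
    """, name="distributive_double")


def phosphotransfer_motif() -> Network:
    """Histidine-kinase phosphotransfer with single-step (de)phosphorylation;
    Zp/Xp denote phosphorylated forms."""
    return parse_network("""
        Zp + X <-> C
        C <-> Xp + Z
        Z -> Zp
        Xp -> X
    """, name="phosphotransfer_motif")


def phosphotransfer_enzymes() -> Network:
    return parse_network("""
        Zp + X <-> C
        C <-> Xp + Z
        Z + F <-> FZ
        FZ -> Zp + F
        Xp + E <-> EXp
        EXp -> X + E
    """, name="phosphotransfer_enzymes")


def phosphorelay(n: int = 3) -> Network:
    """Cascade of n phosphotransfer stages (e.g. KinA-Spo0F-Spo0B-Spo0A)."""
    if n < 2:
        raise ValueError("n >= 2")
    lines = [f"X1 -> X1p", f"X{n}p -> X{n}"]
    for i in range(1, n):
        lines.append(f"X{i}p + X{i+1} <-> C{i}")
        lines.append(f"C{i} <-> X{i+1}p + X{i}")
    return parse_network("\n".join(lines), name=f"phosphorelay({n})")


def kinetic_proofreading(N: int = 2) -> Network:
    """T-cell kinetic proofreading: ligand M binds receptor L, complex
    matures through C_0..C_N, any C_i (i>=1) may dissociate."""
    if N < 1:
        raise ValueError("N >= 1")
    lines = ["M + L <-> C0"]
    for i in range(N):
        lines.append(f"C{i} -> C{i+1}")
    for i in range(1, N + 1):
        lines.append(f"C{i} -> M + L")
    order = ["M", "L"] + [f"C{i}" for i in range(N + 1)]
    return parse_network("\n".join(lines), name=f"kinetic_proofreading({N})",
                         species_order=order)


def erk_rkip() -> Network:
    """ERK signalling with RKIP regulation: K = RKIP, R = activated Raf,
    E = ERK, P = the kinase phosphorylating E, M = the phosphatase acting on
    phosphorylated RKIP (Kp); suffix p marks phosphorylated forms."""
    return parse_network("""
        Kp + M <-> KpM
        KpM -> K + M
        E + P <-> EP
        EP -> Ep + P
        K + R <-> KR
        KR + Ep <-> KREp
        KREp -> R + E + Kp
    """, name="erk_rkip")


def ribosome_flow(n: int = 3) -> Network:
    """Ribosome flow model with n sites: X_i is site occupancy, Y_i vacancy;
    2n species, n+1 reactions, n conservation laws x_i + y_i."""
    if n < 1:
        raise ValueError("n >= 1")
    lines = ["Y1 -> X1"]
    for i in range(1, n):
        lines.append(f"X{i} + Y{i+1} -> Y{i} + X{i+1}")
    lines.append(f"X{n} -> Y{n}")
    return parse_network("\n".join(lines), name=f"ribosome_flow({n})")


def receptor_ptm_open() -> Network:
    """Ligand-receptor-gated PTM cycle: passes every necessary condition but
    no construction method succeeds with the default partition (its global
    stability is an open question)."""
    return parse_network("""
        R + L <-> RL
        S + RL <-> C
        C -> S+ + RL
        S+ -> S
    """, name="receptor_ptm_open")


FIXTURES = {
    "ptm_reduced": ptm_reduced,
    "ptm_full": ptm_full,
    "simple_binding": simple_binding,
    "binding_inflow": binding_inflow,
    "cooperative_binding": cooperative_binding,
    "competitive_binding": competitive_binding,
    "three_body_binding": three_body_binding,
    "transcription": transcription,
    "translation_leak": translation_leak,
    "translation_core": translation_core,
    "enzymatic_motif": enzymatic_motif,
    "enzymatic_cycle": enzymatic_cycle,
    "energy_ptm_basic": energy_ptm_basic,
    "energy_ptm_cycle": energy_ptm_cycle,
    "multisite_distinct": multisite_distinct,
    "processive": processive,
    "all_encompassing": all_encompassing,
    "distributive_double": distributive_double,
    "phosphotransfer_motif": phosphotransfer_motif,
    "phosphotransfer_enzymes": phosphotransfer_enzymes,
    "phosphorelay": phosphorelay,
    "kinetic_proofreading": kinetic_proofreading,
    "erk_rkip": erk_rkip,
    "ribosome_flow": ribosome_flow,
    "receptor_ptm_open": receptor_ptm_open,
}


def fixture(name: str, *args, **kwargs) -> Network:
    """Construct a catalog network by name (parameterized families take the
    family parameter, e.g. ``fixture("ribosome_flow", 4)``)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return FIXTURES[name](*args, **kwargs)


def random_network(rng: np.random.Generator, n_max: int = 6,
                   nu_max: int = 6, max_coeff: int = 2) -> Network:
    """Random small network for property testing: nonnegative integer A, B
    with no reaction empty on both sides."""
    n = int(rng.integers(1, n_max + 1))
    nu = int(rng.integers(1, nu_max + 1))
    while True:
        A = rng.binomial(max_coeff, 0.3, size=(n, nu))
        B = rng.binomial(max_coeff, 0.3, size=(n, nu))
        ok = True
        for j in range(nu):
            if not A[:, j].any() and not B[:, j].any():
                ok = False
                break
        if ok:
            return Network.from_matrices(A, B, name="random")
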
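"""End-to-end network analysis: structural screens, necessary conditions,
certificate construction, and a final attractivity verdict."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _exact
from .core import Network, conservation_analysis, deficiency, m_decomposition
from .rlf import (build_partition, construct_pwl_lp, construct_soc,
                  graphical_maxmin, iterate_convex, construct_pwq_sdp,
                  verify_pwl, MaxMinRLF, PWLCandidate)
from .properties import check_p0, check_robust_nondegeneracy, siphon_analysis

METHOD_ORDER = ("graphical", "soc", "lp", "iterate", "sdp")


@dataclass
class AnalysisReport:
    """Aggregated verdict for one network.

    verdict is "attractive" (a verified Robust Lyapunov Function was
    constructed), "excluded" (a necessary condition for a PWL RLF fails) or
    "inconclusive".
    """
    name: str
    n_species: int
    n_reactions: int
    conservative: bool
    as1: bool
    autocatalytic: bool
    deficiency: int
    is_m_network: bool
    p0: str
    p0_witness: tuple | None
    siphons: list
    critical_siphons: list
    siphon_preclusion: str | None
    nondegenerate: bool | None
    methods: dict = field(default_factory=dict)   # name -> outcome string
    certificates: dict = field(default_factory=dict)
    verdict: str = "inconclusive"

    @property
    def exit_code(self) -> int:
        return {"attractive": 0, "excluded": 1}.get(self.verdict, 2)

    def summary(self) -> str:
        lines = [f"network: {self.name}",
                 f"  species {self.n_species}, reactions {self.n_reactions}, "
                 f"deficiency {self.deficiency}",
                 f"  conservative={self.conservative} AS1={self.as1} "
                 f"autocatalytic={self.autocatalytic} "
                 f"M-network={self.is_m_network}",
                 f"  P0: {self.p0}" +
                 (f" (witness minor on {self.p0_witness})" if self.p0_witness
                  else ""),
                 f"  minimal siphons: {self.siphons or 'none'}"]
        if self.critical_siphons:
            lines.append(f"  critical siphons: {self.critical_siphons}"
                         + (f" -> preclusion clause {self.siphon_preclusion}"
                            if self.siphon_preclusion else ""))
        if self.nondegenerate is not None:
            lines.append(f"  robustly nondegenerate (rho=1): "
                         f"{self.nondegenerate}")
        for m in METHOD_ORDER:
            if m in self.methods:
                lines.append(f"  {m}: {self.methods[m]}")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "certificates"}
        return json.dumps(d, indent=2, default=str)


def _certificate_text(name: str, cert) -> str:
    if isinstance(cert, MaxMinRLF):
        return "V = max R - min R, R = {" + ", ".join(cert.labels) + "}"
    if isinstance(cert, PWLCandidate):
        if cert.xi is not None:
            return ("V = sum_i xi_i |xdot_i|, xi = ("
                    + ", ".join(str(x) for x in cert.xi) + ")")
        return f"PWL ({cert.form}) with {cert.C.shape[0]} rows"
    return type(cert).__name__


def analyze(net: Network, methods=None, all_methods: bool = False,
            sdp: bool = False, iterate_cap: int = 60,
            verify: bool = True, partition=None,
            force_convex: bool = False) -> AnalysisReport:
    """Run the full pipeline on a network.

    Order: structural summary -> necessary-condition screens (siphons, P0,
    non-degeneracy) -> graphical -> SoC -> LP -> iterative -> SDP
    (optional). Construction stops at the first *verified* certificate
    unless ``all_methods``; every certificate is re-verified before being
    reported. Per-stage failures are collected, never fatal.
    """
    cons = conservation_analysis(net)
    defi = deficiency(net)
    md = m_decomposition(net)
    p0 = check_p0(net)
    sip = siphon_analysis(net)
    nd = None
    try:
        nd = check_robust_nondegeneracy(net).nondegenerate
    except Exception:
        pass
    rep = AnalysisReport(
        name=net.name or "network",
        n_species=net.n_species, n_reactions=net.n_reactions,
        conservative=cons.is_conservative, as1=cons.as1,
        autocatalytic=net.is_autocatalytic,
        deficiency=defi.deficiency, is_m_network=md is not None,
        p0=p0.verdict,
        p0_witness=(tuple(net.species[i] for i in p0.witness[0])
                    if p0.witness else None),
        siphons=[tuple(net.species[i] for i in P)
                 for P in sip.minimal_siphons],
        critical_siphons=[tuple(net.species[i] for i in P)
                          for P in sip.critical],
        siphon_preclusion=sip.preclusion,
        nondegenerate=nd)

    excluded = p0.verdict == "fail" or sip.preclusion is not None
    wanted = list(methods) if methods else list(METHOD_ORDER)
    if not sdp and methods is None:
        wanted.remove("sdp")
    part = partition

    def get_part():
        nonlocal part
        if part is None:
            part = build_partition(net)
        return part

    found = False
    for m in wanted:
        if found and not all_methods:
            break
        try:
            if m == "graphical":
                out = graphical_maxmin(net)
                if isinstance(out, MaxMinRLF):
                    ver = verify_pwl(net, out) if verify else None
                    if ver is None or ver.passed:
                        rep.methods[m] = "success: " + _certificate_text(m, out)
                        rep.certificates[m] = out
                        found = True
                    else:
                        rep.methods[m] = f"constructed but failed " \
                                         f"verification: {ver.reason}"
                else:
                    rep.methods[m] = f"conditions not met ({out.reason}: " \
                                     f"{out.detail})"
            elif m == "soc":
                soc_part = get_part()
                if not np.array_equal(_exact.as_float(soc_part.H),
                                      net.Gamma.astype(float)):
                    rep.methods[m] = "skipped (needs H = Gamma)"
                    continue
                out = construct_soc(net, soc_part)
                if out is None:
                    rep.methods[m] = "infeasible (or AS1 fails)"
                else:
                    ver = verify_pwl(net, out) if verify else None
                    if (ver is None or ver.passed) and out.kernel_ok:
                        rep.methods[m] = "success: " + _certificate_text(m, out)
                        rep.certificates[m] = out
                        found = True
                    else:
                        rep.methods[m] = "feasible but degenerate or " \
                                         "unverified"
            elif m == "lp":
                out = construct_pwl_lp(net, get_part(),
                                       force_convex=force_convex)
                if out is None:
                    rep.methods[m] = "infeasible over H = Gamma"
                else:
                    cand, cert = out
                    if not cand.kernel_ok:
                        rep.methods[m] = "feasible but degenerate " \
                                         "(ker C != ker Gamma)"
                    else:
                        ver = verify_pwl(net, cand) if verify else None
                        if ver is None or ver.passed:
                            tag = " [AS1-fallback]" if cert.as1_fallback else ""
                            rep.methods[m] = "success" + tag + ": " + \
                                _certificate_text(m, cand)
                            rep.certificates[m] = cand
                            found = True
                        else:
                            rep.methods[m] = f"failed verification: " \
                                             f"{ver.reason}"
            elif m == "iterate":
                out = iterate_convex(net, n_max=iterate_cap)
                if out is None:
                    rep.methods[m] = f"not converged within {iterate_cap} " \
                                     f"iterations (inconclusive)"
                else:
                    ver = verify_pwl(net, out) if verify else None
                    if ver is None or ver.passed:
                        rep.methods[m] = "success: " + _certificate_text(m, out)
                        rep.certificates[m] = out
                        found = True
                    else:
                        rep.methods[m] = f"terminated but failed " \
                                         f"verification: {ver.reason}"
            elif m == "sdp":
                out = construct_pwq_sdp(net, get_part())
                if out is None:
                    rep.methods[m] = "no PWQ certificate under this relaxation"
                else:
                    rep.methods[m] = f"success: PWQ ({out.label}), residual " \
                                     f"{out.residual:.2e}"
                    rep.certificates[m] = out
                    found = True
        except Exception as e:   # per-stage failures are collected
            rep.methods[m] = f"error: {e}"

    if found:
        rep.verdict = "attractive"
    elif excluded:
        rep.verdict = "excluded"
    else:
        rep.verdict = "inconclusive"
    return rep
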
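"""Independent brute-force re-enumeration of both model families.

Deliberately written from scratch against the model definitions (plain Python
loops over bitmask states), sharing no code with the package's evaluators, so
it can serve as an oracle in equivalence tests.
"""

from __future__ import annotations

import math


def _bin_q(act_pos, rep_pos, act_max, binning, Q):
    if rep_pos > act_max:
        return Q[binning.terminal_bin]
    d = abs(act_pos - rep_pos)
    for lab, (lo, hi) in binning.bins:
        if lo <= d <= hi:
            return Q[lab]
    raise ValueError(f"distance {d} not in any bin")


def brute_fakhouri(construct, params, conc, binning, pairing="two_term", mode="binding"):
    """Total expression by explicit loop over all 2^n bitmask states."""
    sites = construct.sites
    n = len(sites)
    acts = [s for s in sites if s.role == "activator"]
    act_max = max((s.position for s in acts), default=None)
    num = 0.0
    den = 0.0
    for mask in range(2 ** n):
        bound = [sites[i] for i in range(n) if mask >> i & 1]
        w = 1.0
        for s in bound:
            scale = params.A if s.role == "activator" else params.R
            w *= scale * conc[s.factor]
        npairs = 0
        for i in range(n - 1):
            if (
                sites[i].role == "repressor"
                and sites[i + 1].role == "repressor"
                and mask >> i & 1
                and mask >> (i + 1) & 1
            ):
                npairs += 1
        if pairing == "single_term":
            coop = params.C1 ** npairs
        else:
            coop = 1.0
            for k in range(npairs):
                coop *= params.C1 if k == 0 else params.C2
        contrib = 0.0
        breps = [s for s in bound if s.role == "repressor"]
        for a in bound:
            if a.role != "activator":
                continue
            term = 1.0
            for r in breps:
                term *= 1.0 - _bin_q(a.position, r.position, act_max, binning, params.Q)
            contrib += term
        if acts:
            contrib /= len(acts)
        num += w * coop * contrib
        den += w if mode == "post_binding" else w * coop
    return num / den


def brute_zinzen(structure, params, class_tag, dl, twi, sna):
    """Expression at one position by explicit loop over labeled site subsets."""
    if class_tag == "rho-like":
        DT, TT, SS = params.DTr, params.TTr, params.SSr
    elif class_tag == "vnd-like":
        DT, TT, SS = params.DTv, params.TTv, params.SSv
    else:
        raise ValueError(class_tag)
    labels = ["D"] * structure.n_D + ["T"] * structure.n_T + ["S"] * structure.n_S
    n = len(labels)
    num = den = 0.0
    for mask in range(2 ** n):
        nd = nt = ns = 0
        w = 1.0
        for i in range(n):
            if not mask >> i & 1:
                continue
            if labels[i] == "D":
                nd += 1
                w *= params.D * dl
            elif labels[i] == "T":
                nt += 1
                w *= params.T * twi
            else:
                ns += 1
                w *= params.S * sna
        w *= DT ** (nd * nt) * TT ** math.comb(nt, 2) * SS ** math.comb(ns, 2)
        den += w
        if nd + nt >= 1 and ns == 0:
            num += w
    return num / den
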
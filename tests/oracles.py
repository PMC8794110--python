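"""Independent brute-force reference implementations used as test oracles.

These recompute the local scores and all evaluation metrics directly from
raw edge lists, label maps and set algebra, with no shared code paths with
the package (naive loops only), so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math


def brute_lambda(edges, degrees, labels, hop_levels, term_sets, v, c, topology=False):
    """λ(v, c) from raw maps: ln(k_v/hl_v) · |g_v ∩ ∪ g_u| over neighbours
    of v labelled c (GO mode), or the bare log ratio (topology mode)."""
    neighbours = {b for a, b in edges if a == v} | {a for a, b in edges if b == v}
    members = [u for u in neighbours if labels.get(u) == c]
    if not members:
        raise ValueError("no neighbour in community")
    base = math.log(degrees[v] / hop_levels[v])
    if topology:
        return base
    pooled = set()
    for u in members:
        pooled |= set(term_sets.get(u, ()))
    return base * len(set(term_sets.get(v, ())) & pooled)


def brute_mu(edges, labels, v, c):
    """μ(v, c) = (E_in − E_out)/(E_in + E_out) with E_out = links of v to
    every neighbour not labelled c (other labels and unlabelled alike)."""
    neighbours = {b for a, b in edges if a == v} | {a for a, b in edges if b == v}
    if not any(u in labels for u in neighbours):
        raise ValueError("no labelled neighbour")
    e_in = sum(1 for u in neighbours if labels.get(u) == c)
    e_out = len(neighbours) - e_in
    return (e_in - e_out) / (e_in + e_out)


def brute_affinity(p, b):
    inter = len(set(p) & set(b))
    return inter * inter / (len(set(p)) * len(set(b)))


def brute_match_counts(P, B, theta):
    ncp = sum(1 for p in P if any(brute_affinity(p, b) >= theta for b in B))
    ncb = sum(1 for b in B if any(brute_affinity(p, b) >= theta for p in P))
    return ncp, ncb


def brute_sn_ppv_acc(P, B):
    T = [[len(set(b) & set(p)) for p in P] for b in B]
    sn_num = sum(max(row) for row in T)
    sn_den = sum(len(set(b)) for b in B)
    sn = sn_num / sn_den
    total = sum(sum(row) for row in T)
    if total == 0:
        ppv = 0.0
    else:
        ppv = sum(max(T[i][j] for i in range(len(B))) for j in range(len(P))) / total
    return sn, ppv, math.sqrt(sn * ppv)


def brute_report(P, B, theta):
    """Full metric battery, all naive loops."""
    ncp, ncb = brute_match_counts(P, B, theta)
    precision = ncp / len(P)
    recall = ncb / len(B)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    sn, ppv, acc = brute_sn_ppv_acc(P, B)
    return {
        "Ncp": ncp, "Ncb": ncb, "Precision": precision, "Recall": recall,
        "F-measure": f, "Sn": sn, "PPV": ppv, "Acc": acc,
        "Composite Score": precision + sn + acc,
    }
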
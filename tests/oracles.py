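"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's vectorised code paths: trees are
walked node by node with explicit descendant-tip sets, and AUC is counted
pair by pair.
"""
import numpy as np


def _tip_sets(tree):
    """(node, frozenset of descendant tip names) for every non-root node."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset([node.name])
        out.append((node, tips))
    return out


def oracle_unweighted_unifrac(tree, taxon_ids, a, b):
    present_a = {t for t, v in zip(taxon_ids, a) if v > 0}
    present_b = {t for t, v in zip(taxon_ids, b) if v > 0}
    unique = 0.0
    union = 0.0
    for node, tips in _tip_sets(tree):
        length = node.length or 0.0
        hits_a = bool(tips & present_a)
        hits_b = bool(tips & present_b)
        if hits_a or hits_b:
            union += length
            if hits_a != hits_b:
                unique += length
    return unique / union if union else 0.0


def oracle_weighted_unifrac(tree, taxon_ids, a, b, normalized=False):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pa = dict(zip(taxon_ids, a / a.sum()))
    pb = dict(zip(taxon_ids, b / b.sum()))
    raw = 0.0
    mass = 0.0
    for node, tips in _tip_sets(tree):
        length = node.length or 0.0
        flow_a = sum(pa.get(t, 0.0) for t in tips)
        flow_b = sum(pb.get(t, 0.0) for t in tips)
        raw += length * abs(flow_a - flow_b)
        mass += length * (flow_a + flow_b)
    if normalized:
        return raw / mass if mass else 0.0
    return raw


def oracle_auc(scores, labels):
    """Pairwise concordance count: P(case > control) + 0.5 P(tie)."""
    cases = [s for s, l in zip(scores, labels) if l == "case"]
    controls = [s for s, l in zip(scores, labels) if l == "control"]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def oracle_kruskal_h(*groups):
    """Tie-corrected Kruskal–Wallis H from the rank-sum definition."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g, float)
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / correction
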
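"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: exhaustive enumeration and O(n^2)
scans that follow the documented contracts directly, sharing no code with
the package internals they check.
"""
from itertools import combinations


def hypergeom_tail_enum(G, K, n, k):
    """P(X >= k) by enumerating every draw of n positions among G.

    The first K positions are "inside the window"; a draw counts when at
    least k of its positions fall inside.
    """
    hit = total = 0
    for draw in combinations(range(G), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hit += 1
    return hit / total


def tail_count_histogram(G, K, n):
    """counts[j] = number of n-draws among G with exactly j positions < K."""
    counts = [0] * (min(n, K) + 1)
    for draw in combinations(range(G), n):
        counts[sum(1 for x in draw if x < K)] += 1
    return counts


def window_hits_naive(out_gene_ids, ortholog_pairs, target_windows):
    """(window -> k, n) by direct scanning, mirroring the documented contract."""
    partners = {}
    for a, b in ortholog_pairs:
        partners.setdefault(a, set()).add(b)
    all_target_genes = {g for w in target_windows for g in w.gene_ids}
    n = sum(
        1
        for g in out_gene_ids
        if partners.get(g, set()) & all_target_genes
    )
    k = {}
    for w in target_windows:
        wset = set(w.gene_ids)
        c = sum(1 for g in out_gene_ids if partners.get(g, set()) & wset)
        if c:
            k[w] = c
    return k, n


def detect_anchors_naive(outgroup, target, orthologs, cfg):
    """Anchor (query window, frozenset of target windows) set by direct scan."""
    from paralogon.synteny import build_windows

    found = set()
    for size in cfg.window_sizes:
        step = cfg.step_for(size)
        target_windows = build_windows(target, size, step)
        min_k = cfg.scaled_min_hits(size)
        for w_out in build_windows(outgroup, size, step):
            k, _ = window_hits_naive(w_out.gene_ids, orthologs, target_windows)
            cands = sorted(
                ((w, c) for w, c in k.items() if c >= min_k),
                key=lambda t: (-t[1], t[0].chromosome, t[0].start_rank),
            )
            chosen = []
            for w, c in cands:
                if all(not w.overlaps(x) for x, _ in chosen):
                    chosen.append((w, c))
            if len(chosen) >= 2:
                found.add((size, w_out, frozenset(w for w, _ in chosen)))
    return found
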
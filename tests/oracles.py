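"""Independent oracles used to check the package implementations.

These deliberately avoid the package's own algorithms: the alignment
oracle enumerates every global alignment recursively; the tree-distance
oracle goes through dendropy's bipartition machinery; the cleavage-site
oracle scans every length-2 substring.
"""

from __future__ import annotations

import dendropy
from dendropy.calculate import treecompare

NEG = float("-inf")
_DYADS = {"KR", "RK", "RR", "KK"}


def naive_dyad_scan(seq: str) -> list:
    """Every position whose length-2 substring is a basic dyad."""
    return [
        (i, seq[i : i + 2])
        for i in range(len(seq) - 1)
        if seq[i : i + 2] in _DYADS
    ]


def brute_force_align_score(a: str, b: str, params, table) -> float:
    """Best global-alignment score by exhaustive enumeration.

    Walks every monotone alignment of ``a`` and ``b``, scoring columns
    incrementally: residue pairs score substitution + bonus; a gap run
    costs open + extend*(L-1) internally and terminal_gap per residue
    when it touches either end of the alignment.
    """
    m, n = len(a), len(b)
    op, ex, tg, bonus = (
        params.gap_open,
        params.gap_extend,
        params.terminal_gap,
        params.bonus,
    )
    best = NEG

    # stack of (i, j, state, run_len, run_is_leading, score)
    stack = [(0, 0, None, 0, False, 0.0)]
    while stack:
        i, j, state, run_len, leading, score = stack.pop()
        if i == m and j == n:
            if state in ("GA", "GB") and not leading:
                # the final run touches the end: terminal pricing
                score += (op + ex * (run_len - 1)) - tg * run_len
            if score > best:
                best = score
            continue
        if i < m and j < n:
            stack.append(
                (i + 1, j + 1, "M", 0, False, score + table[(a[i], b[j])] + bonus)
            )
        if i < m:  # column (a[i], -)
            if state == "GB":
                inc = tg if leading else ex
                stack.append((i + 1, j, "GB", run_len + 1, leading, score - inc))
            else:
                lead = state is None
                inc = tg if lead else op
                stack.append((i + 1, j, "GB", 1, lead, score - inc))
        if j < n:  # column (-, b[j])
            if state == "GA":
                inc = tg if leading else ex
                stack.append((i, j + 1, "GA", run_len + 1, leading, score - inc))
            else:
                lead = state is None
                inc = tg if lead else op
                stack.append((i, j + 1, "GA", 1, lead, score - inc))
    return best


def dendropy_rf(newick1: str, newick2: str) -> int:
    """Unrooted Robinson-Foulds distance via dendropy bipartitions."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=newick1, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    t2 = dendropy.Tree.get(
        data=newick2, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    for t in (t1, t2):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(t1, t2))
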
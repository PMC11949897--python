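"""Independent brute-force reference implementations used as test oracles.

Everything here is written for clarity, not speed: double loops and textbook
formulas only, sharing no code with the package under test.
"""

import numpy as np


def nodf_oracle(m: np.ndarray) -> float:
    """All-pairs NODF: strict decreasing-fill rule, equal totals score 0."""
    m = np.asarray(m)
    scores = []
    for axis_matrix in (m, m.T):
        n = axis_matrix.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                ti = axis_matrix[i].sum()
                tj = axis_matrix[j].sum()
                if not (ti > tj > 0):
                    continue
                overlap = int((axis_matrix[i] & axis_matrix[j]).sum())
                scores.append(100.0 * overlap / tj)
        # pairs that never satisfied the strict rule count as zeros
    n_pairs = (m.shape[0] * (m.shape[0] - 1) // 2
               + m.shape[1] * (m.shape[1] - 1) // 2)
    return sum(scores) / n_pairs


def kendall_tau_b_oracle(x, y) -> float | None:
    """Exhaustive concordant/discordant pair counting with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    concordant = discordant = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    denom = np.sqrt((concordant + discordant + tie_x)
                    * (concordant + discordant + tie_y))
    if denom == 0:
        return None
    return (concordant - discordant) / denom


def bh_oracle(p) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, p[idx] * m / (rank_from_top + 1))
        adj[idx] = running
    return adj


def holm_oracle(p) -> np.ndarray:
    """Textbook Holm-Bonferroni step-down with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, p[idx] * (m - rank)))
        adj[idx] = running
    return adj


def zi_pi_oracle(graph, assignment):
    """Per-node double-loop Zi and Pi over an unweighted networkx graph."""
    out = {}
    for node in graph.nodes:
        k = graph.degree(node)
        if k == 0:
            out[node] = (0.0, 0.0)
            continue
        own = assignment[node]
        members = [n for n in graph.nodes if assignment[n] == own]
        kappas = []
        for member in members:
            kappa = 0
            for nb in graph.neighbors(member):
                if assignment[nb] == own:
                    kappa += 1
            kappas.append(kappa)
        mean = float(np.mean(kappas))
        sd = float(np.std(kappas))
        own_kappa = sum(
            1 for nb in graph.neighbors(node) if assignment[nb] == own
        )
        zi = (own_kappa - mean) / sd if sd > 0 else 0.0
        per_module = {}
        for nb in graph.neighbors(node):
            per_module[assignment[nb]] = per_module.get(assignment[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        out[node] = (zi, pi)
    return out


def semiglobal_score_oracle(query: str, ref: str, match=1.0, mismatch=-1.0,
                            gap_open=-2.0, gap_extend=-1.0) -> float:
    """Gotoh affine-gap DP with free terminal gaps on both sequences.

    A gap of length L costs |gap_open| + L * |gap_extend|, matching the
    package's scoring convention; ambiguity codes are scored as a match when
    their base sets intersect.
    """
    from mycohub.php import _IUPAC_SETS

    def sub(a, b):
        return match if set(_IUPAC_SETS[a]) & set(_IUPAC_SETS[b]) else mismatch

    n, m = len(query), len(ref)
    neg = -np.inf
    open_cost = gap_open + gap_extend  # first gapped column
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in ref (query consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in query (ref consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # terminal gap: free
    for j in range(1, m + 1):
        Y[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(query[i - 1], ref[j - 1])
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] + open_cost, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + open_cost, Y[i, j - 1] + gap_extend)
    # free terminal gaps: best over the last row and column of match states
    best = neg
    for i in range(n + 1):
        best = max(best, M[i, m], X[i, m], Y[i, m])
    for j in range(m + 1):
        best = max(best, M[n, j], X[n, j], Y[n, j])
    return float(best)


def permanova_f_oracle(d: np.ndarray, labels) -> float:
    """Pseudo-F from explicit within/between sums of squared distances."""
    labels = np.asarray(labels)
    n = d.shape[0]
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    a_groups = len(np.unique(labels))
    return ((ss_total - ss_within) / (a_groups - 1)) / (
        ss_within / (n - a_groups)
    )
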
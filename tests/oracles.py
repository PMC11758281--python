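"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — threshold
enumeration, GF(2) linear algebra, explicit matchings — so that it shares no
code path with the package implementations it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

EMPTY = -1


# ---------------------------------------------------------------------------
# Sublevel-set persistence of a 1-D signal by threshold enumeration
# ---------------------------------------------------------------------------


def sublevel_barcode(series) -> tuple[list[tuple[float, float]], float]:
    """Dim-0 bars of the sublevel filtration, by recomputing the connected
    components of {t : f(t) <= s} at every threshold s.

    Returns (finite bars, essential birth).  Elder rule: at a merge the
    component whose minimum is larger dies (ties: the later minimum dies).
    """
    x = [float(v) for v in series]
    y = [x[0]]
    for v in x[1:]:  # collapse plateaus
        if v != y[-1]:
            y.append(v)
    levels = sorted(set(y))
    # components tracked as (member set, birth value, birth index)
    comps: list[tuple[set, float, int]] = []
    bars: list[tuple[float, float]] = []
    for s in levels:
        active = [i for i, v in enumerate(y) if v <= s]
        runs: list[list[int]] = []
        for i in active:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        new_comps = []
        for run in runs:
            members = set(run)
            touching = [c for c in comps if c[0] & members]
            if not touching:
                argmin = min(run, key=lambda i: (y[i], i))
                new_comps.append((members, y[argmin], argmin))
            else:
                elder = min(touching, key=lambda c: (c[1], c[2]))
                for c in touching:
                    if c is not elder and s > c[1]:
                        bars.append((c[1], s))
                new_comps.append((members, elder[1], elder[2]))
        comps = new_comps
    assert len(comps) == 1
    return sorted(bars), comps[0][1]


# ---------------------------------------------------------------------------
# GF(2) linear algebra
# ---------------------------------------------------------------------------


def gf2_rank(rows: list[int]) -> int:
    rows = [int(r) for r in rows]
    rank = 0
    while rows:
        row = rows.pop()
        if row == 0:
            continue
        rank += 1
        low = row.bit_length() - 1
        rows = [r ^ row if (r >> low) & 1 else r for r in rows]
    return rank


def gf2_nullspace(columns: list[int], n_cols: int) -> list[int]:
    """Kernel basis of the matrix whose j-th column is the bitmask
    ``columns[j]`` (over rows); kernel vectors are bitmasks over columns."""
    pivots: dict[int, tuple[int, int]] = {}
    null = []
    for j in range(n_cols):
        col = int(columns[j])
        combo = 1 << j
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                pc, pcombo = pivots[low]
                col ^= pc
                combo ^= pcombo
            else:
                pivots[low] = (col, combo)
                break
        if col == 0:
            null.append(combo)
    return null


# ---------------------------------------------------------------------------
# Vietoris-Rips barcodes by persistent-Betti enumeration
# ---------------------------------------------------------------------------


def vr_barcode_oracle(dist: np.ndarray):
    """Brute-force VR persistence (vertices, edges, triangles) of a small
    distance matrix.

    Returns (dim-0 finite death multiset, dim-1 finite bar multiset,
    dim-1 essential birth multiset).  Dim-0 deaths come from component
    counts at each threshold; dim-1 bars from the persistent Betti numbers
    beta(a, b) = rank(Z1(K_a) + B1(K_b)) - rank(B1(K_b)) via the standard
    inclusion-exclusion over threshold indices.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    edges = [(i, j, d[i, j]) for i in range(n) for j in range(i + 1, n)]
    edge_pos = {(i, j): k for k, (i, j, _) in enumerate(edges)}
    triangles = [
        (a, b, c, max(d[a, b], d[a, c], d[b, c]))
        for a in range(n) for b in range(a + 1, n) for c in range(b + 1, n)
    ]
    levels = sorted({w for _, _, w in edges})

    # --- dim 0 from component counts -----------------------------------
    deaths0: list[float] = []
    prev_count = n
    for s in levels:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from([(i, j) for i, j, w in edges if w <= s])
        count = nx.number_connected_components(g)
        if s > 0.0:
            deaths0.extend([s] * (prev_count - count))
        prev_count = count

    # --- dim 1 from persistent Betti numbers ---------------------------
    def z1_basis(s: float) -> list[int]:
        present = [(i, j, k) for k, (i, j, w) in enumerate(edges) if w <= s]
        columns = [(1 << i) | (1 << j) for i, j, _ in present]
        local_null = gf2_nullspace(columns, len(columns))
        out = []
        for vec in local_null:  # re-index to global edge positions
            mask = 0
            for local, (_, _, k) in enumerate(present):
                if (vec >> local) & 1:
                    mask |= 1 << k
            out.append(mask)
        return out

    def b1_cols(s: float) -> list[int]:
        out = []
        for a, b, c, w in triangles:
            if w <= s:
                out.append(
                    (1 << edge_pos[(a, b)]) | (1 << edge_pos[(a, c)]) | (1 << edge_pos[(b, c)])
                )
        return out

    m = len(levels)

    def beta(a: int, b: int) -> int:
        if a < 0:
            return 0
        z = z1_basis(levels[a])
        bb = b1_cols(levels[b])
        return gf2_rank(z + bb) - gf2_rank(list(bb))

    bars1: list[tuple[float, float]] = []
    essential1: list[float] = []
    for a in range(m):
        for b in range(a + 1, m):
            mu = (beta(a, b - 1) - beta(a, b)) - (beta(a - 1, b - 1) - beta(a - 1, b))
            bars1.extend([(levels[a], levels[b])] * mu)
        mu_inf = beta(a, m - 1) - beta(a - 1, m - 1)
        essential1.extend([levels[a]] * mu_inf)
    return sorted(deaths0), sorted(bars1), sorted(essential1)


# ---------------------------------------------------------------------------
# Bottleneck distance for small dim-0 diagrams
# ---------------------------------------------------------------------------


def bottleneck_distance(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Exact bottleneck distance between two small finite diagrams, allowing
    matches to the diagonal, by binary search over candidate costs with
    Hopcroft-Karp feasibility checks."""
    A = [tuple(map(float, p)) for p in np.atleast_2d(points_a)] if len(points_a) else []
    B = [tuple(map(float, p)) for p in np.atleast_2d(points_b)] if len(points_b) else []

    def linf(p, q):
        return max(abs(p[0] - q[0]), abs(p[1] - q[1]))

    def diag(p):
        return (p[1] - p[0]) / 2.0

    candidates = sorted(
        {linf(a, b) for a in A for b in B} | {diag(a) for a in A} | {diag(b) for b in B} | {0.0}
    )

    def feasible(eps: float) -> bool:
        g = nx.Graph()
        left = [("a", i) for i in range(len(A))] + [("db", j) for j in range(len(B))]
        right = [("b", j) for j in range(len(B))] + [("da", i) for i in range(len(A))]
        g.add_nodes_from(left, bipartite=0)
        g.add_nodes_from(right, bipartite=1)
        for i, a in enumerate(A):
            for j, b in enumerate(B):
                if linf(a, b) <= eps:
                    g.add_edge(("a", i), ("b", j))
            if diag(a) <= eps:
                g.add_edge(("a", i), ("da", i))
        for j, b in enumerate(B):
            if diag(b) <= eps:
                g.add_edge(("db", j), ("b", j))
        for i in range(len(A)):
            for j in range(len(B)):
                g.add_edge(("db", j), ("da", i))
        matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=left) if g.edges else {}
        return sum(1 for k in matching if k in set(left)) == len(left)

    for eps in candidates:
        if feasible(eps):
            return eps
    return math.inf


# ---------------------------------------------------------------------------
# Recall-scoring oracle (counting-based re-derivation)
# ---------------------------------------------------------------------------


def score_sequence_oracle(stimuli, answer: str) -> list[float]:
    """Score every stimulus of a sequence by explicit counting.

    Same documented conventions as the package, re-derived independently:
    Target inconclusive iff its digit also occurs among digit Distractors
    and is reported; otherwise the r-th same-digit Target occurrence pairs
    with the r-th report of that digit, scoring 0.2 per position of
    displacement (saturating at 1), or 1 if unreported.  Distractors score
    by comparing report counts with Target / Target+Distractor counts;
    empty circles are inconclusive.
    """
    targets = [d for d, k in stimuli if k == "Target"]
    distractor_digits = [d for d, k in stimuli if k == "Distractor" and d != EMPTY]
    out: list[float] = []
    rank = 0
    for digit, kind in stimuli:
        if kind == "Target":
            rank += 1
            reported = [i for i, ch in enumerate(answer, start=1) if ch == str(digit)]
            if distractor_digits.count(digit) > 0 and reported:
                out.append(-1.0)
                continue
            occurrence = targets[:rank].count(digit) - 1
            if occurrence >= len(reported):
                out.append(1.0)
            else:
                shift = abs(reported[occurrence] - rank)
                out.append(0.0 if shift == 0 else min(0.2 * shift, 1.0))
        else:
            if digit == EMPTY:
                out.append(-1.0)
                continue
            c_answer = answer.count(str(digit))
            c_target = targets.count(digit)
            c_total = c_target + distractor_digits.count(digit)
            if c_answer <= c_target:
                out.append(0.0)
            elif c_answer >= c_total:
                out.append(1.0)
            else:
                out.append(-1.0)
    return out
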
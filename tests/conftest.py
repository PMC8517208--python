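"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths (and where possible the
libraries) used by the package: betweenness by explicit shortest-path
enumeration, community detection by exhaustive partition search, Manders by a
double pixel loop, BH by the textbook step-up recursion, the hypergeometric
tail by a combinatorial sum.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from epitrack.silac_screen import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


# ---------------------------------------------------------------------------
# Graph oracles
# ---------------------------------------------------------------------------

def enumerate_edge_betweenness(nodes, edges):
    """Edge betweenness by explicit enumeration of all shortest paths.

    Pure-python BFS path enumeration; unordered node pairs counted once,
    equal split across multiple shortest paths.
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        # BFS layers from s, then recursive path reconstruction
        from collections import deque
        dist = {s: 0}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    dq.append(w)
        if t not in dist:
            return []
        paths = []

        def back(path):
            head = path[0]
            if head == s:
                paths.append(list(path))
                return
            for w in adj[head]:
                if dist.get(w, -1) == dist[head] - 1:
                    back([w] + path)

        back([t])
        return paths

    eb = {tuple(sorted(e)): 0.0 for e in edges}
    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for u, v in zip(path, path[1:]):
                    eb[tuple(sorted((u, v)))] += w
    return eb


def modularity_oracle(nodes, edges, communities):
    """Direct Q = sum_c [e_c/m - (d_c/2m)^2] from raw counts."""
    m = len(edges)
    if m == 0:
        return 0.0
    cids = set(communities.values())
    q = 0.0
    for c in cids:
        members = {n for n in nodes if communities[n] == c}
        e_c = sum(1 for u, v in edges if u in members and v in members)
        d_c = sum(1 for u, v in edges for x in (u, v) if x in members)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def iter_set_partitions(items):
    """All set partitions of ``items`` (restricted-growth strings)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return

    def rec(i, groups):
        if i == n:
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([items[i]])
        yield from rec(i + 1, groups)
        groups.pop()

    yield from rec(0, [])


def brute_force_best_modularity(nodes, edges):
    """Maximum modularity over every partition (feasible for <= 8 nodes)."""
    best_q, best_part = -np.inf, None
    for groups in iter_set_partitions(sorted(nodes)):
        comm = {n: i for i, g in enumerate(groups) for n in g}
        q = modularity_oracle(nodes, edges, comm)
        if q > best_q:
            best_q, best_part = q, groups
    return best_q, best_part


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(k, n, K, N):
    """P(X >= k) by direct combinatorial summation."""
    denom = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(n, K) + 1)) / denom


def bh_step_up_oracle(p_values):
    """Textbook Benjamini-Hochberg step-up, preserving input order."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def manders_double_loop(a, b, ta, tb):
    """M1/M2 by an explicit double loop over pixels."""
    num1 = den1 = num2 = den2 = 0.0
    h, w = a.shape
    for i in range(h):
        for j in range(w):
            av, bv = float(a[i, j]), float(b[i, j])
            if av > ta:
                den1 += av
                if bv > tb:
                    num1 += av
            if bv > tb:
                den2 += bv
                if av > ta:
                    num2 += bv
    return num1 / den1, num2 / den2


def two_sample_pooled_t_oracle(x, y):
    """Textbook pooled two-sided t-test: statistic, df, p via the t tail."""
    from scipy.special import betainc

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx_, ny_ = len(x), len(y)
    sp2 = (((nx_ - 1) * x.var(ddof=1) + (ny_ - 1) * y.var(ddof=1))
           / (nx_ + ny_ - 2))
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx_ + 1 / ny_))
    df = nx_ + ny_ - 2
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, df, p


def one_sample_t_upper_oracle(x):
    """Textbook one-sample upper-tail t against 0."""
    from scipy.special import betainc

    x = np.asarray(x, float)
    n = len(x)
    t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
    df = n - 1
    tail_two = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, (tail_two / 2.0 if t >= 0 else 1.0 - tail_two / 2.0)


def random_small_graph(rng, n_max=10, p=0.4):
    n = rng.integers(3, n_max + 1)
    nodes = [f"n{i}" for i in range(n)]
    edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
             if rng.random() < p]
    return nodes, edges
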
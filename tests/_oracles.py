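"""Independent brute-force oracles used by the property tests.

Deliberately separate code paths from the implementations they check:
random-network generation plus naive summation for inference, and a
binomial-product enumeration for exact contingency tests.
"""

import itertools
import math

import numpy as np

from suidbayes.bayesnet import BayesNet, Cpt, NetworkSpec


def random_network(rng, max_nodes=8, max_states=3, edge_prob=0.3):
    """A random DAG with Dirichlet CPT rows."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    states = {nm: tuple(f"s{j}" for j in range(int(rng.integers(2, max_states + 1))))
              for nm in names}
    edges = tuple((names[i], names[j]) for i in range(n) for j in range(i + 1, n)
                  if rng.random() < edge_prob)
    spec = NetworkSpec(tuple((nm, states[nm]) for nm in names), edges)
    cpts = {}
    for nm in names:
        parents = spec.parents(nm)
        pstates = tuple(spec.states(p) for p in parents)
        k = len(states[nm])
        n_rows = int(np.prod([len(ps) for ps in pstates])) if pstates else 1
        vals = rng.dirichlet(np.ones(k), size=n_rows)
        shape = tuple(len(ps) for ps in pstates) + (k,)
        cpts[nm] = Cpt(nm, parents, states[nm], pstates, vals.reshape(shape))
    return BayesNet(spec, cpts)


def random_evidence(net, rng, observe_prob=0.4):
    """Pick a query node and random evidence on a subset of the others."""
    names = list(net.spec.node_names)
    query = names[int(rng.integers(len(names)))]
    evidence = {}
    for nm in names:
        if nm != query and rng.random() < observe_prob:
            states = net.spec.states(nm)
            evidence[nm] = states[int(rng.integers(len(states)))]
    return query, evidence


def fixed_margin_tables(row_sums, col_sums):
    """All tables with the given margins (independent of the package's
    recursive enumerator: direct product over free cells)."""
    r, c = len(row_sums), len(col_sums)
    free_ranges = [range(min(row_sums[i], col_sums[j]) + 1)
                   for i in range(r - 1) for j in range(c - 1)]
    for combo in itertools.product(*free_ranges):
        t = np.zeros((r, c), dtype=int)
        it = iter(combo)
        for i in range(r - 1):
            for j in range(c - 1):
                t[i, j] = next(it)
        ok = True
        for i in range(r - 1):
            t[i, c - 1] = row_sums[i] - t[i, : c - 1].sum()
            ok &= t[i, c - 1] >= 0
        for j in range(c):
            t[r - 1, j] = col_sums[j] - t[: r - 1, j].sum()
            ok &= t[r - 1, j] >= 0
        if ok:
            yield t


def table_prob(t):
    """Fixed-margin null probability via a product of column binomials."""
    t = np.asarray(t)
    n = int(t.sum())
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    # P = prod_j multinomial(col_j; t[:, j]) / multinomial(n; row_sums)
    logp = 0.0
    for j, cs in enumerate(col_sums):
        logp += math.lgamma(cs + 1) - sum(math.lgamma(x + 1) for x in t[:, j])
    logp -= math.lgamma(n + 1) - sum(math.lgamma(r + 1) for r in row_sums)
    return math.exp(logp)


def brute_force_exact_p(table):
    """Two-sided exact p by the point-probability rule, via full enumeration."""
    t = np.asarray(table)
    p_obs = table_prob(t)
    total = 0.0
    for cand in fixed_margin_tables(tuple(t.sum(axis=1)), tuple(t.sum(axis=0))):
        p = table_prob(cand)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
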
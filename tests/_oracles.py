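"""Independent brute-force oracles shared across test modules."""

import math

import numpy as np
from scipy import integrate
from scipy import stats as sps


def studentized_range_cdf(q, k, df):
    """CDF of the studentized range by direct numerical integration,
    conditioning on the pooled-SD scale factor s = sqrt(chi2_df/df)."""

    def inner(s):
        def leadterm(z):
            return sps.norm.pdf(z) * (sps.norm.cdf(z + q * s) - sps.norm.cdf(z)) ** (k - 1)
        val, _ = integrate.quad(leadterm, -8, 8, limit=200)
        return k * val

    def outer(s):
        chi_pdf = (2 * (df / 2) ** (df / 2) / math.gamma(df / 2)
                   * s ** (df - 1) * np.exp(-df * s**2 / 2))
        return chi_pdf * inner(s)

    val, _ = integrate.quad(outer, 1e-6, 4, limit=200)
    return val


def segment_sum(vertices):
    """Per-segment hypotenuse summation over an ordered vertex list."""
    return sum(((r1 - r0) ** 2 + (c1 - c0) ** 2) ** 0.5
               for (r0, c0), (r1, c1) in zip(vertices[:-1], vertices[1:]))


def root_leaf_path_lengths(tree):
    """Exhaustive DFS enumeration of every root-to-leaf cumulative length."""
    g, root = tree.graph, tree.soma_anchor
    out = []

    def dfs(node, parent, acc):
        nbrs = [n for n in g[node] if n != parent]
        if not nbrs:
            out.append(acc)
        for n in nbrs:
            dfs(n, node, acc + g[node][n]["weight"])

    dfs(root, None, 0.0)
    return out
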
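"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and stdlib statistics so it
shares no code path with the package: the package is vectorised over numpy,
these oracles are not.
"""

import math
import statistics


def pairwise_v_oracle(q, j, k):
    """SD (n-1) of log2 quantity ratios of genes j, k; q is a nested list."""
    ratios = [math.log2(q[j][s] / q[k][s]) for s in range(len(q[0]))]
    return statistics.stdev(ratios)


def m_values_oracle(q):
    """Per-gene M by the defining double loop."""
    G = len(q)
    out = []
    for j in range(G):
        total = 0.0
        for k in range(G):
            if k != j:
                total += pairwise_v_oracle(q, j, k)
        out.append(total / (G - 1))
    return out


def nf_oracle(q, gene_indices):
    """Per-sample geometric mean of the chosen genes' quantities."""
    S = len(q[0])
    out = []
    for s in range(S):
        prod = 1.0
        for i in gene_indices:
            prod *= q[i][s]
        out.append(prod ** (1.0 / len(gene_indices)))
    return out


def v_series_oracle(q, order):
    """V_n/n+1 via explicit normalization-factor vectors; order best-first."""
    series = []
    for n in range(2, len(order)):
        nf_n = nf_oracle(q, order[:n])
        nf_n1 = nf_oracle(q, order[: n + 1])
        ratios = [math.log2(a / b) for a, b in zip(nf_n, nf_n1)]
        series.append(statistics.stdev(ratios))
    return series


def two_way_residuals_oracle(y):
    """Four-loop two-way centering of one genes x samples block."""
    G, S = len(y), len(y[0])
    row = [sum(y[i][j] for j in range(S)) / S for i in range(G)]
    col = [sum(y[i][j] for i in range(G)) / G for j in range(S)]
    grand = sum(row) / G
    R = [[0.0] * S for _ in range(G)]
    for i in range(G):
        for j in range(S):
            R[i][j] = y[i][j] - row[i] - col[j] + grand
    return R


def percentile_oracle(values, p):
    """Linear-interpolation percentile between order statistics."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    h = (len(xs) - 1) * p / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return xs[lo]
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
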
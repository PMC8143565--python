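"""Partition quality and agreement measures.

Modularity Q compares the fraction of edges inside communities with the
expectation under a degree-preserving random null model:

    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(C_i, C_j)
      = sum_c [ l_c/m - (d_c/2m)^2 ]

with ``l_c`` the number of edges internal to community c and ``d_c`` the
total degree of its members.

NMI is mutual information normalized by the mean of the two partition
entropies (sum convention); AMI subtracts the expected mutual information
under the hypergeometric permutation model so that unrelated partitions
score 0 on average.  The stability statistic is the Shannon entropy (bits)
of the multiset of metric values observed across repeated runs: 0 iff the
algorithm returns the same value every time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .graph_core import Network, Partition


def _check_cover(net: Network, part: Partition) -> None:
    missing = [u for u in net.node_ids if u not in part]
    if missing:
        raise ValueError(f"partition missing {len(missing)} node(s), e.g. {missing[:5]}")


def modularity(net: Network, part: Partition) -> float:
    """Newman-Girvan modularity of ``part`` on ``net`` (unweighted)."""
    if net.m == 0:
        raise ValueError("modularity is undefined for a graph with no edges")
    _check_cover(net, part)
    labels = [part[u] for u in net.node_ids]
    m = net.m
    internal: Counter = Counter()
    deg_tot: Counter = Counter()
    for i, li in enumerate(labels):
        deg_tot[li] += net.degrees[i]
        for j in net.adj[i]:
            if i < j and labels[j] == li:
                internal[li] += 1
    return sum(
        internal[c] / m - (deg_tot[c] / (2 * m)) ** 2 for c in deg_tot
    )


@dataclass(frozen=True)
class ContingencyTable:
    """Confusion counts N_ij between the communities of two partitions."""

    counts: np.ndarray          # shape (C_A, C_B), integer
    row_labels: tuple           # community labels of partition A, sorted
    col_labels: tuple           # community labels of partition B, sorted

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _sorted_labels(values) -> list:
    labels = set(values)
    try:
        return sorted(labels)
    except TypeError:
        return sorted(labels, key=repr)


def contingency(a: Partition, b: Partition) -> ContingencyTable:
    """Build the N_ij contingency table of two partitions of the same nodes."""
    sa, sb = set(a), set(b)
    if sa != sb:
        diff = sorted(map(repr, sa ^ sb))[:6]
        raise ValueError(f"partitions cover different node sets; differ on {diff}")
    if not a:
        raise ValueError("empty partitions")
    rows = _sorted_labels(a.values())
    cols = _sorted_labels(b.values())
    ri = {l: i for i, l in enumerate(rows)}
    ci = {l: i for i, l in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for node in a:
        counts[ri[a[node]], ci[b[node]]] += 1
    return ContingencyTable(counts=counts, row_labels=tuple(rows), col_labels=tuple(cols))


def _entropy(sums: np.ndarray, n: int) -> float:
    p = sums[sums > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(tab: ContingencyTable) -> float:
    n = tab.total
    nz = tab.counts[tab.counts > 0].astype(float)
    outer = np.outer(tab.row_sums, tab.col_sums)[tab.counts > 0].astype(float)
    return float((nz / n * (np.log(nz * n) - np.log(outer))).sum())


def nmi(a: Partition, b: Partition) -> float:
    """Normalized mutual information of two partitions, in [0, 1].

    Single-community degenerate case (both entropies zero): 1 if the
    partitions are identical up to relabeling, else 0.
    """
    tab = contingency(a, b)
    n = tab.total
    ha, hb = _entropy(tab.row_sums, n), _entropy(tab.col_sums, n)
    if ha + hb == 0.0:
        return 1.0  # both single-community over the same nodes: identical
    mi = _mutual_information(tab)
    return float(min(1.0, 2.0 * mi / (ha + hb)))


def expected_mutual_information(tab: ContingencyTable) -> float:
    """E[MI] over random contingency tables with the given margins.

    Hypergeometric permutation model: the expectation runs, for every
    (row, column) pair, over all feasible cell counts, weighting each by
    its hypergeometric probability (computed in log space).
    """
    n = tab.total
    emi = 0.0
    log_n = np.log(n)
    for ai in tab.row_sums:
        for bj in tab.col_sums:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term1 = nij / n * (np.log(nij) + log_n - np.log(ai) - np.log(bj))
            log_p = (
                gammaln(ai + 1) + gammaln(bj + 1)
                + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                - gammaln(n + 1) - gammaln(nij + 1)
                - gammaln(ai - nij + 1) - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float((term1 * np.exp(log_p)).sum())
    return emi


def ami(a: Partition, b: Partition) -> float:
    """Adjusted mutual information (arithmetic-mean normalization), in [-1, 1]."""
    tab = contingency(a, b)
    n = tab.total
    ha, hb = _entropy(tab.row_sums, n), _entropy(tab.col_sums, n)
    if ha == 0.0 and hb == 0.0:
        return 1.0  # both trivial and identical
    mi = _mutual_information(tab)
    emi = expected_mutual_information(tab)
    denom = 0.5 * (ha + hb) - emi
    if denom == 0.0:
        return 0.0
    return float(np.clip((mi - emi) / denom, -1.0, 1.0))


def community_count(part: Partition) -> int:
    """Number of distinct community labels in use."""
    if not part:
        raise ValueError("empty partition")
    return len(set(part.values()))


def sequence_entropy(values, precision: int = 3) -> float:
    """Shannon entropy (bits) of a metric sequence, after rounding.

    Values are rounded to ``precision`` decimals, the empirical distribution
    over distinct rounded values is formed, and ``-sum p log2 p`` returned.
    A perfectly stable (constant) sequence has entropy 0.
    """
    values = list(values)
    if not values:
        raise ValueError("empty sequence")
    if precision < 0:
        raise ValueError("precision must be >= 0")
    counts = Counter(round(float(v), precision) for v in values)
    n = len(values)
    return float(-sum(c / n * np.log2(c / n) for c in counts.values())) + 0.0
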
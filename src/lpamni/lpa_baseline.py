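"""The original stochastic label propagation algorithm (LPA).

Every node starts with a unique label.  Sweeps visit all nodes in a fresh
uniformly-random order; each node adopts the label held by the maximum
number of its neighbors, breaking ties uniformly at random (the node's own
label is not added to the tally).  The run stops when every node's label is
among its neighbors' most frequent labels, or after ``max_sweeps`` sweeps.

Randomness enters through the visit order, the tie-breaks and nothing
else; a single seeded generator drives both, so runs are reproducible
bit-for-bit given the seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .graph_core import Network, NodeId, Partition


@dataclass(frozen=True)
class LPAResult:
    partition: dict[NodeId, NodeId]
    sweeps: int
    converged: bool


def run_lpa(net: Network, seed: int, max_sweeps: int = 100) -> LPAResult:
    """Run asynchronous label propagation with the given RNG seed.

    Initial labels are the node ids themselves; isolated nodes keep their
    own label.  ``converged`` is False when the sweep cap was reached first.
    """
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    n = net.n
    adj = net.adj
    label = list(range(n))
    order = np.arange(n)
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        sweeps += 1
        rng.shuffle(order)
        for u in order:
            nbrs = adj[u]
            if not nbrs:
                continue
            counts = Counter(label[v] for v in nbrs)
            top = max(counts.values())
            tied = [l for l, c in counts.items() if c == top]
            if len(tied) == 1:
                label[u] = tied[0]
            else:
                label[u] = tied[rng.integers(len(tied))]
        if _is_stable(adj, label):
            converged = True
            break
    part = {net.node_ids[i]: net.node_ids[label[i]] for i in range(n)}
    return LPAResult(partition=part, sweeps=sweeps, converged=converged)


def _is_stable(adj, label) -> bool:
    """Every node's label is among the most frequent labels of its neighbors."""
    for u, nbrs in enumerate(adj):
        if not nbrs:
            continue
        counts = Counter(label[v] for v in nbrs)
        if counts.get(label[u], 0) != max(counts.values()):
            return False
    return True


def stability_run(
    net: Network,
    runs: int,
    truth: Partition | None = None,
    base_seed: int = 0,
    algorithm: str = "lpa",
    max_sweeps: int = 100,
) -> dict[str, list[float]]:
    """Repeat an algorithm and collect per-run metric sequences.

    ``algorithm`` is ``"lpa"`` (seeds ``base_seed .. base_seed+runs-1``) or
    ``"lpa-mni"`` (deterministic; seeds are ignored).  Returns sequences
    ``{"Q": [...], "CN": [...]}`` plus ``"NMI"``/``"AMI"`` when a ground
    truth is supplied — ready for :func:`lpamni.metrics.sequence_entropy`.
    """
    from . import metrics
    from .lpa_mni import run_lpa_mni

    if runs < 1:
        raise ValueError("runs must be >= 1")
    out: dict[str, list[float]] = {"Q": [], "CN": []}
    if truth is not None:
        out["NMI"] = []
        out["AMI"] = []
    for r in range(runs):
        if algorithm == "lpa":
            part = run_lpa(net, seed=base_seed + r, max_sweeps=max_sweeps).partition
        elif algorithm in ("lpa-mni", "lpa_mni"):
            part = run_lpa_mni(net, max_sweeps=max_sweeps).partition
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        out["Q"].append(metrics.modularity(net, part))
        out["CN"].append(metrics.community_count(part))
        if truth is not None:
            out["NMI"].append(metrics.nmi(truth, part))
            out["AMI"].append(metrics.ami(truth, part))
    return out
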
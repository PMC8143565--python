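"""Synthetic benchmark graphs (GN planted partition, LFR-style) and sweeps.

GN benchmark: 128 nodes in four planted blocks of 32; every node has
expected total degree 16, of which a fraction ``f`` is external.  Edges are
sampled independently with within-block probability ``z_in/31`` and
between-block probability ``z_out/96`` where ``z_in = (1-f)*16`` and
``z_out = f*16``.  As ``f`` grows past ~0.5 the planted structure fades.

LFR-style benchmark: node degrees follow a truncated power law (exponent
``tau1``) rescaled to the requested mean; community sizes follow a power law
(exponent ``tau2``) within ``[min_community, max_community]``; each node
spends a fraction ``mu`` of its degree on edges leaving its community
(stochastic rounding keeps the average exact).  Stubs are paired by a
configuration model with re-shuffling to avoid self-loops and duplicates.
The mixing parameter ``mu`` plays the same role as ``f`` above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .graph_core import Network, NodeId


@dataclass(frozen=True)
class GNParams:
    """Parameters of the four-block planted-partition (GN) benchmark."""

    external_fraction: float = 0.1
    n_communities: int = 4
    community_size: int = 32
    expected_degree: float = 16.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.external_fraction <= 1.0:
            raise ValueError("external_fraction must be in [0, 1]")
        if self.n_communities < 2 or self.community_size < 2:
            raise ValueError("need at least 2 communities of at least 2 nodes")


@dataclass(frozen=True)
class LFRParams:
    """Parameters of the LFR-style benchmark with power-law heterogeneity."""

    n: int = 1000
    avg_degree: float = 15.0
    max_degree: int = 50
    tau1: float = 2.0
    tau2: float = 1.0
    min_community: int = 10
    max_community: int = 50
    mu: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if not (self.min_community <= self.max_community <= self.n):
            raise ValueError("need min_community <= max_community <= n")
        if not (self.avg_degree <= self.max_degree < self.n):
            raise ValueError("need avg_degree <= max_degree < n")
        # every node must fit its internal degree inside some community
        if round((1.0 - self.mu) * self.max_degree) > self.max_community - 1:
            raise ValueError(
                "infeasible: (1-mu)*max_degree exceeds max_community-1; "
                "the highest-degree node cannot fit its internal edges"
            )


@dataclass(frozen=True)
class BenchmarkInstance:
    network: Network
    truth: dict[NodeId, int]
    realized: dict = field(default_factory=dict)


def generate_gn(p: GNParams) -> BenchmarkInstance:
    """Sample a GN planted-partition instance; truth = the planted blocks."""
    rng = np.random.default_rng(p.seed)
    k, s = p.n_communities, p.community_size
    n = k * s
    z_out = p.external_fraction * p.expected_degree
    z_in = p.expected_degree - z_out
    p_in = z_in / (s - 1)
    p_out = z_out / (n - s)
    if p_in > 1.0 or p_out > 1.0:
        raise ValueError("edge probability exceeds 1 for these parameters")
    block = np.repeat(np.arange(k), s)
    edges = []
    internal = 0
    for i, j in combinations(range(n), 2):
        same = block[i] == block[j]
        if rng.random() < (p_in if same else p_out):
            edges.append((i, j))
            internal += same
    net = Network(edges, nodes=range(n))
    truth = {u: int(block[u]) for u in range(n)}
    m = net.m
    realized = {
        "mean_degree": 2 * m / n,
        "external_edge_fraction": (m - internal) / m if m else 0.0,
    }
    return BenchmarkInstance(network=net, truth=truth, realized=realized)


# -- LFR-style generator ---------------------------------------------------

def _inverse_powerlaw(u: np.ndarray, tau: float, lo: float, hi: float) -> np.ndarray:
    """Inverse CDF of the continuous power law (density ~ x^-tau) on [lo, hi]."""
    if abs(tau - 1.0) < 1e-9:
        return lo * (hi / lo) ** u
    a = lo ** (1.0 - tau)
    b = hi ** (1.0 - tau)
    return (a + u * (b - a)) ** (1.0 / (1.0 - tau))


def _powerlaw_sample(rng, tau: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Continuous power-law draws with density ~ x^-tau on [lo, hi]."""
    return _inverse_powerlaw(rng.random(size), tau, lo, hi)


def _sample_degrees(rng, p: LFRParams) -> np.ndarray:
    """Power-law degrees on [k_min, max_degree] with k_min tuned to the mean.

    The lower cutoff is found by bisection on a fixed uniform sample, so the
    realized mean matches ``avg_degree`` without piling probability mass at
    the cap (which rescale-and-clip would, making dense communities'
    internal degree sequences non-graphical).
    """
    u = rng.random(p.n)
    lo_a, hi_a = 1.0, float(p.max_degree)

    def draws(a: float) -> np.ndarray:
        return np.clip(
            np.rint(_inverse_powerlaw(u, p.tau1, a, p.max_degree)),
            1, p.max_degree,
        )

    for _ in range(60):
        a = 0.5 * (lo_a + hi_a)
        if draws(a).mean() < p.avg_degree:
            lo_a = a
        else:
            hi_a = a
    deg = draws(0.5 * (lo_a + hi_a)).astype(int)
    if deg.sum() % 2:  # configuration model needs an even stub count
        i = int(np.argmin(deg))
        deg[i] += 1
    return deg


def _sample_community_sizes(rng, p: LFRParams) -> list[int]:
    sizes: list[int] = []
    while sum(sizes) < p.n:
        s = int(np.rint(_powerlaw_sample(rng, p.tau2, p.min_community, p.max_community, 1)[0]))
        sizes.append(int(np.clip(s, p.min_community, p.max_community)))
    excess = sum(sizes) - p.n
    # shave the excess off communities that are above the minimum
    while excess > 0:
        room = [i for i, s in enumerate(sizes) if s > p.min_community]
        if not room:
            # drop one community and spread its nodes over the others
            drop = sizes.pop()
            excess -= drop
            while excess < 0:
                grow = [i for i, s in enumerate(sizes) if s < p.max_community]
                if not grow:
                    raise ValueError("cannot partition n into community sizes within bounds")
                sizes[grow[int(rng.integers(len(grow)))]] += 1
                excess += 1
            continue
        i = room[int(rng.integers(len(room)))]
        take = min(excess, sizes[i] - p.min_community)
        sizes[i] -= take
        excess -= take
    return sizes


def _pair_stubs(rng, stubs: np.ndarray, forbidden_same: np.ndarray | None,
                existing: set, max_rounds: int = 40) -> list[tuple[int, int]]:
    """Configuration-model pairing with degree-preserving swap completion.

    ``forbidden_same`` (optional) maps node -> group id; pairs inside one
    group are rejected (used to keep external edges external).  Stubs left
    over after re-shuffling rounds are resolved by double-edge swaps against
    already-placed edges of the same class, so very dense communities still
    realize (almost) their full degree sequence; irreducible leftovers are
    dropped.
    """

    def valid(u: int, v: int) -> bool:
        if u == v:
            return False
        key = (u, v) if u < v else (v, u)
        if key in existing:
            return False
        return forbidden_same is None or forbidden_same[u] != forbidden_same[v]

    def add(u: int, v: int) -> None:
        key = (u, v) if u < v else (v, u)
        existing.add(key)
        edges.append(key)

    edges: list[tuple[int, int]] = []
    pool = stubs.copy()
    for _ in range(max_rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        retry = []
        for a, b in zip(pool[0::2], pool[1::2]):
            if valid(int(a), int(b)):
                add(int(a), int(b))
            else:
                retry.extend((int(a), int(b)))
        if len(pool) % 2:
            retry.append(int(pool[-1]))
        if len(retry) == len(pool):  # no progress
            pool = np.array(retry, dtype=int)
            break
        pool = np.array(retry, dtype=int)
    # swap completion: consume leftover stubs u,v by rewiring an existing
    # edge (x,y) into (u,x) and (v,y)
    leftovers = [int(s) for s in pool]
    while len(leftovers) >= 2 and edges:
        u = leftovers.pop()
        v = leftovers.pop()
        done = False
        for _ in range(200):
            k = int(rng.integers(len(edges)))
            x, y = edges[k]
            kux = (u, x) if u < x else (x, u)
            kvy = (v, y) if v < y else (y, v)
            if valid(u, x) and valid(v, y) and kux != kvy:
                existing.discard((x, y) if x < y else (y, x))
                edges[k] = edges[-1]
                edges.pop()
                add(u, x)
                add(v, y)
                done = True
                break
            kuy = (u, y) if u < y else (y, u)
            kvx = (v, x) if v < x else (x, v)
            if valid(u, y) and valid(v, x) and kuy != kvx:
                existing.discard((x, y) if x < y else (y, x))
                edges[k] = edges[-1]
                edges.pop()
                add(u, y)
                add(v, x)
                done = True
                break
        if not done:
            pass  # drop this stub pair
    return edges


def generate_lfr(p: LFRParams) -> BenchmarkInstance:
    """Sample an LFR-style instance; truth = the planted communities."""
    rng = np.random.default_rng(p.seed)
    deg = _sample_degrees(rng, p)
    sizes = _sample_community_sizes(rng, p)

    # split each degree into external/internal parts; stochastic rounding of
    # mu*k keeps the average mixing at mu instead of biasing it
    ext = np.floor(p.mu * deg).astype(int)
    frac = p.mu * deg - np.floor(p.mu * deg)
    ext += (rng.random(p.n) < frac).astype(int)
    ext = np.minimum(ext, deg)
    internal = deg - ext

    # assign nodes to communities: big internal degrees first, into the
    # community with the most free slots that can host them; when none is
    # large enough, repair by shifting an unfilled slot to the largest
    # community (bounded by max_community)
    comm_of = np.full(p.n, -1, dtype=int)
    sizes = list(sizes)
    free = list(sizes)
    for u in sorted(range(p.n), key=lambda u: -internal[u]):
        while True:
            best, best_free = -1, 0
            for c, fr in enumerate(free):
                if fr > 0 and sizes[c] - 1 >= internal[u] and fr > best_free:
                    best, best_free = c, fr
            if best >= 0:
                break
            grow = max(
                (c for c in range(len(sizes)) if sizes[c] < p.max_community),
                key=lambda c: sizes[c],
                default=-1,
            )
            donors = [
                c for c in range(len(sizes))
                if c != grow and free[c] > 0 and sizes[c] > p.min_community
            ]
            if grow < 0 or not donors:
                raise ValueError(
                    "could not place every node: internal degrees exceed "
                    "community capacity"
                )
            donor = max(donors, key=lambda c: free[c])
            sizes[donor] -= 1
            free[donor] -= 1
            sizes[grow] += 1
            free[grow] += 1
        comm_of[u] = best
        free[best] -= 1

    # parity fixes: each community's internal stub count and the global
    # external stub count must be even; shift one stub between the two parts
    for c in range(len(sizes)):
        members = np.flatnonzero(comm_of == c)
        if internal[members].sum() % 2:
            u = members[int(np.argmax(internal[members]))]
            internal[u] -= 1
            ext[u] += 1
    if ext.sum() % 2:  # drop one external stub (one node ends up one short)
        u = int(np.argmax(ext))
        ext[u] -= 1

    existing: set = set()
    edges: list[tuple[int, int]] = []
    for c in range(len(sizes)):
        members = np.flatnonzero(comm_of == c)
        stubs = np.repeat(members, internal[members])
        edges.extend(_pair_stubs(rng, stubs, None, existing))
    stubs = np.repeat(np.arange(p.n), ext)
    edges.extend(_pair_stubs(rng, stubs, comm_of, existing))

    net = Network(edges, nodes=range(p.n))
    truth = {u: int(comm_of[u]) for u in range(p.n)}
    degs = np.array(net.degrees, dtype=float)
    ext_deg = np.zeros(p.n)
    for u, v in net.edges():
        if comm_of[u] != comm_of[v]:
            ext_deg[u] += 1
            ext_deg[v] += 1
    with np.errstate(invalid="ignore"):
        per_node = np.where(degs > 0, ext_deg / np.maximum(degs, 1), 0.0)
    realized = {
        "mean_degree": float(degs.mean()),
        "mixing": float(per_node[degs > 0].mean()),
        "community_sizes": sorted(sizes),
    }
    return BenchmarkInstance(network=net, truth=truth, realized=realized)


# -- sweep harness ---------------------------------------------------------

def sweep(
    algorithms: dict,
    grid: list,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Score algorithms across a grid of benchmark parameter bundles.

    ``algorithms`` maps name -> callable ``(net, seed) -> partition``;
    ``grid`` holds :class:`GNParams` or :class:`LFRParams` bundles (their
    own seeds are replaced per replicate, derived from ``seed``).  Returns a
    tidy frame with one row per (grid point, replicate, algorithm) carrying
    NMI, AMI, community count and modularity against the planted truth;
    generation failures are flagged in the ``ok`` column and skipped.
    """
    from dataclasses import replace

    from . import metrics

    if not algorithms:
        raise ValueError("need at least one algorithm")
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for gi, params in enumerate(grid):
        param_value = (
            params.external_fraction if isinstance(params, GNParams) else params.mu
        )
        for r in range(replicates):
            inst_seed = (seed * 1_000_003 + gi * 1009 + r) % (2**31)
            try:
                params_r = replace(params, seed=inst_seed)
                inst = (
                    generate_gn(params_r)
                    if isinstance(params_r, GNParams)
                    else generate_lfr(params_r)
                )
            except (ValueError, RuntimeError) as exc:
                rows.append(
                    dict(param=param_value, replicate=r, algorithm=None,
                         nmi=np.nan, ami=np.nan, cn=np.nan, q=np.nan,
                         ok=False, error=str(exc))
                )
                continue
            for name, algo in algorithms.items():
                part = algo(inst.network, inst_seed)
                rows.append(
                    dict(
                        param=param_value,
                        replicate=r,
                        algorithm=name,
                        nmi=metrics.nmi(inst.truth, part),
                        ami=metrics.ami(inst.truth, part),
                        cn=metrics.community_count(part),
                        q=metrics.modularity(inst.network, part),
                        ok=True,
                        error="",
                    )
                )
    return pd.DataFrame(rows)
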
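"""Independent brute-force oracles shared across test modules."""

from __future__ import annotations

import heapq
import math

from neighscale import delineation as dl


def origin_at(net: dl.StreetNetwork, key: tuple[int, int], offset: float) -> dl.NetworkLocation:
    geom = net.edge_geometry(key)
    return dl.NetworkLocation(
        edge=key, offset=float(offset), point=geom.interpolate(offset), snap_distance=0.0
    )


def subdivided_reached_length(
    net: dl.StreetNetwork, origin: dl.NetworkLocation, d: float
) -> float:
    """Reached network length via Dijkstra on a 1-m-subdivided graph.

    Requires integer edge lengths and an integer origin offset, which makes
    the brute-force computation exact; independent of the analytic
    edge-coverage logic in the delineation module.
    """
    adj: dict = {}

    def add(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    unit_edges = []
    for key in net.edge_keys():
        length = int(round(net.edge_length(key)))
        prev = key[0]
        for i in range(1, length):
            cur = (key, i)
            add(prev, cur)
            unit_edges.append((prev, cur))
            prev = cur
        add(prev, key[1])
        unit_edges.append((prev, key[1]))

    t = int(round(origin.offset))
    length = int(round(net.edge_length(origin.edge)))
    if t == 0:
        start = origin.edge[0]
    elif t == length:
        start = origin.edge[1]
    else:
        start = (origin.edge, t)

    dist: dict = {}
    heap = [(0.0, 0, start)]
    tie = 1
    while heap:
        dd, _, node = heapq.heappop(heap)
        if node in dist:
            continue
        dist[node] = dd
        if dd >= d:
            continue
        for nbr in adj[node]:
            if nbr not in dist:
                heapq.heappush(heap, (dd + 1.0, tie, nbr))
                tie += 1

    total = 0.0
    for a, b in unit_edges:
        da, db = dist.get(a, math.inf), dist.get(b, math.inf)
        ca = min(1.0, max(0.0, d - da))
        cb = min(1.0, max(0.0, d - db))
        total += min(1.0, ca + cb)
    return total
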
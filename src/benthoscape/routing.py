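"""Transit-route planning over nested site subsets.

Vessels work a spatially balanced design in increments: the first 30 sites,
then 35, and so on.  For each increment this module builds an open path (the
vessel transits from a start point, it does not return) over the prefix of
the master sample with nearest-neighbour construction followed by 2-opt
improvement.  Site *sets* nest across increments by the master-sample prefix
property; the routes themselves are recomputed per increment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grts import MasterSample, prefix_subset

__all__ = ["Route", "nested_routes", "route_length_km", "nearest_neighbour_order", "two_opt"]


@dataclass
class Route:
    """An ordered open path over one increment of sites."""

    increment: int
    unit_ids: list
    xs: np.ndarray  # includes the start point at index 0
    ys: np.ndarray
    length_km: float

    def to_dataframe(self) -> pd.DataFrame:
        legs = np.hypot(np.diff(self.xs), np.diff(self.ys)) / 1000.0
        return pd.DataFrame(
            {
                "increment": self.increment,
                "leg_order": np.arange(1, len(self.unit_ids) + 1),
                "unit_id": self.unit_ids,
                "cumulative_km": np.cumsum(legs),
            }
        )


def _path_length(xs: np.ndarray, ys: np.ndarray) -> float:
    return float(np.hypot(np.diff(xs), np.diff(ys)).sum())


def route_length_km(xs: np.ndarray, ys: np.ndarray) -> float:
    """Open-path Euclidean length in km (coordinates in metres)."""
    return _path_length(np.asarray(xs, float), np.asarray(ys, float)) / 1000.0


def nearest_neighbour_order(
    start: tuple[float, float],
    xs: np.ndarray,
    ys: np.ndarray,
    unit_ids: np.ndarray,
) -> list[int]:
    """Greedy visiting order from the start point; distance ties broken by
    lowest unit_id, so the construction is deterministic."""
    n = len(xs)
    remaining = list(range(n))
    # pre-sort by unit_id so argmin picks the lowest id on ties
    remaining.sort(key=lambda i: (str(unit_ids[i])))
    order: list[int] = []
    cx, cy = start
    while remaining:
        d = [np.hypot(xs[i] - cx, ys[i] - cy) for i in remaining]
        j = int(np.argmin(d))
        nxt = remaining.pop(j)
        order.append(nxt)
        cx, cy = xs[nxt], ys[nxt]
    return order


def two_opt(xs: np.ndarray, ys: np.ndarray, max_rounds: int = 60) -> np.ndarray:
    """Local-search improvement (2-opt reversals + single-node relocation)
    of an open path whose first node is fixed.

    ``xs[0], ys[0]`` is the start point; improving moves (evaluated by O(1)
    edge deltas) are applied until none remain or ``max_rounds`` sweeps.
    Returns the permutation of indices 1..n-1 (start excluded).
    """
    import math

    n = len(xs)
    order = list(range(n))
    if n < 3:
        return np.array(order[1:], dtype=int)
    px = [float(v) for v in xs]
    py = [float(v) for v in ys]

    def d(a: int, b: int) -> float:
        return math.hypot(px[a] - px[b], py[a] - py[b])

    for _ in range(max_rounds):
        improved = False
        # 2-opt: reverse order[i..j]; removes edges (i-1,i),(j,j+1)
        for i in range(1, n - 1):
            for j in range(i + 1, n):
                a, b, c = order[i - 1], order[i], order[j]
                delta = d(a, c) - d(a, b)
                if j < n - 1:
                    e = order[j + 1]
                    delta += d(b, e) - d(c, e)
                if delta < -1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
        # or-opt: relocate the node at position i to after position j
        for i in range(1, n):
            node = order[i]
            prv, nxt = order[i - 1], order[i + 1] if i < n - 1 else None
            gain_remove = d(prv, node) + (d(node, nxt) - d(prv, nxt) if nxt is not None else 0.0)
            best_delta, best_j = -1e-12, None
            for j in range(0, n - 1):
                if j in (i, i - 1):
                    continue
                u, v = order[j], order[j + 1]
                if u == node or v == node:
                    continue
                add = d(u, node) + d(node, v) - d(u, v)
                delta = add - gain_remove
                if delta < best_delta:
                    best_delta, best_j = delta, j
            # also consider appending at the end of the path
            if i < n - 1:
                add_end = d(order[-1], node)
                delta = add_end - gain_remove
                if delta < best_delta:
                    best_delta, best_j = delta, n - 1
            if best_j is not None:
                order.pop(i)
                if best_j >= i:
                    best_j -= 1
                order.insert(best_j + 1, node)
                improved = True
        if not improved:
            break
    return np.array(order[1:], dtype=int)


def _exact_open_path(start: tuple[float, float], xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Held–Karp dynamic program for the shortest open path from the start
    point through all sites (exact; used for small instances)."""
    import math

    n = len(xs)
    d0 = [math.hypot(xs[i] - start[0], ys[i] - start[1]) for i in range(n)]
    d = [[math.hypot(xs[i] - xs[j], ys[i] - ys[j]) for j in range(n)] for i in range(n)]
    full = 1 << n
    dp = [[math.inf] * n for _ in range(full)]
    parent = [[-1] * n for _ in range(full)]
    for i in range(n):
        dp[1 << i][i] = d0[i]
    for mask in range(full):
        for i in range(n):
            cur = dp[mask][i]
            if not math.isfinite(cur):
                continue
            for j in range(n):
                if mask & (1 << j):
                    continue
                nm = mask | (1 << j)
                cand = cur + d[i][j]
                if cand < dp[nm][j]:
                    dp[nm][j] = cand
                    parent[nm][j] = i
    end = min(range(n), key=lambda i: dp[full - 1][i])
    order = [end]
    mask = full - 1
    while parent[mask][order[-1]] != -1:
        p = parent[mask][order[-1]]
        mask ^= 1 << order[-1]
        order.append(p)
    return order[::-1]


#: exact dynamic programming is used up to this many sites per route
EXACT_ROUTE_LIMIT = 9


def nested_routes(
    master: MasterSample,
    increments: list[int],
    start_point: tuple[float, float],
) -> list[Route]:
    """Open transit routes for each increment of the master sample."""
    if not increments:
        raise ValueError("increments must be non-empty")
    if sorted(increments) != list(increments):
        raise ValueError("increments must be sorted ascending")
    if increments[-1] > master.n_master:
        raise ValueError("largest increment exceeds the master sample size")

    routes: list[Route] = []
    for n in increments:
        sites = prefix_subset(master, n)
        xs = sites["x"].to_numpy(float)
        ys = sites["y"].to_numpy(float)
        ids = sites["unit_id"].to_numpy()
        if n <= EXACT_ROUTE_LIMIT:
            visit = _exact_open_path(start_point, xs, ys)
        else:
            nn = nearest_neighbour_order(start_point, xs, ys, ids)
            full_x = np.concatenate([[start_point[0]], xs[nn]])
            full_y = np.concatenate([[start_point[1]], ys[nn]])
            perm = two_opt(full_x, full_y)
            visit = [nn[k - 1] for k in perm]
        rx = np.concatenate([[start_point[0]], xs[visit]])
        ry = np.concatenate([[start_point[1]], ys[visit]])
        routes.append(
            Route(
                increment=n,
                unit_ids=[ids[k] for k in visit],
                xs=rx,
                ys=ry,
                length_km=_path_length(rx, ry) / 1000.0,
            )
        )
    return routes
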
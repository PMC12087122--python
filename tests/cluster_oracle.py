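"""Brute-force agglomerative clustering, independent of scipy.

Cluster distances are recomputed from member coordinates (or merge history
for the history-dependent linkages) at every step, with no Lance-Williams
shortcuts, so this is a from-first-principles oracle for small instances.
Ties are broken toward the pair containing the smallest original index; at
each merge the subtree holding the smaller original index goes left, which
matches the canonical leaf order of the implementation under test.
"""

import itertools
import math

import numpy as np


def _euclid(a, b):
    return math.dist(a, b)


def _pair_distances(members_a, members_b, points):
    return [
        _euclid(points[i], points[j])
        for i in members_a
        for j in members_b
    ]


def _cluster_distance(linkage, a, b, points, medians):
    if linkage == "single":
        return min(_pair_distances(a["members"], b["members"], points))
    if linkage == "complete":
        return max(_pair_distances(a["members"], b["members"], points))
    if linkage == "average":
        d = _pair_distances(a["members"], b["members"], points)
        return sum(d) / len(d)
    if linkage == "centroid":
        ca = np.mean([points[i] for i in a["members"]], axis=0)
        cb = np.mean([points[i] for i in b["members"]], axis=0)
        return _euclid(ca, cb)
    if linkage == "ward":
        na, nb = len(a["members"]), len(b["members"])
        ca = np.mean([points[i] for i in a["members"]], axis=0)
        cb = np.mean([points[i] for i in b["members"]], axis=0)
        return math.sqrt(2.0 * na * nb / (na + nb)) * _euclid(ca, cb)
    if linkage == "median":
        return _euclid(medians[a["id"]], medians[b["id"]])
    if linkage == "weighted":
        # WPGMA: defined recursively over the merge history
        def dist(x, y):
            if x["children"] is None and y["children"] is None:
                return _euclid(points[x["members"][0]], points[y["members"][0]])
            if x["children"] is None:
                x, y = y, x
            l, r = x["children"]
            return (dist(l, y) + dist(r, y)) / 2.0

        return dist(a, b)
    raise ValueError(linkage)


def brute_force_leaf_order(data, linkage):
    """Leaf order of agglomerative clustering over the rows of *data*."""
    points = [np.asarray(row, dtype=float) for row in data]
    n = len(points)
    clusters = [
        {"id": i, "members": [i], "leaves": [i], "children": None}
        for i in range(n)
    ]
    medians = {i: points[i].copy() for i in range(n)}
    next_id = n
    active = list(clusters)
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(active, 2):
            d = _cluster_distance(linkage, a, b, points, medians)
            key = (d, min(a["members"] + b["members"]),
                   min(b["members"] + a["members"]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        left, right = (a, b) if min(a["members"]) <= min(b["members"]) else (b, a)
        merged = {
            "id": next_id,
            "members": left["members"] + right["members"],
            "leaves": left["leaves"] + right["leaves"],
            "children": (left, right),
        }
        medians[next_id] = (medians[left["id"]] + medians[right["id"]]) / 2.0
        next_id += 1
        active = [c for c in active if c is not a and c is not b] + [merged]
    return active[0]["leaves"]
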
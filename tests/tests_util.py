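"""Shared brute-force oracles and fixture helpers for the test suite."""

from collections import deque

import numpy as np

from phenolig.atom_types import TypedAtom
from phenolig.synthetic import _Builder


def typed_points(points, label="C.3", context="lig", resname="UNL", chain="L"):
    """Typed atom records at given positions (ligand or protein context)."""
    b = _Builder()
    out = []
    for i, p in enumerate(points):
        het = context == "lig"
        a = b.add(f"X{i}", "C", resname, 100 if het else i + 1, chain, p, het=het)
        out.append(TypedAtom(a, label, context))
    return out


def brute_force_dbscan(points, eps, min_pts):
    """Textbook DBSCAN: O(n^2) neighborhoods, FIFO cluster expansion."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighborhoods = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighborhoods]
    labels = np.full(n, -1)
    c = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = c
        q = deque([i])
        while q:
            j = q.popleft()
            for k in neighborhoods[j]:
                if labels[k] == -1:
                    labels[k] = c
                    if core[k]:
                        q.append(k)
        c += 1
    return labels
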
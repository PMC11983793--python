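"""Atom-pair counting and normalized radial distribution functions.

For each (protein-side type, ligand-side type) pair observed inside the
cutoff, distances are tallied into fixed-width bins and converted into a
background-subtracted radial distribution

    g_ij(r) = p_ij(r) / (4 pi r^2 b N) - g_ab(r)

where ``p_ij`` is the per-bin pair count, ``b`` the bin width, ``r`` the bin
center and ``g_ab`` the type-blind profile computed the same way over all
pairs.  By default ``N`` is the per-type-pair total ``N_ij`` inside the
cutoff (the type-blind total ``N_all`` inside ``g_ab``); with that reading
the count-weighted sum of all profiles is identically zero in every bin and
profiles of rare and abundant pairs live on one scale.  A ``global`` switch
normalizes every pair with ``N_all`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from phenolig.atom_types import TypedAtom

DEFAULT_CUTOFF = 7.5
DEFAULT_BIN_WIDTH = 0.1


@dataclass
class PairHistogram:
    """Binned distance counts for one (protein type, ligand type) pair."""

    type_i: str  # protein-side label, e.g. "O.3_sc"
    type_j: str  # ligand-side label, e.g. "O.3"
    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def n_pairs(self) -> int:
        """Total pair occurrences within the cutoff (N_ij)."""
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RDFProfile:
    """The normalized, background-subtracted profile of one pair type."""

    type_i: str
    type_j: str
    r: np.ndarray
    g: np.ndarray
    g_ab: np.ndarray
    histogram: PairHistogram

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type_i": self.type_i,
                "type_j": self.type_j,
                "r": self.r,
                "p_ij": self.histogram.counts,
                "g_ij": self.g,
                "g_ab": self.g_ab,
                "N_ij": self.histogram.n_pairs,
            }
        )


def _bin_edges(cutoff: float, bin_width: float) -> np.ndarray:
    n_bins = int(round(cutoff / bin_width))
    return np.linspace(0.0, n_bins * bin_width, n_bins + 1)


def count_pairs(
    ligand_typed: list[TypedAtom],
    site_typed: list[TypedAtom],
    cutoff: float = DEFAULT_CUTOFF,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[tuple[str, str], PairHistogram]:
    """Histogram every ligand-atom x site-atom distance within the cutoff.

    Bins are right-closed: a distance d falls in bin k iff
    ``edges[k] < d <= edges[k+1]``; a pair exactly at the cutoff counts.
    Pairs are ligand vs site only - no intra-ligand or intra-site pairs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = _bin_edges(cutoff, bin_width)
    out: dict[tuple[str, str], PairHistogram] = {}
    if not ligand_typed or not site_typed:
        return out
    lig_xyz = np.array([t.atom.coordinates for t in ligand_typed])
    site_xyz = np.array([t.atom.coordinates for t in site_typed])
    tree = cKDTree(site_xyz)
    for li, neighbors in enumerate(tree.query_ball_point(lig_xyz, r=cutoff)):
        for si in neighbors:
            d = float(np.linalg.norm(lig_xyz[li] - site_xyz[si]))
            if d <= 0 or d > cutoff:
                continue
            k = min(int(np.searchsorted(edges, d, side="left")) - 1, len(edges) - 2)
            key = (site_typed[si].label, ligand_typed[li].sybyl)
            if key not in out:
                out[key] = PairHistogram(
                    type_i=key[0],
                    type_j=key[1],
                    bin_edges=edges,
                    counts=np.zeros(len(edges) - 1, dtype=int),
                    bin_width=bin_width,
                )
            out[key].counts[k] += 1
    return out


def background(histograms: dict[tuple[str, str], PairHistogram]) -> np.ndarray:
    """Type-blind profile g_ab(r) = p_all(r) / (4 pi r^2 b N_all)."""
    if not histograms:
        raise ValueError("background requires at least one histogram")
    hs = list(histograms.values())
    _check_common_bins(hs)
    p_all = np.sum([h.counts for h in hs], axis=0)
    n_all = int(p_all.sum())
    if n_all == 0:
        return np.zeros_like(p_all, dtype=float)
    r = hs[0].bin_centers
    return p_all / (4.0 * np.pi * r**2 * hs[0].bin_width * n_all)


def normalize_rdf(
    h: PairHistogram,
    g_ab: np.ndarray,
    n_mode: str = "per_pair",
    n_all: int | None = None,
) -> RDFProfile:
    """Background-subtracted profile of one pair histogram.

    ``n_mode="per_pair"`` divides by the pair's own total N_ij (default);
    ``n_mode="global"`` divides by the type-blind total ``n_all``.
    """
    if len(g_ab) != len(h.counts):
        raise ValueError("background profile does not match histogram binning")
    r = h.bin_centers
    if n_mode == "per_pair":
        n = h.n_pairs
    elif n_mode == "global":
        if n_all is None:
            raise ValueError("n_mode='global' requires n_all")
        n = n_all
    else:
        raise ValueError(f"unknown n_mode {n_mode!r}")
    shell = 4.0 * np.pi * r**2 * h.bin_width * max(n, 1)
    g = h.counts / shell - g_ab
    return RDFProfile(type_i=h.type_i, type_j=h.type_j, r=r, g=g, g_ab=np.asarray(g_ab), histogram=h)


def aggregate(
    histogram_sets: list[dict[tuple[str, str], PairHistogram]],
) -> dict[tuple[str, str], PairHistogram]:
    """Pool pair histograms across structures (binwise count sums)."""
    pooled: dict[tuple[str, str], PairHistogram] = {}
    for hset in histogram_sets:
        for key, h in hset.items():
            if key in pooled:
                p = pooled[key]
                if len(p.counts) != len(h.counts) or p.bin_width != h.bin_width:
                    raise ValueError(f"binning mismatch while pooling pair {key}")
                p.counts = p.counts + h.counts
            else:
                pooled[key] = PairHistogram(
                    type_i=h.type_i,
                    type_j=h.type_j,
                    bin_edges=h.bin_edges.copy(),
                    counts=h.counts.copy(),
                    bin_width=h.bin_width,
                )
    return pooled


def profiles_frame(histograms: dict[tuple[str, str], PairHistogram], n_mode: str = "per_pair") -> pd.DataFrame:
    """Normalize every histogram against the pooled background; long table."""
    g_ab = background(histograms)
    n_all = sum(h.n_pairs for h in histograms.values())
    frames = [
        normalize_rdf(h, g_ab, n_mode=n_mode, n_all=n_all).to_frame()
        for _, h in sorted(histograms.items())
    ]
    return pd.concat(frames, ignore_index=True)


def _check_common_bins(hs: list[PairHistogram]) -> None:
    first = hs[0]
    for h in hs[1:]:
        if len(h.counts) != len(first.counts) or h.bin_width != first.bin_width:
            raise ValueError("histograms do not share a common binning")
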
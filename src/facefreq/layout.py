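"""Sensor layout: electrode names, 2-D positions, adjacency, and ROIs.

The montage is a synthetic 64-channel template laid out on concentric
rings inside a unit head circle (nose toward +y).  It is not the exact
geometry of any commercial net; the six electrodes used by the a priori
component analyses (E27/E30 and E44/E45 over left/right temporo-parietal
cortex, E35/E39 over left/right parieto-occipital cortex) are pinned to
canonical 10-10-like positions (~P7/P8 and ~PO1/PO2) so that named ROI
extraction behaves like it would on a real net.

Adjacency is derived from a Delaunay triangulation of the 2-D positions
with an edge-length cap, which yields a planar, symmetric, irreflexive
neighbor relation suitable for spatiotemporal clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["SensorLayout", "default_layout"]


@dataclass
class SensorLayout:
    """Electrode names, 2-D positions, neighbor relation and named ROIs.

    Parameters
    ----------
    names : list of str
        Unique electrode labels (``E1`` .. ``E64`` for the default montage).
    pos : ndarray, shape (n_channels, 2)
        2-D positions in head-circle coordinates (unit radius, nose +y).
    adjacency : ndarray of bool, shape (n_channels, n_channels)
        Symmetric, irreflexive neighbor matrix.
    roi_sets : dict of str -> list of str
        Named electrode groups (e.g. ``"right-parietal"``).
    """

    names: list[str]
    pos: np.ndarray
    adjacency: np.ndarray
    roi_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("electrode names must be unique")
        if self.pos.shape != (n, 2):
            raise ValueError("pos must have shape (n_channels, 2)")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square (n_channels, n_channels)")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        for roi, members in self.roi_sets.items():
            missing = set(members) - set(self.names)
            if missing:
                raise ValueError(f"ROI {roi!r} references unknown electrodes {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown electrode {name!r}") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def roi_indices(self, roi: str) -> np.ndarray:
        if roi not in self.roi_sets:
            raise KeyError(f"unknown ROI {roi!r}")
        return self.indices(self.roi_sets[roi])

    def neighbors(self, name: str) -> list[str]:
        i = self.index(name)
        return [self.names[j] for j in np.flatnonzero(self.adjacency[i])]


def _ring_positions() -> np.ndarray:
    """64 positions on concentric rings inside the unit circle."""
    radii = [0.0, 0.25, 0.5, 0.75, 0.95]
    counts = [1, 7, 12, 20, 24]
    pts = []
    for r, c in zip(radii, counts):
        if c == 1:
            pts.append((0.0, 0.0))
            continue
        # Offset alternate rings so electrodes interleave.
        phase = np.pi / c
        ang = np.pi / 2 + phase + 2 * np.pi * np.arange(c) / c
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.array(pts)


# Canonical 2-D targets for the electrodes named by the component specs
# (posterior y < 0): ~P7/P8 for the N170/N250 pairs, ~PO1/PO2 for P1.
_NAMED_TARGETS = {
    "E27": (-0.72, -0.45),  # ~P7
    "E30": (-0.55, -0.60),  # left temporo-parietal partner
    "E44": (0.72, -0.45),   # ~P8
    "E45": (0.55, -0.60),   # right temporo-parietal partner
    "E35": (-0.20, -0.75),  # ~PO1
    "E39": (0.20, -0.75),   # ~PO2
}


def delaunay_adjacency(pos: np.ndarray, max_edge_factor: float = 1.6) -> np.ndarray:
    """Neighbor matrix from Delaunay triangulation with an edge-length cap.

    Edges longer than ``max_edge_factor`` times the median Delaunay edge are
    dropped, which removes the long sliver edges that triangulation creates
    along the convex hull.
    """
    tri = Delaunay(pos)
    n = len(pos)
    adj = np.zeros((n, n), dtype=bool)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(i, j), max(i, j)))
    lengths = {e: np.linalg.norm(pos[e[0]] - pos[e[1]]) for e in edges}
    cap = max_edge_factor * np.median(list(lengths.values()))
    for (i, j), d in lengths.items():
        if d <= cap:
            adj[i, j] = adj[j, i] = True
    return adj


def default_layout(n_channels: int = 64) -> SensorLayout:
    """Build the synthetic 64-channel ring montage with named ROIs.

    For ``n_channels`` other than 64 a reduced montage is produced by
    subsampling the ring positions evenly; the six named electrodes are
    retained whenever ``n_channels >= 16``.
    """
    full = _ring_positions()
    if n_channels == 64:
        pos = full
    elif 4 <= n_channels < 64:
        idx = np.unique(np.round(np.linspace(0, 63, n_channels)).astype(int))
        # Ensure the pinned names keep posterior sites available.
        pos = full[idx]
    else:
        raise ValueError("n_channels must be in [4, 64]")

    n = len(pos)
    names = [None] * n
    taken = set()
    if n >= 16:
        for name, target in _NAMED_TARGETS.items():
            d = np.linalg.norm(pos - np.asarray(target), axis=1)
            d[list(taken)] = np.inf
            i = int(np.argmin(d))
            names[i] = name
            taken.add(i)
    used_numbers = {int(nm[1:]) for nm in names if nm}
    spare = iter(k for k in range(1, n + 65) if k not in used_numbers)
    for i in range(n):
        if names[i] is None:
            names[i] = f"E{next(spare)}"

    adj = delaunay_adjacency(pos)

    x, y = pos[:, 0], pos[:, 1]
    rois = {
        "occipital": [names[i] for i in np.flatnonzero((y < -0.55) & (abs(x) < 0.45))],
        "left-frontal": [names[i] for i in np.flatnonzero((y > 0.3) & (x < -0.15))],
        "right-parietal": [
            names[i] for i in np.flatnonzero((y < -0.15) & (y > -0.75) & (x > 0.25))
        ],
        "left-temporoparietal": [
            names[i] for i in np.flatnonzero((y < -0.1) & (x < -0.45))
        ],
        "right-temporoparietal": [
            names[i] for i in np.flatnonzero((y < -0.1) & (x > 0.45))
        ],
    }
    rois = {k: v for k, v in rois.items() if v}
    return SensorLayout(names=names, pos=pos, adjacency=adj, roi_sets=rois)
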
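"""Graph-search layer segmentation of averaged corneal B-scans.

Each interface is extracted as the minimum-total-cost left-to-right path
through an amplitude-only energy map (cost = 1 − normalised amplitude), one
depth node per lateral column, with a bounded vertical step between
adjacent columns.  The specular interface reflections at the normal-
incidence orientation dominate the image, so no gradient (differential)
energy term is needed.  Three sequential searches, each blocking a band
around the previously found path, return the anterior surface, the
epithelium–Bowman's boundary and the Bowman's–stroma boundary; incorrect
paths can be blocked through a manual mask and the search re-run.

Images are [n_depth, n_columns] with depth increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyMap",
    "PathMask",
    "InterfacePath",
    "SegmentationResult",
    "preprocess",
    "build_energy",
    "graph_search",
    "find_three_paths",
]


# ---------------------------------------------------------------------------
# 2×2 filters — footprint anchored top-left, edge replication
# ---------------------------------------------------------------------------

def _four_neighbourhood(image: np.ndarray) -> np.ndarray:
    """Stack of the 2×2 neighbourhood values (self, right, down, down-right)
    for every pixel, bottom/right edges replicated."""
    padded = np.pad(image, ((0, 1), (0, 1)), mode="edge")
    h, w = image.shape
    return np.stack(
        [padded[:h, :w], padded[:h, 1 : w + 1], padded[1 : h + 1, :w], padded[1 : h + 1, 1 : w + 1]]
    )


def preprocess(image: np.ndarray) -> np.ndarray:
    """2×2 median filter.

    For the even-sized window the *upper* median (third order statistic of
    the four) is used: a single hot pixel still vanishes, a one-pixel-wide
    bright interface line survives, and the filter never invents values not
    present in the neighbourhood.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    return np.sort(_four_neighbourhood(image), axis=0)[2]


@dataclass(frozen=True)
class EnergyMap:
    """Per-node path costs: lower cost ⇔ brighter amplitude."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_energy(image: np.ndarray) -> EnergyMap:
    """Amplitude-only energy: cost = 1 − min-max-normalised amplitude,
    smoothed with a 2×2 top-hat (uniform) convolution.

    Scale-invariant by construction: doubling all amplitudes leaves the
    energy unchanged.  A constant image has no contrast to segment.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise ValueError("constant image: no contrast to segment")
    cost = 1.0 - (image - lo) / (hi - lo)
    cost = _four_neighbourhood(cost).mean(axis=0)
    return EnergyMap(values=cost, provenance={"median": "2x2", "tophat": "2x2"})


# ---------------------------------------------------------------------------
# Dynamic-programming path search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathMask:
    """Nodes excluded from the search (True = blocked)."""

    blocked: np.ndarray

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "PathMask":
        return cls(blocked=np.zeros(shape, dtype=bool))

    def union(self, other: "PathMask") -> "PathMask":
        return PathMask(blocked=self.blocked | other.blocked)


@dataclass(frozen=True)
class InterfacePath:
    """One depth index per column (0-based, depth increases downward)."""

    depth_index: np.ndarray
    cost: float

    @property
    def mean_depth(self) -> float:
        return float(self.depth_index.mean())


@dataclass(frozen=True)
class SegmentationResult:
    """The three corneal interfaces ordered by mean depth."""

    paths: tuple[InterfacePath, InterfacePath, InterfacePath]
    region: tuple[int, int]

    def __post_init__(self) -> None:
        p0, p1, p2 = (p.depth_index for p in self.paths)
        if not (np.all(p0 < p1) and np.all(p1 < p2)):
            raise ValueError("interface paths must be strictly ordered and non-crossing")

    @property
    def surface(self) -> InterfacePath:
        return self.paths[0]

    @property
    def epi_bowman(self) -> InterfacePath:
        return self.paths[1]

    @property
    def bowman_stroma(self) -> InterfacePath:
        return self.paths[2]


def graph_search(energy: EnergyMap, mask: PathMask | None = None, max_step: int = 2) -> InterfacePath:
    """Minimum-cost left-to-right path, one node per column.

    Dynamic programming over columns with |Δdepth| ≤ ``max_step`` between
    neighbours and blocked nodes excluded.  Among equal-cost paths the
    lexicographically smallest depth sequence is returned (smaller depth
    index first, then leftmost divergence), which the backward-DP greedy
    reconstruction realises exactly.
    """
    cost = energy.values
    n_depth, n_cols = cost.shape
    if mask is None:
        mask = PathMask.empty(cost.shape)
    blocked = mask.blocked
    for c in range(n_cols):
        if blocked[:, c].all():
            raise ValueError(f"column {c} is fully blocked")
    inf = np.inf
    node = np.where(blocked, inf, cost)

    # g[r, c]: minimal cost of a path from column c to the last column
    # starting at depth r
    g = np.full((n_depth, n_cols), inf)
    g[:, -1] = node[:, -1]
    for c in range(n_cols - 2, -1, -1):
        nxt = g[:, c + 1]
        best = np.full(n_depth, inf)
        for off in range(-max_step, max_step + 1):
            shifted = np.full(n_depth, inf)
            if off >= 0:
                shifted[: n_depth - off] = nxt[off:]
            else:
                shifted[-off:] = nxt[:off]
            best = np.minimum(best, shifted)
        g[:, c] = node[:, c] + best

    total = g[:, 0].min()
    if not np.isfinite(total):
        raise ValueError("no feasible path through the energy map")
    # greedy left-to-right reconstruction → lexicographically smallest optimum
    path = np.empty(n_cols, dtype=int)
    path[0] = int(np.flatnonzero(np.isclose(g[:, 0], total, rtol=0, atol=1e-9))[0])
    for c in range(1, n_cols):
        r_prev = path[c - 1]
        remaining = g[r_prev, c - 1] - node[r_prev, c - 1]
        lo = max(0, r_prev - max_step)
        hi = min(n_depth, r_prev + max_step + 1)
        cand = np.flatnonzero(np.isclose(g[lo:hi, c], remaining, rtol=0, atol=1e-9))
        if cand.size == 0:  # numerical guard: fall back to the argmin
            cand = np.array([int(np.argmin(g[lo:hi, c]))])
        path[c] = lo + int(cand[0])
    return InterfacePath(depth_index=path, cost=float(total))


def find_three_paths(
    energy: EnergyMap,
    mask: PathMask | None = None,
    max_step: int = 2,
    exclusion_halfwidth: int = 3,
) -> SegmentationResult:
    """Three sequential path searches with inter-path exclusion bands.

    After each search a band of ±``exclusion_halfwidth`` pixels around the
    found path is blocked before the next search; a manual ``mask`` (from a
    previous run's incorrect paths) is honoured throughout.  The final
    paths are sorted by mean depth and must be strictly non-crossing.
    """
    n_depth, n_cols = energy.shape
    if n_depth < 3 * (2 * exclusion_halfwidth + 1):
        raise ValueError("image too shallow to hold 3 disjoint interface bands")
    work = mask if mask is not None else PathMask.empty(energy.shape)
    rows = np.arange(n_depth)[:, None]
    paths = []
    for _ in range(3):
        try:
            p = graph_search(energy, work, max_step)
        except ValueError as exc:
            raise ValueError(f"cannot place 3 disjoint paths: {exc}") from exc
        paths.append(p)
        band = np.abs(rows - p.depth_index[None, :]) <= exclusion_halfwidth
        work = work.union(PathMask(blocked=band))
    paths.sort(key=lambda p: p.mean_depth)
    return SegmentationResult(paths=tuple(paths), region=(0, n_cols))
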
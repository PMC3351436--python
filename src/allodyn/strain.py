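"""Time-resolved geometric strain of individual residues.

Where the pairwise fluctuation matrix reports coordination between residue
pairs, geometric strain reports how much a single residue's local contact
geometry deforms over time.  With neighbours N(i) fixed from the
time-averaged structure,

    s_i(t) = (1/|N(i)|) * sum_{j in N(i)} (d_ij(t) - <d_ij>)^2   [angstrom^2],

optionally averaged over windows of consecutive frames for time-resolved
maps.  The neighbourhood is frozen (not recomputed per frame) so that the
strain measures deformation of one fixed local network; normalising by
|N(i)| makes surface and core residues comparable.

All quantities are functions of internal distances only and therefore
invariant to per-frame rigid-body motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ResidueRange, Trajectory
from .regions import RegionCall, calls_from_scores, significance_threshold

__all__ = [
    "NeighborMap",
    "StrainSeries",
    "StrainProfile",
    "neighbor_map",
    "strain_series",
    "average_strain_profile",
    "strain_hotspots",
]

DEFAULT_CUTOFF = 8.0  # angstrom, standard CA-CA residue-contact scale
DEFAULT_WINDOW = 50   # frames per time-map column


@dataclass
class NeighborMap:
    """Contact neighbourhood from the time-averaged distance matrix."""

    neighbors: dict[int, np.ndarray]  # residue id -> array of neighbour ids
    cutoff: float
    residue_ids: np.ndarray
    mean_distances: np.ndarray  # time-averaged d_ij, same order as residue_ids

    @property
    def isolated(self) -> list[int]:
        return [rid for rid, nb in self.neighbors.items() if nb.size == 0]


@dataclass
class StrainSeries:
    """Per-residue, per-time-window strain values (angstrom^2, NaN = isolated)."""

    values: np.ndarray  # (residues, windows)
    residue_ids: np.ndarray
    window: int
    range: ResidueRange

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError("strain values must be >= 0")
        self.values = v


@dataclass
class StrainProfile:
    """Mean strain per residue over all windows (angstrom^2)."""

    values: np.ndarray
    residue_ids: np.ndarray
    range: ResidueRange


def _mean_distance_matrix(coords: np.ndarray) -> np.ndarray:
    chunk = 256
    F, R = coords.shape[0], coords.shape[1]
    acc = np.zeros((R, R))
    for lo in range(0, F, chunk):
        block = coords[lo:lo + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        acc += np.sqrt((diff * diff).sum(axis=-1)).sum(axis=0)
    return acc / F


def neighbor_map(traj: Trajectory, cutoff: float = DEFAULT_CUTOFF,
                 rng: ResidueRange | None = None) -> NeighborMap:
    """Neighbours are pairs whose *time-averaged* distance is within cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sub = traj.select_range(rng) if rng is not None else traj
    mean_d = _mean_distance_matrix(sub.coords)
    ids = sub.residue_ids
    adj = (mean_d <= cutoff)
    np.fill_diagonal(adj, False)
    neighbors = {int(ids[i]): ids[adj[i]].copy() for i in range(ids.size)}
    return NeighborMap(neighbors, float(cutoff), ids.copy(), mean_d)


def strain_series(traj: Trajectory, nmap: NeighborMap, window: int = DEFAULT_WINDOW,
                  rng: ResidueRange | None = None) -> StrainSeries:
    """Window-averaged geometric strain per residue.

    Isolated residues (no neighbour within cutoff) propagate as NaN.
    Trailing frames that do not fill a whole window are dropped, so the
    series has floor(n_frames / window) columns.
    """
    sub = traj.select_range(rng) if rng is not None else traj
    if not np.array_equal(sub.residue_ids, nmap.residue_ids):
        raise ValueError("neighbor map was built on a different residue selection")
    if window < 1:
        raise ValueError("window must be >= 1")
    F = sub.n_frames
    if window > F:
        raise ValueError(f"window ({window}) exceeds frame count ({F})")

    ids = sub.residue_ids
    id_to_col = {int(r): i for i, r in enumerate(ids)}
    mean_d = nmap.mean_distances
    n_windows = F // window
    per_frame = np.full((ids.size, F), np.nan)

    chunk = 256
    for lo in range(0, F, chunk):
        block = sub.coords[lo:lo + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        d = np.sqrt((diff * diff).sum(axis=-1))          # (f, R, R)
        dev2 = (d - mean_d) ** 2
        for i, rid in enumerate(ids):
            nb = nmap.neighbors[int(rid)]
            if nb.size == 0:
                continue
            cols = [id_to_col[int(j)] for j in nb]
            per_frame[i, lo:lo + block.shape[0]] = dev2[:, i, cols].mean(axis=1)

    trimmed = per_frame[:, : n_windows * window]
    values = trimmed.reshape(ids.size, n_windows, window).mean(axis=2)
    srange = rng if rng is not None else ResidueRange(int(ids[0]), int(ids[-1]))
    return StrainSeries(values, ids.copy(), window, srange)


def average_strain_profile(series: StrainSeries) -> StrainProfile:
    """Row means over windows; residues missing everywhere stay NaN."""
    finite = np.isfinite(series.values)
    counts = finite.sum(axis=1)
    sums = np.where(finite, series.values, 0.0).sum(axis=1)
    means = np.divide(sums, counts, out=np.full(counts.shape, np.nan),
                      where=counts > 0)
    return StrainProfile(means, series.residue_ids.copy(), series.range)


def strain_hotspots(
    apo: StrainProfile,
    holo: StrainProfile,
    k: float = 1.0,
    min_len: int = 3,
) -> list[RegionCall]:
    """Segments where the holo-minus-apo strain change is significant.

    Per-residue change delta_s = holo - apo; residues with |delta_s| above
    mean + k*SD of all |delta_s| are scored, and contiguous same-sign runs
    of >= min_len residues become calls (quenched = strain reduced upon
    binding).
    """
    if not np.array_equal(apo.residue_ids, holo.residue_ids):
        raise ValueError("apo/holo strain profiles cover different residues")
    if k <= 0:
        raise ValueError("k must be > 0")
    delta = holo.values - apo.values
    thresh = significance_threshold(delta, k)
    scores = np.where(np.abs(delta) > thresh, delta, np.nan)
    return calls_from_scores(apo.residue_ids, scores, min_len=min_len)
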
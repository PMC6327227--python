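"""Single-molecule localization processing and replication-fork NND analysis.

Ground-state-depletion (GSDIM) imaging yields a list of localization events
(x, y, photon count).  Dim events (< 500 photons by default) are discarded,
the rest are binned onto a 10-nm pixel grid by counting, and replication
forks are detected on the reconstructed count image by:

1. a 3x3 median filter;
2. removal of foreground pixels connected (8-connectivity, foreground =
   nonzero) to fewer than 3 other foreground pixels;
3. grayscale dilation with a disc structural element (radius 4 pixels;
   the disc contains the pixels whose center distance is <= the radius);
4. marking pixels where dilated minus original equals 0 — the local maxima —
   restricted to foreground;
5. deduplication of directly neighboring maxima: one fork is kept per
   8-connected plateau (the lexicographically smallest pixel).

Fork-to-fork nearest-neighbor distances (NND) are Euclidean, center to
center, in nanometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "LocalizationSet",
    "ReconstructedImage",
    "ForkSet",
    "NNDDistribution",
    "read_localizations",
    "reconstruct",
    "detect_forks",
    "nnd_stats",
    "disc_footprint",
]


@dataclass
class ReconstructedImage:
    counts: np.ndarray  # (ny, nx) event counts
    pixel_size: float  # nm

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


@dataclass
class ForkSet:
    pixels: np.ndarray  # (m, 2) integer (row, col)
    pixel_size: float
    disc_radius: float
    min_neighbors: int

    def coordinates_nm(self) -> np.ndarray:
        """Pixel-center coordinates in nm, (m, 2) as (y, x)."""
        return (self.pixels + 0.5) * self.pixel_size

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class NNDDistribution:
    distances: np.ndarray  # nm, one per fork

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


# kept for interface symmetry with the event CSV dialect
LocalizationSet = pd.DataFrame


def read_localizations(path) -> pd.DataFrame:
    """Read an event CSV with columns frame, x_nm, y_nm, photons."""
    df = pd.read_csv(path)
    required = {"x_nm", "y_nm", "photons"}
    if not required <= set(df.columns):
        raise ValueError(f"event table must contain columns {sorted(required)}")
    return df


def reconstruct(
    events: pd.DataFrame, pixel_size: float = 10.0, min_photons: float = 500.0
) -> ReconstructedImage:
    """Bin photon-filtered events into a count image (floor division)."""
    if len(events) == 0:
        raise ValueError("no events supplied")
    keep = events["photons"].to_numpy() >= min_photons
    if not np.any(keep):
        raise ValueError("no events retained")
    x = (events["x_nm"].to_numpy()[keep] // pixel_size).astype(int)
    y = (events["y_nm"].to_numpy()[keep] // pixel_size).astype(int)
    nx, ny = x.max() + 1, y.max() + 1
    counts = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(counts, (y, x), 1)
    return ReconstructedImage(counts=counts, pixel_size=pixel_size)


def disc_footprint(radius: float) -> np.ndarray:
    """Boolean disc: pixels whose center distance from the origin is <= radius."""
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius**2


def detect_forks(
    image: ReconstructedImage,
    disc_radius: float = 4.0,
    min_neighbors: int = 3,
) -> ForkSet:
    """Detect replication forks as deduplicated grayscale-dilation maxima."""
    img = np.asarray(image.counts, dtype=float)
    if img.size == 0 or not np.any(img):
        return ForkSet(
            pixels=np.empty((0, 2), dtype=int),
            pixel_size=image.pixel_size,
            disc_radius=disc_radius,
            min_neighbors=min_neighbors,
        )
    med = ndimage.median_filter(img, size=3, mode="constant")
    fg = med > 0
    neighbor_count = ndimage.convolve(
        fg.astype(int), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant"
    )
    med = np.where(fg & (neighbor_count >= min_neighbors), med, 0.0)
    fg = med > 0
    dilated = ndimage.grey_dilation(med, footprint=disc_footprint(disc_radius))
    maxima = fg & ((dilated - med) == 0)
    if not np.any(maxima):
        return ForkSet(
            pixels=np.empty((0, 2), dtype=int),
            pixel_size=image.pixel_size,
            disc_radius=disc_radius,
            min_neighbors=min_neighbors,
        )
    labels, n_lab = ndimage.label(maxima, structure=np.ones((3, 3), dtype=int))
    pixels = []
    for lab in range(1, n_lab + 1):
        ys, xs = np.nonzero(labels == lab)
        order = np.lexsort((xs, ys))
        pixels.append((ys[order[0]], xs[order[0]]))
    return ForkSet(
        pixels=np.array(sorted(pixels), dtype=int),
        pixel_size=image.pixel_size,
        disc_radius=disc_radius,
        min_neighbors=min_neighbors,
    )


def nnd_stats(forks: ForkSet) -> NNDDistribution:
    """Euclidean nearest-neighbor distance (nm) from each fork to its closest peer."""
    if len(forks) < 2:
        raise ValueError("NND undefined for fewer than 2 forks")
    coords = forks.coordinates_nm()
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    return NNDDistribution(distances=dist[:, 1])
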
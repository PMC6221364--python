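"""3D transcription-spot detection and nucleus birth-time estimation.

Spots are detected in 3D confocal stacks by per-slice mean filtering, a
threshold at a fixed multiple (~2x) of the background level, and 3D
connected-component labeling; only components of at least 10 connected
voxels are kept, and the spot intensity is the sum of the raw (unsmoothed)
voxel values of the component.  Nucleus birth times are read from the
sibling-separation curve after anaphase: birth is when the separation speed
first decays to near zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "estimate_background",
    "detect_spots",
    "assign_spots_to_nuclei",
    "estimate_birth_time",
    "read_stack",
    "write_stack",
]


def estimate_background(stack: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Robust background level: the median of non-spot (unmasked) voxels."""
    stack = np.asarray(stack, dtype=float)
    if stack.size == 0:
        raise ValueError("empty stack")
    if mask is not None:
        vals = stack[~np.asarray(mask, dtype=bool)]
        if vals.size == 0:
            raise ValueError("mask excludes every voxel")
    else:
        vals = stack.ravel()
    return float(np.median(vals))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def detect_spots(stack: np.ndarray, background: float | None = None,
                 k_thresh: float = 2.0, min_voxels: int = 10,
                 smooth_radius: int = 1, connectivity: int = 26,
                 frame: int | None = None) -> pd.DataFrame:
    """Detect 3D spots by smoothing, thresholding and size filtering.

    A mean filter of half-width ``smooth_radius`` is applied within each Z
    slice before thresholding at ``k_thresh * background``; components are
    found with 3D connectivity (26-connected by default) and those smaller
    than ``min_voxels`` are discarded.  Intensities are sums of the raw
    voxel values.  Returns a table (frame, z, y, x, voxel_count, intensity,
    k_thresh) sorted by intensity, brightest first.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("stack must be a non-empty 3D array")
    if background is None:
        background = estimate_background(stack)
    if background <= 0:
        raise ValueError("background must be positive")
    if smooth_radius > 0:
        size = 2 * smooth_radius + 1
        smoothed = ndimage.uniform_filter(stack, size=(1, size, size), mode="nearest")
    else:
        smoothed = stack
    binary = smoothed > k_thresh * background
    labels, n = ndimage.label(binary, structure=_connectivity_structure(connectivity))
    rows = []
    if n:
        idx = np.arange(1, n + 1)
        counts = ndimage.sum_labels(np.ones_like(stack), labels, idx)
        sums = ndimage.sum_labels(stack, labels, idx)
        centroids = ndimage.center_of_mass(stack, labels, idx)
        for c, vox, inten in zip(centroids, counts, sums):
            if vox >= min_voxels:
                rows.append({"frame": frame, "z": c[0], "y": c[1], "x": c[2],
                             "voxel_count": int(vox), "intensity": float(inten),
                             "k_thresh": k_thresh})
    df = pd.DataFrame(rows, columns=["frame", "z", "y", "x", "voxel_count",
                                     "intensity", "k_thresh"])
    return df.sort_values("intensity", ascending=False, ignore_index=True)


def assign_spots_to_nuclei(spots: pd.DataFrame, nuclei_centers: pd.DataFrame,
                           max_radius: float = 12.0) -> pd.DataFrame:
    """Assign each spot to the nearest nucleus center within ``max_radius``.

    At most one spot — the brightest — is kept per nucleus (per frame if a
    frame column is present); the others are flagged ``kept=False``.  Spots
    outside every nucleus stay unassigned and are reported with a warning.
    ``nuclei_centers`` needs columns nucleus_id, z, y, x.
    """
    spots = spots.copy()
    centers = nuclei_centers[["z", "y", "x"]].to_numpy(dtype=float)
    ids = nuclei_centers["nucleus_id"].to_numpy()
    assigned = []
    for row in spots.itertuples(index=False):
        d = np.linalg.norm(centers - np.array([row.z, row.y, row.x]), axis=1)
        j = int(np.argmin(d)) if d.size else -1
        assigned.append(ids[j] if d.size and d[j] <= max_radius else None)
    spots["nucleus_id"] = assigned
    n_orphans = sum(a is None for a in assigned)
    if n_orphans:
        warnings.warn(f"{n_orphans} spot(s) outside every nucleus left unassigned",
                      stacklevel=2)
    group_cols = ["nucleus_id"]
    if "frame" in spots and spots["frame"].notna().any():
        group_cols.append("frame")
    spots["kept"] = False
    valid = spots["nucleus_id"].notna()
    if valid.any():
        best = spots[valid].groupby(group_cols, dropna=True)["intensity"].idxmax()
        spots.loc[best.to_numpy(), "kept"] = True
    return spots


def estimate_birth_time(times: np.ndarray, distances: np.ndarray,
                        smooth_window: int = 3, near_zero_frac: float = 0.1) -> float:
    """Nucleus birth time from the sibling centroid-distance curve.

    Birth is the first time, after the peak separation speed, at which the
    smoothed derivative of the distance falls below ``near_zero_frac`` of
    that peak.  A curve still rising at the end returns the last frame with
    a warning.
    """
    times = np.asarray(times, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two frames")
    speed = np.gradient(distances, times)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        speed = np.convolve(speed, kernel, mode="same")
    peak = int(np.argmax(speed))
    if speed[peak] <= 0:
        return float(times[0])  # never separating: born at the first frame
    below = np.nonzero(speed[peak:] < near_zero_frac * speed[peak])[0]
    if below.size == 0:
        warnings.warn("separation never settles; returning the last frame",
                      stacklevel=2)
        return float(times[-1])
    i = peak + below[0]
    thresh = near_zero_frac * speed[peak]
    # interpolate the crossing and undo the moving-average group delay
    if i > 0 and speed[i - 1] != speed[i]:
        frac = (speed[i - 1] - thresh) / (speed[i - 1] - speed[i])
        t_cross = times[i - 1] + frac * (times[i] - times[i - 1])
    else:
        t_cross = times[i]
    dt = float(np.median(np.diff(times)))
    lag = 0.5 * (smooth_window - 1) * dt if smooth_window > 1 else 0.0
    return float(max(times[0], t_cross - lag))


def read_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF stack as a 3D float array."""
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_stack(path, stack: np.ndarray, voxel_size_um=(0.5, 0.2, 0.2)) -> None:
    """Write a 3D stack to TIFF with voxel-size metadata."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     metadata={"voxel_size_um": list(voxel_size_um)})
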
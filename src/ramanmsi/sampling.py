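"""AF-image segmentation, Raman sampling-point generation and frame mapping.

Auto-fluorescence gives fast, high-sensitivity but low-specificity contrast:
bright structures (tumour, epidermis, fat) stand out against dermis and
background but cannot be told apart.  The AF image is segmented by
multi-level Otsu thresholding (thresholds minimizing the pooled within-class
intensity variance) followed by connected-component splitting; Raman
sampling points are then laid out inside each segment in proportion to its
area, with a blue-noise (Poisson-disc style) spatial distribution, and
finally mapped from the AF microscope's stage frame into the Raman
instrument's frame with an affine transform fitted to brightfield landmark
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import distance_transform_edt
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels


@dataclass
class SegmentMap:
    """Integer segment-label image plus per-segment summaries.

    Label 0 is background; labels 1..n are contiguous.
    """

    labels: np.ndarray
    table: pd.DataFrame      # id, area_px, mean_af, priority
    pixel_size: float = 1.0  # um per pixel

    @property
    def n_segments(self) -> int:
        return int(self.labels.max())

    def mask(self, seg_id: int) -> np.ndarray:
        return self.labels == seg_id

    def save(self, prefix) -> None:
        tifffile.imwrite(f"{prefix}_segments.tiff",
                         self.labels.astype(np.uint16))
        self.table.to_csv(f"{prefix}_segments.csv", index=False)


@dataclass
class SamplingPoint:
    """One Raman sampling location in stage coordinates (um)."""

    x_um: float
    y_um: float
    segment_id: int = -1
    origin: str = "af"          # "af" (AF-derived) or "fill" (random padding)
    batch_id: int = -1
    zero_order: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValueError("sampling-point coordinates must be finite")


def points_to_csv(points, path) -> None:
    pd.DataFrame([{"x_um": p.x_um, "y_um": p.y_um,
                   "segment_id": p.segment_id, "origin": p.origin,
                   "batch_id": p.batch_id, "zero_order": p.zero_order}
                  for p in points]).to_csv(path, index=False)


def points_from_csv(path) -> list[SamplingPoint]:
    df = pd.read_csv(path)
    return [SamplingPoint(r.x_um, r.y_um, int(r.segment_id), r.origin,
                          int(r.batch_id), bool(r.zero_order))
            for r in df.itertuples()]


def segment_af_image(af: np.ndarray, n_levels: int = 3,
                     min_area_px: int = 32, pixel_size: float = 1.0,
                     priority_gamma: float = 1.0) -> SegmentMap:
    """Threshold-and-split segmentation maximizing intensity homogeneity.

    ``n_levels`` intensity classes are separated by thresholds that minimize
    the pooled within-class variance (multi-level Otsu); each class above
    the darkest is split into connected components, and components smaller
    than ``min_area_px`` are merged into their nearest neighbouring segment.
    The per-segment priority is (mean AF / global mean AF) ** priority_gamma,
    so bright (AF-positive) segments are sampled more densely.
    """
    af = np.asarray(af, dtype=float)
    if np.any(af < 0):
        raise ValueError("AF image must be non-negative")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if np.ptp(af) == 0 or n_levels == 1:
        warnings.warn("constant or single-level AF image: one segment")
        labels = np.ones_like(af, dtype=int)
        table = pd.DataFrame([{"id": 1, "area_px": af.size,
                               "mean_af": float(af.mean()), "priority": 1.0}])
        return SegmentMap(labels=labels, table=table, pixel_size=pixel_size)
    nbins = min(256, max(np.unique(af).size, 2))
    try:
        thresholds = threshold_multiotsu(af, classes=n_levels, nbins=nbins)
    except ValueError:
        # fewer distinct values than requested classes
        thresholds = np.unique(af)[:-1]
    bands = np.digitize(af, thresholds)
    # every intensity band becomes segments (connected components of equal
    # band value); the slide background simply ends up as dim segments that
    # the priority weighting de-emphasizes
    labels = cc_label(bands, connectivity=2, background=-1)
    # merge tiny components into their surroundings
    sizes = np.bincount(labels.ravel())
    small = np.isin(labels, np.flatnonzero(sizes < min_area_px)) & (labels > 0)
    if small.any():
        keep = labels.copy()
        keep[small] = 0
        grown = expand_labels(keep, distance=max(af.shape))
        labels[small] = grown[small]
        labels = cc_label(labels, connectivity=2, background=0)
    rows = []
    global_mean = af[labels > 0].mean() if (labels > 0).any() else 1.0
    for seg_id in range(1, labels.max() + 1):
        m = labels == seg_id
        mean_af = float(af[m].mean())
        rows.append({"id": seg_id, "area_px": int(m.sum()), "mean_af": mean_af,
                     "priority": float((mean_af / global_mean) ** priority_gamma)})
    return SegmentMap(labels=labels, table=pd.DataFrame(rows),
                      pixel_size=pixel_size)


def _blue_noise_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator,
                        pixel_size: float) -> list[tuple[float, float]]:
    """Seeded dart-throwing with a target minimum spacing (best candidate)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0 or n == 0:
        return []
    rows, cols = mask.shape
    area_um2 = idx.size * pixel_size**2
    r_target = 0.7 * np.sqrt(area_um2 / max(n, 1) / np.pi)
    chosen: list[tuple[float, float]] = []
    if n == 1:
        # single point: the segment's interior pole (deepest-inside pixel)
        dist = distance_transform_edt(mask)
        r, c = np.unravel_index(int(np.argmax(dist)), mask.shape)
        return [((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)]
    for _ in range(n):
        best, best_d = None, -1.0
        for _attempt in range(12):
            j = idx[rng.integers(idx.size)]
            r, c = divmod(int(j), cols)
            x = (c + 0.5) * pixel_size
            y = (r + 0.5) * pixel_size
            if not chosen:
                best = (x, y)
                break
            d = min((x - px) ** 2 + (y - py) ** 2 for px, py in chosen)
            if d > best_d:
                best_d, best = d, (x, y)
            if d >= r_target**2:
                break
        chosen.append(best)
    return chosen


def generate_sampling_points(seg: SegmentMap, density_per_mm2: float = 100.0,
                             min_per_segment: int = 1, seed: int = 0,
                             min_af_fraction: float = 0.1
                             ) -> list[SamplingPoint]:
    """Area-proportional, priority-weighted blue-noise sampling per segment.

    Per-segment count = max(min_per_segment, round(area * density * priority)),
    reduced to the pixel count when the segment is too small to host it.
    All points lie strictly inside their segment mask.  Segments whose mean
    AF falls below ``min_af_fraction`` of the image-wide mean are treated as
    bare substrate and receive no points (set 0 to sample everything).
    """
    if density_per_mm2 <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    global_mean = float((seg.table.mean_af * seg.table.area_px).sum()
                        / seg.table.area_px.sum())
    points: list[SamplingPoint] = []
    for row in seg.table.itertuples():
        if global_mean > 0 and row.mean_af < min_af_fraction * global_mean:
            continue
        m = seg.mask(row.id)
        area_mm2 = row.area_px * (seg.pixel_size / 1000.0) ** 2
        n = max(min_per_segment,
                int(round(area_mm2 * density_per_mm2 * row.priority)))
        if n > row.area_px:
            warnings.warn(
                f"segment {row.id} too small for {n} points; reduced")
            n = int(row.area_px)
        for x, y in _blue_noise_in_mask(m, n, rng, seg.pixel_size):
            points.append(SamplingPoint(x_um=x, y_um=y, segment_id=row.id,
                                        origin="af"))
    return points


@dataclass
class AffineMap:
    """2-D affine transform between microscope stage frames (um)."""

    linear: np.ndarray                 # 2x2
    translation: np.ndarray            # length 2
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, float).reshape(2, 2)
        self.translation = np.asarray(self.translation, float).reshape(2)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, float))
        return xy @ self.linear.T + self.translation

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.linear)
        return AffineMap(linear=inv, translation=-inv @ self.translation,
                         residual_rms=self.residual_rms)


def fit_coordinate_transform(src: np.ndarray, dst: np.ndarray) -> AffineMap:
    """Least-squares affine fit of matched landmark pairs (>= 3, non-collinear).

    Absorbs the magnification difference between the AF and Raman
    microscopes into the linear part; shear is allowed because stitched
    brightfield mosaics may be slightly non-rigid.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("landmark arrays must both be (n, 2)")
    n = src.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 landmark pairs, got {n}")
    a = np.hstack([src, np.ones((n, 1))])
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("landmarks are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(a, dst, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    fitted = a @ coef
    rms = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    return AffineMap(linear=linear, translation=translation, residual_rms=rms)


def landmark_pairs_to_csv(src: np.ndarray, dst: np.ndarray, path) -> None:
    pd.DataFrame({"src_x_um": src[:, 0], "src_y_um": src[:, 1],
                  "dst_x_um": dst[:, 0], "dst_y_um": dst[:, 1]}
                 ).to_csv(path, index=False)


def landmark_pairs_from_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df[["src_x_um", "src_y_um"]].to_numpy(),
            df[["dst_x_um", "dst_y_um"]].to_numpy())
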
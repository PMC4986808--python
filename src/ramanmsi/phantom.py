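"""Synthetic tissue phantoms and per-class Raman spectral bases.

The spectral library holds one basis spectrum per tissue class, built as a
sum of Gaussian bands on a shared 1 cm^-1 wavenumber grid.  Band positions
follow the biochemistry of skin: BCC is enriched in nucleic-acid bands
(O-P-O symmetric stretch at 788 cm^-1, PO2- stretch at 1098 cm^-1), dermis
is dominated by collagen (proline/hydroxyproline at 851 and 950 cm^-1), and
lipid-rich structures (fat, sebaceous glands) show strong C-H/C-C/C=C bands
(850, 1070, 1267, 1301, 1450, ~1660 cm^-1).  The phenylalanine ring-breathing
band near 1004 cm^-1 and the CH2 deformation at 1450 cm^-1 appear in every
tissue class.

The tissue phantom is a pair of co-registered images: an integer class-label
image and an auto-fluorescence (AF) intensity image.  AF contrast is drawn
so that tumour (BCC), epidermis and fat overlap in intensity — AF detects
those structures with high sensitivity but cannot tell them apart (low
specificity) — while dermis and background are darker.  A dye-contamination
mask marks tumour-adjacent pixels carrying the surgical marking dyes that
add a strong fluorescence background to the Raman spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml
from scipy.ndimage import binary_dilation, distance_transform_edt, gaussian_filter

# class coding shared across the whole package
CLASS_NAMES = ("background", "BCC", "epidermis", "dermis", "fat", "dye")
CLASS_IDS = {name: i for i, name in enumerate(CLASS_NAMES)}

WAVENUMBER_MIN = 260.0
WAVENUMBER_MAX = 1900.0

#: default band tables: (center cm^-1, FWHM cm^-1, relative amplitude)
DEFAULT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "BCC": [
        (788.0, 10.0, 1.00),   # O-P-O symmetric stretch (DNA backbone)
        (1004.0, 8.0, 0.55),   # phenylalanine
        (1098.0, 12.0, 0.85),  # PO2- stretch
        (1245.0, 20.0, 0.50),  # amide III
        (1304.0, 14.0, 0.45),  # CH2 twist
        (1450.0, 16.0, 0.70),  # CH2 deformation
        (1660.0, 20.0, 0.80),  # amide I
    ],
    "epidermis": [
        (852.0, 10.0, 0.25),
        (935.0, 12.0, 0.30),
        (1004.0, 8.0, 0.90),
        (1033.0, 10.0, 0.40),
        (1245.0, 18.0, 0.55),
        (1301.0, 14.0, 0.30),  # CH2 twist
        (1450.0, 16.0, 0.80),
        (1660.0, 20.0, 0.90),
    ],
    "dermis": [
        (817.0, 10.0, 0.30),
        (851.0, 10.0, 0.90),   # proline
        (880.0, 12.0, 0.40),
        (950.0, 12.0, 0.80),   # hydroxyproline
        (1004.0, 8.0, 0.45),
        (1033.0, 10.0, 0.35),
        (1245.0, 18.0, 0.80),  # amide III (collagen)
        (1271.0, 14.0, 0.60),
        (1305.0, 14.0, 0.30),  # CH2 twist
        (1450.0, 16.0, 0.60),
        (1660.0, 18.0, 0.85),
    ],
    "fat": [
        (850.0, 10.0, 0.35),
        (1070.0, 12.0, 0.60),  # C-C stretch
        (1130.0, 12.0, 0.40),
        (1267.0, 12.0, 0.50),  # =C-H deformation
        (1301.0, 12.0, 0.90),  # CH2 twist
        (1450.0, 14.0, 1.00),  # CH2 scissoring
        (1660.0, 14.0, 0.75),  # C=C stretch
        (1745.0, 12.0, 0.30),  # ester carbonyl
    ],
    # the dye contributes mostly broad fluorescence; its weak Raman signature
    # is a pair of very broad humps
    "dye": [
        (1350.0, 320.0, 0.30),
        (1590.0, 120.0, 0.25),
    ],
    "background": [],
}

#: relative fluorescence-baseline scale per class (dye is dominated by it)
BASELINE_SCALES: dict[str, float] = {
    "background": 0.05,
    "BCC": 0.70,
    "epidermis": 0.50,
    "dermis": 0.40,
    "fat": 0.30,
    "dye": 6.00,
}

#: AF intensity distributions per class (mean, SD) on a 16-bit scale.
#: BCC / epidermis / fat are drawn from overlapping distributions by
#: construction: AF alone cannot separate them.
AF_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "background": (300.0, 60.0),
    "BCC": (13000.0, 2500.0),
    "epidermis": (12000.0, 2500.0),
    "dermis": (3000.0, 700.0),
    "fat": (11500.0, 2500.0),
    "dye": (14000.0, 2500.0),
}

#: polystyrene fingerprint reference bands used for wavenumber calibration
POLYSTYRENE_PEAKS_CM1 = (620.9, 1001.4, 1031.8, 1155.3, 1583.1)
MGF2_PEAK_CM1 = 320.0


def gaussian_band(axis: np.ndarray, center: float, fwhm: float,
                  amplitude: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2)


@dataclass
class SpectralLibrary:
    """Per-class Raman basis spectra on a shared 1 cm^-1 wavenumber grid."""

    axis: np.ndarray
    basis: dict[str, np.ndarray]
    bands: dict[str, list[tuple[float, float, float]]]
    baseline_scales: dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_SCALES))

    def __post_init__(self) -> None:
        for name, spec in self.basis.items():
            if spec.shape != self.axis.shape:
                raise ValueError(f"basis for {name!r} not on the shared axis")
            if np.any(spec < -1e-12):
                raise ValueError(f"basis for {name!r} has negative intensities")

    def classes(self) -> list[str]:
        return list(self.basis)

    def fluorescence_baseline(self, class_name: str) -> np.ndarray:
        """Broad class-scaled fluorescence baseline (4th-order polynomial)."""
        u = (self.axis - WAVENUMBER_MIN) / (WAVENUMBER_MAX - WAVENUMBER_MIN)
        shape = 1.0 - 0.9 * u + 0.55 * u**2 - 0.25 * u**3 + 0.05 * u**4
        return self.baseline_scales.get(class_name, 0.0) * shape

    def save_yaml(self, path) -> None:
        payload = {
            "bands": {c: [list(b) for b in bl] for c, bl in self.bands.items()},
            "baseline_scales": self.baseline_scales,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


class BandOutsideAxisError(ValueError):
    """A band centre lies outside the shared wavenumber axis."""


def build_spectral_library(
    band_overrides: Mapping[str, Sequence[tuple[float, float, float]]] | None = None,
    axis: np.ndarray | None = None,
) -> SpectralLibrary:
    """Build the per-class basis spectra as sums of Gaussian bands.

    ``band_overrides`` replaces the band table of individual classes; an
    empty table yields a flat zero basis for that class.  Band centres must
    lie on the shared axis, widths must be positive and amplitudes
    non-negative.
    """
    if axis is None:
        axis = np.arange(WAVENUMBER_MIN, WAVENUMBER_MAX + 0.5, 1.0)
    bands = {c: list(t) for c, t in DEFAULT_BANDS.items()}
    if band_overrides:
        for cls, table in band_overrides.items():
            bands[cls] = [tuple(b) for b in table]
    basis: dict[str, np.ndarray] = {}
    for cls, table in bands.items():
        spec = np.zeros_like(axis)
        for center, fwhm, amp in table:
            if not (axis[0] <= center <= axis[-1]):
                raise BandOutsideAxisError(
                    f"band centre {center} cm^-1 for class {cls!r} outside "
                    f"axis [{axis[0]}, {axis[-1]}]")
            if fwhm <= 0:
                raise ValueError(f"band width must be positive, got {fwhm}")
            if amp < 0:
                raise ValueError(f"band amplitude must be >= 0, got {amp}")
            spec += gaussian_band(axis, center, fwhm, amp)
        basis[cls] = spec
    return SpectralLibrary(axis=axis, basis=basis, bands=bands)


def polystyrene_spectrum(axis: np.ndarray) -> np.ndarray:
    """Polystyrene reference: five fingerprint bands used for calibration."""
    amps = (0.6, 1.0, 0.5, 0.35, 0.7)
    spec = np.zeros_like(axis)
    for c, a in zip(POLYSTYRENE_PEAKS_CM1, amps):
        spec += gaussian_band(axis, c, 8.0, a)
    return spec


def mgf2_peak(axis: np.ndarray, amplitude: float = 1.2) -> np.ndarray:
    """MgF2 substrate band at 320 cm^-1 used for per-beam shift correction."""
    return gaussian_band(axis, MGF2_PEAK_CM1, 10.0, amplitude)


# --------------------------------------------------------------------------
# tissue phantom


@dataclass
class TissuePhantom:
    """Co-registered class-label image, AF image and dye-contamination mask."""

    label: np.ndarray          # integer class per pixel (CLASS_IDS coding)
    af: np.ndarray             # non-negative AF intensity, 16-bit range
    dye_mask: np.ndarray       # bool; dye contamination overlay
    pixel_size: float          # um per pixel
    seed: int

    def __post_init__(self) -> None:
        if self.label.shape != self.af.shape or self.label.shape != self.dye_mask.shape:
            raise ValueError("label, AF and dye images must share one shape")
        if np.any(self.af < 0):
            raise ValueError("AF intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label.shape

    def size_um(self) -> tuple[float, float]:
        return (self.shape[1] * self.pixel_size, self.shape[0] * self.pixel_size)

    def class_at(self, x_um: float, y_um: float) -> int:
        """Class id under a stage coordinate (pixel centres at half-integers)."""
        col = int(np.clip(np.floor(x_um / self.pixel_size), 0, self.shape[1] - 1))
        row = int(np.clip(np.floor(y_um / self.pixel_size), 0, self.shape[0] - 1))
        return int(self.label[row, col])

    def dye_at(self, x_um: float, y_um: float) -> bool:
        col = int(np.clip(np.floor(x_um / self.pixel_size), 0, self.shape[1] - 1))
        row = int(np.clip(np.floor(y_um / self.pixel_size), 0, self.shape[0] - 1))
        return bool(self.dye_mask[row, col])

    def save(self, prefix) -> None:
        tifffile.imwrite(f"{prefix}_label.tiff", self.label.astype(np.uint16))
        tifffile.imwrite(f"{prefix}_af.tiff",
                         np.clip(self.af, 0, 65535).astype(np.uint16))
        tifffile.imwrite(f"{prefix}_dye.tiff", self.dye_mask.astype(np.uint16))

    @classmethod
    def load(cls, prefix, pixel_size: float, seed: int = 0) -> "TissuePhantom":
        return cls(
            label=tifffile.imread(f"{prefix}_label.tiff").astype(int),
            af=tifffile.imread(f"{prefix}_af.tiff").astype(float),
            dye_mask=tifffile.imread(f"{prefix}_dye.tiff").astype(bool),
            pixel_size=pixel_size,
            seed=seed,
        )


def _rasterize(region: Mapping, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one layout region to a boolean mask (pixel units)."""
    rows, cols = shape
    kind = region.get("shape", "rect")
    yy, xx = np.mgrid[0:rows, 0:cols]
    # pixel centres at half-integers
    yc, xc = yy + 0.5, xx + 0.5
    if kind == "rect":
        x0, y0, w, h = (region["x"], region["y"],
                        region["width"], region["height"])
        if w <= 0 or h <= 0:
            raise ValueError(f"zero-area rect region: {region}")
        mask = (xc >= x0) & (xc < x0 + w) & (yc >= y0) & (yc < y0 + h)
    elif kind == "disk":
        cx, cy, r = region["cx"], region["cy"], region["radius"]
        if r <= 0:
            raise ValueError(f"zero-area disk region: {region}")
        mask = (xc - cx) ** 2 + (yc - cy) ** 2 <= r**2
    elif kind == "annulus":
        cx, cy = region["cx"], region["cy"]
        r_in, r_out = region["r_inner"], region["r_outer"]
        if r_out <= r_in:
            raise ValueError(f"zero-area annulus region: {region}")
        d2 = (xc - cx) ** 2 + (yc - cy) ** 2
        mask = (d2 > r_in**2) & (d2 <= r_out**2)
    else:
        raise ValueError(f"unknown region shape {kind!r}")
    if not mask.any():
        raise ValueError(f"region rasterizes to zero pixels: {region}")
    return mask


def render_phantom(layout_spec: Mapping, pixel_size: float = 4.0,
                   seed: int = 0) -> TissuePhantom:
    """Render a phantom from a region-list layout (deterministic per seed).

    ``layout_spec`` keys: ``shape`` (rows, cols); ``regions``: ordered list of
    region dicts with ``class`` plus geometry in pixel units (later regions
    overwrite earlier ones); optional ``dye_fraction`` (fraction of
    tumour-adjacent pixels contaminated) and ``dye_halo_um``.
    """
    shape = tuple(layout_spec.get("shape", (256, 256)))
    regions = layout_spec.get("regions", [])
    rng = np.random.default_rng(seed)
    label = np.zeros(shape, dtype=int)
    for region in regions:
        cls = region["class"]
        if cls not in CLASS_IDS:
            raise ValueError(f"unknown tissue class {cls!r}")
        label[_rasterize(region, shape)] = CLASS_IDS[cls]

    af = np.zeros(shape, dtype=float)
    for cls, cid in CLASS_IDS.items():
        mask = label == cid
        if not mask.any():
            continue
        mean, sd = AF_DISTRIBUTIONS[cls]
        af[mask] = rng.normal(mean, sd, size=int(mask.sum()))
    af = gaussian_filter(af, sigma=1.0)
    af = np.clip(af, 0.0, 65535.0)

    dye_fraction = float(layout_spec.get("dye_fraction", 0.0))
    dye_halo_um = float(layout_spec.get("dye_halo_um", 20.0))
    dye_mask = np.zeros(shape, dtype=bool)
    if dye_fraction > 0:
        bcc = label == CLASS_IDS["BCC"]
        if bcc.any():
            halo_px = max(int(round(dye_halo_um / pixel_size)), 1)
            near = binary_dilation(bcc, iterations=halo_px) & (label > 0)
            idx = np.flatnonzero(near)
            take = rng.choice(idx, size=int(round(dye_fraction * idx.size)),
                              replace=False)
            dye_mask.flat[take] = True
    return TissuePhantom(label=label, af=af, dye_mask=dye_mask,
                         pixel_size=pixel_size, seed=seed)


def default_layout(shape: tuple[int, int] = (256, 256)) -> dict:
    """A ~1 mm^2 skin-resection phantom: dermis bulk, epidermis band,
    BCC nodules, fat lobules, and dye contamination around the tumour."""
    rows, cols = shape
    return {
        "shape": [rows, cols],
        "dye_fraction": 0.25,
        "dye_halo_um": 20.0,
        "regions": [
            {"class": "dermis", "shape": "rect", "x": cols * 0.05,
             "y": rows * 0.08, "width": cols * 0.9, "height": rows * 0.86},
            {"class": "epidermis", "shape": "rect", "x": cols * 0.05,
             "y": rows * 0.08, "width": cols * 0.9, "height": rows * 0.10},
            {"class": "BCC", "shape": "disk", "cx": cols * 0.32,
             "cy": rows * 0.40, "radius": rows * 0.10},
            {"class": "BCC", "shape": "disk", "cx": cols * 0.52,
             "cy": rows * 0.30, "radius": rows * 0.06},
            {"class": "fat", "shape": "disk", "cx": cols * 0.72,
             "cy": rows * 0.68, "radius": rows * 0.11},
            {"class": "fat", "shape": "disk", "cx": cols * 0.28,
             "cy": rows * 0.76, "radius": rows * 0.08},
        ],
    }


def interior_pole(mask: np.ndarray) -> tuple[int, int]:
    """(row, col) of the deepest-inside pixel of a boolean mask."""
    dist = distance_transform_edt(mask)
    return np.unravel_index(int(np.argmax(dist)), mask.shape)
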
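"""CCD track extraction, wavenumber calibration and spectral preprocessing.

The detector records each beam's dispersed spectrum on two adjacent CCD
rows ("tracks").  The chain applied to every beam is: sum the two tracks
(removing cosmic-ray hits by track disagreement), convert the pixel axis to
relative wavenumber with a cubic calibration fitted to five polystyrene
reference peaks, correct the per-beam dispersion offset with the 320 cm^-1
MgF2 substrate band, crop to the stored range (520-1830 cm^-1) on a shared
1 cm^-1 grid, and normalize to zero mean / unit standard deviation (SNV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .phantom import MGF2_PEAK_CM1, POLYSTYRENE_PEAKS_CM1

STORE_RANGE_CM1 = (520.0, 1830.0)
CLASSIFY_RANGE_CM1 = (600.0, 1800.0)


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationModel:
    """Cubic pixel-column -> relative-wavenumber map for the spectrometer.

    Fitted to reference peaks of a polystyrene sample measured with the
    0th-order beam; must be strictly monotone across the detector.
    """

    coeffs: np.ndarray                      # ascending powers, length 4
    residual_rms: float = 0.0
    reference_peaks: list[tuple[float, float]] = field(default_factory=list)
    n_columns: int = 1024

    def wavenumber(self, columns) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(columns, float),
                                                self.coeffs)

    def column(self, wavenumbers) -> np.ndarray:
        """Inverse map via dense monotone interpolation."""
        cols = np.arange(self.n_columns, dtype=float)
        nu = self.wavenumber(cols)
        return np.interp(np.asarray(wavenumbers, float), nu, cols)

    def check_monotone(self) -> None:
        cols = np.arange(self.n_columns, dtype=float)
        d = np.diff(self.wavenumber(cols))
        if np.any(d <= 0):
            bad = int(np.argmax(d <= 0))
            raise CalibrationError(
                f"calibration not strictly monotone between columns "
                f"{bad} and {bad + 1}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"coeffs": list(self.coeffs),
                       "residual_rms": self.residual_rms,
                       "reference_peaks": self.reference_peaks,
                       "n_columns": self.n_columns}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(coeffs=np.asarray(d["coeffs"], float),
                   residual_rms=d["residual_rms"],
                   reference_peaks=[tuple(p) for p in d["reference_peaks"]],
                   n_columns=d["n_columns"])


def default_true_calibration(n_columns: int = 1024) -> CalibrationModel:
    """The simulator's ground-truth dispersion: a gently nonlinear cubic
    covering roughly 260-1936 cm^-1 over 1024 columns."""
    return CalibrationModel(coeffs=np.array([260.0, 1.72, -1.0e-4, 2.0e-8]),
                            n_columns=n_columns)


def calibrate_axis(peak_pixels: Sequence[float],
                   peak_wavenumbers: Sequence[float] = POLYSTYRENE_PEAKS_CM1,
                   n_columns: int = 1024) -> CalibrationModel:
    """Least-squares cubic fit of reference peak positions.

    Needs at least 4 distinct peaks (5 polystyrene fingerprint bands at
    default); the fitted polynomial must be strictly monotone over the
    detector width.
    """
    px = np.asarray(peak_pixels, float)
    nu = np.asarray(peak_wavenumbers, float)
    if px.size != nu.size:
        raise CalibrationError("peak pixel and wavenumber lists differ in length")
    if np.unique(px).size < 4:
        raise CalibrationError(
            f"need >= 4 distinct reference peaks for a cubic fit, got {px.size}")
    if np.any(px < 0) or np.any(px >= n_columns):
        raise CalibrationError("reference peak pixel outside the detector")
    coeffs = np.polynomial.polynomial.polyfit(px, nu, 3)
    fitted = np.polynomial.polynomial.polyval(px, coeffs)
    model = CalibrationModel(
        coeffs=coeffs,
        residual_rms=float(np.sqrt(np.mean((fitted - nu) ** 2))),
        reference_peaks=list(zip(px.tolist(), nu.tolist())),
        n_columns=n_columns,
    )
    model.check_monotone()
    return model


@dataclass
class Spectrum:
    """One beam's spectrum with acquisition provenance and QC flags."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)
    track_a: np.ndarray | None = None
    track_b: np.ndarray | None = None
    saturated: bool = False
    no_substrate_peak: bool = False
    cosmic_corrected: bool = False
    shift_cm1: float = 0.0

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if self.wavenumber.size > 1 and np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber axis must be strictly ascending")


def extract_tracks(frame, bias: float = 0.0) -> list[Spectrum]:
    """Per-beam track sums on a pixel-column axis.

    For each beam in the frame's track layout, the two rows are summed and
    shifted back by the beam's dispersion column offset so that all beams
    share the reference (0-offset) column axis; out-of-range columns read 0.
    A constant detector bias per track is subtracted first.
    """
    counts = np.asarray(frame.counts, float)
    rows, cols = counts.shape
    used: set[int] = set()
    out: list[Spectrum] = []
    for beam in frame.layout:
        r1, r2, off = beam.row1, beam.row2, beam.col_offset
        if not (0 <= r1 < rows and 0 <= r2 < rows):
            raise ValueError(
                f"track rows ({r1}, {r2}) outside frame with {rows} rows")
        for r in (r1, r2):
            if r in used:
                raise ValueError(f"track row {r} assigned to two beams")
            used.add(r)
        a = np.zeros(cols)
        b = np.zeros(cols)
        src = np.arange(cols) + off
        ok = (src >= 0) & (src < cols)
        a[ok] = counts[r1, src[ok]] - bias
        b[ok] = counts[r2, src[ok]] - bias
        meta = {"member_idx": beam.member_idx, "batch_id": beam.batch_id,
                "order": beam.order, "rows": (r1, r2), "col_offset": off}
        out.append(Spectrum(wavenumber=np.arange(cols, dtype=float),
                            intensity=a + b, meta=meta,
                            track_a=a, track_b=b,
                            saturated=bool(counts[[r1, r2]].max()
                                           >= frame.full_well)))
    return out


def remove_cosmic_rays(track_a: np.ndarray, track_b: np.ndarray,
                       read_noise: float = 5.0, k: float = 6.0
                       ) -> tuple[np.ndarray, bool]:
    """Despiked track sum using two-track redundancy.

    Both tracks view the same spectrum, so a cosmic-ray hit appears in one
    track only: where the tracks disagree beyond ``k`` times the expected
    shot+read noise of their difference, the sum is replaced by twice the
    lower track.  Spikes that happen to hit both tracks at the same column
    are caught by a 5-point rolling-median fallback on the sum.

    Returns (cleaned sum, whether anything was corrected).
    """
    from scipy.ndimage import median_filter

    a = np.asarray(track_a, float)
    b = np.asarray(track_b, float)
    sigma = np.sqrt(np.clip(a, 0, None) + np.clip(b, 0, None)
                    + 2.0 * read_noise**2)
    spike = np.abs(a - b) > k * sigma
    total = a + b
    total[spike] = 2.0 * np.minimum(a, b)[spike]
    corrected = bool(spike.any())
    # coincident spikes: compare against local median of the cleaned sum
    med = median_filter(total, size=5, mode="nearest")
    resid = total - med
    sigma_sum = np.sqrt(np.clip(med, 0, None) + 4.0 * read_noise**2)
    coincident = resid > 2 * k * sigma_sum
    if coincident.any():
        total[coincident] = med[coincident]
        corrected = True
    return total, corrected


def despike(s: Spectrum, read_noise: float = 5.0, k: float = 6.0) -> Spectrum:
    """Cosmic-ray removal applied to a Spectrum carrying its two tracks."""
    if s.track_a is None or s.track_b is None:
        return s
    cleaned, corrected = remove_cosmic_rays(s.track_a, s.track_b,
                                            read_noise=read_noise, k=k)
    out = replace(s, intensity=cleaned)
    out.cosmic_corrected = corrected
    return out


def apply_calibration(s: Spectrum, calib: CalibrationModel) -> Spectrum:
    """Replace the pixel-column axis with calibrated relative wavenumbers."""
    calib.check_monotone()
    return replace(s, wavenumber=calib.wavenumber(s.wavenumber))


def correct_shift_mgf2(s: Spectrum, window_cm1: float = 40.0,
                       prominence_factor: float = 4.0,
                       reference_cm1: float = MGF2_PEAK_CM1) -> Spectrum:
    """Align the axis on the 320 cm^-1 MgF2 substrate band.

    The local maximum inside the search window is refined by quadratic
    sub-bin interpolation and the whole axis translated so the peak lands at
    ``reference_cm1``.  The default reference is the nominal 320 cm^-1; in a
    calibrated workflow, pass the *apparent* substrate-peak position of the
    0th-order calibration spectrum instead, so that all beams are aligned to
    the reference beam's axis without importing the calibration's
    extrapolation error at the low-wavenumber end.  If no sufficiently
    prominent peak exists the spectrum is flagged ``no_substrate_peak`` and
    returned unshifted.
    """
    lo, hi = reference_cm1 - window_cm1, reference_cm1 + window_cm1
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if mask.sum() < 5:
        raise ValueError("axis does not cover the MgF2 search window")
    win = s.intensity[mask]
    nu = s.wavenumber[mask]
    i = int(np.argmax(win))
    edge_level = np.median(win)
    noise = np.std(np.diff(win)) / np.sqrt(2.0) + 1e-12
    if win[i] - edge_level < prominence_factor * noise or i in (0, win.size - 1):
        out = replace(s)
        out.no_substrate_peak = True
        return out
    # quadratic interpolation through the 3 samples around the maximum
    y0, y1, y2 = win[i - 1], win[i], win[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    step = nu[i + 1] - nu[i] if delta >= 0 else nu[i] - nu[i - 1]
    peak_nu = nu[i] + delta * step
    shift = reference_cm1 - peak_nu
    out = replace(s, wavenumber=s.wavenumber + shift)
    out.shift_cm1 = float(shift)
    return out


def crop_range(s: Spectrum, lo: float = STORE_RANGE_CM1[0],
               hi: float = STORE_RANGE_CM1[1]) -> Spectrum:
    """Crop to [lo, hi] and resample onto the shared 1 cm^-1 grid.

    Every beam ends up with an identical axis (and hence identical length)
    regardless of its dispersion offset.
    """
    if s.wavenumber[0] > lo or s.wavenumber[-1] < hi:
        raise ValueError(
            f"axis [{s.wavenumber[0]:.1f}, {s.wavenumber[-1]:.1f}] does not "
            f"cover the crop range [{lo}, {hi}]")
    grid = np.arange(lo, hi + 0.5, 1.0)
    return replace(s, wavenumber=grid,
                   intensity=np.interp(grid, s.wavenumber, s.intensity),
                   track_a=None, track_b=None)


def snv_normalize(s: Spectrum) -> Spectrum:
    """Standard normal variate: zero mean, unit standard deviation."""
    sd = float(np.std(s.intensity))
    if sd == 0:
        raise ValueError("cannot SNV-normalize a constant spectrum")
    return replace(s, intensity=(s.intensity - np.mean(s.intensity)) / sd)


def qc_saturation(s: Spectrum, full_well: float | None = None) -> bool:
    """True if the raw counts touched the detector's full well."""
    if full_well is not None and s.track_a is not None:
        return bool(max(s.track_a.max(), s.track_b.max()) >= full_well)
    return s.saturated


def compute_snr(s: Spectrum, band_cm1: tuple[float, float] = (1440.0, 1460.0),
                noise_cm1: tuple[float, float] = (1490.0, 1510.0)) -> float:
    """SNR of the 1450 cm^-1 band.

    Signal: baseline-subtracted maximum inside 1440-1460 cm^-1, the local
    linear baseline being anchored at the mean of the 3 samples at each
    window edge.  Noise: RMS of the linearly detrended 1490-1510 cm^-1
    region.  Returns +inf for a noiseless spectrum.
    """
    nu, y = s.wavenumber, s.intensity
    bm = (nu >= band_cm1[0]) & (nu <= band_cm1[1])
    nm = (nu >= noise_cm1[0]) & (nu <= noise_cm1[1])
    if bm.sum() < 7 or nm.sum() < 5:
        raise ValueError("axis does not cover the SNR windows")
    bw, bn = y[bm], nu[bm]
    left = (np.mean(bn[:3]), np.mean(bw[:3]))
    right = (np.mean(bn[-3:]), np.mean(bw[-3:]))
    slope = (right[1] - left[1]) / (right[0] - left[0])
    baseline = left[1] + slope * (bn - left[0])
    signal = float(np.max(bw - baseline))
    nn, nw = nu[nm], y[nm]
    p = np.polynomial.polynomial.polyfit(nn, nw, 1)
    resid = nw - np.polynomial.polynomial.polyval(nn, p)
    noise = float(np.sqrt(np.mean(resid**2)))
    if noise <= 1e-9 * max(abs(signal), 1.0):
        return np.inf
    return signal / noise


def preprocess_frame(frame, calib: CalibrationModel,
                     read_noise: float = 5.0,
                     crop: tuple[float, float] = STORE_RANGE_CM1,
                     mgf2_reference_cm1: float = MGF2_PEAK_CM1,
                     ) -> list[Spectrum]:
    """Full per-frame chain: extract -> despike -> calibrate -> MgF2 shift ->
    crop.  SNV is left to the caller (SNR is computed pre-normalization)."""
    spectra = []
    for s in extract_tracks(frame, bias=frame.bias):
        s = despike(s, read_noise=read_noise)
        s = apply_calibration(s, calib)
        s = correct_shift_mgf2(s, reference_cm1=mgf2_reference_cm1)
        s = crop_range(s, *crop)
        spectra.append(s)
    return spectra
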
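"""Forward simulation of multifocal CCD acquisitions.

One exposure records a whole batch: every beam illuminates one sampling
point, its Raman emission (class basis + fluorescence baseline + optional
dye emission + MgF2 substrate band) is broadened by the pseudo-slit kernel,
dispersed through the spectrometer's cubic pixel/wavenumber map with a
per-beam column offset, and written onto two adjacent CCD rows.  Photon
shot noise (Poisson), Gaussian read noise, a constant bias, cosmic-ray
spikes and full-well clipping complete the detector model.

Power sharing: the undiffracted 0th-order beam carries 10x the throughput
of the strongest 1st-order beam, and 1st-order throughput falls off
quadratically towards the edge of the 180 x 60 um field of view (to 0.1 of
its central value), emulating hologram efficiency loss plus vignetting in
the collection path.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

from .phantom import CLASS_NAMES, SpectralLibrary, mgf2_peak, polystyrene_spectrum
from .readout import CalibrationModel, Spectrum, default_true_calibration


@dataclass
class AcquisitionConfig:
    """Instrument model parameters (defaults emulate the reference setup)."""

    ccd_rows: int = 256
    ccd_cols: int = 1024
    integration_time: float = 2.0        # s
    readout_rate: str = "50 kHz"
    zero_order_weight: float = 10.0      # relative throughput of the 0th order
    first_order_edge_ratio: float = 0.1  # 1st-order weight at the FOV edge
    fov_width_um: float = 180.0
    fov_height_um: float = 60.0
    slit_fwhm_cm1: float = 6.0           # pseudo-slit spectral broadening
    full_well: int = 65535
    read_noise: float = 5.0              # counts RMS
    bias: float = 100.0                  # counts
    cosmic_ray_rate: float = 2.0         # expected events per frame
    fluorescence_scale: float = 1.0
    substrate_peak: bool = True          # MgF2 320 cm^-1 band
    gain: float = 800.0                  # counts per basis unit per s (track sum)
    rows_per_um: float = 256.0 / 60.0
    cols_per_um: float = 0.1            # dispersion-direction offset scale
    dispersion_jitter_cm1: float = 2.0   # per-beam residual shift (uniform +/-)
    noise: bool = True
    inject_saturation: bool = False      # burn one signal pixel to full well

    def __post_init__(self) -> None:
        if self.full_well <= 0:
            raise ValueError("full_well must be positive")
        if self.zero_order_weight <= 0:
            raise ValueError("zero_order_weight must be positive")

    def first_order_weight(self, x_local: float, y_local: float) -> float:
        """Quadratic radial falloff of 1st-order throughput across the FOV."""
        rho2 = ((x_local / (self.fov_width_um / 2.0)) ** 2
                + (y_local / (self.fov_height_um / 2.0)) ** 2)
        rho2 = min(rho2, 1.0)
        return 1.0 - (1.0 - self.first_order_edge_ratio) * rho2

    def beam_weight(self, x_local: float, y_local: float,
                    zero_order: bool) -> float:
        if zero_order:
            return self.zero_order_weight
        return self.first_order_weight(x_local, y_local)


@dataclass(frozen=True)
class TrackAssignment:
    """Where one beam lands on the CCD: a row pair plus a column offset."""

    member_idx: int
    row1: int
    row2: int
    col_offset: int
    order: int = 1
    batch_id: int = -1


@dataclass
class CCDFrame:
    """Simulated 256 x 1024 detector image with its track layout."""

    counts: np.ndarray
    layout: list[TrackAssignment]
    full_well: int
    bias: float
    seed: int

    def save(self, prefix) -> None:
        tifffile.imwrite(f"{prefix}.tiff", self.counts.astype(np.uint16))
        with open(f"{prefix}_layout.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["beam_id", "row1", "row2", "col_offset", "order",
                        "batch_id"])
            for t in self.layout:
                w.writerow([t.member_idx, t.row1, t.row2, t.col_offset,
                            t.order, t.batch_id])

    @classmethod
    def load(cls, prefix, full_well: int = 65535, bias: float = 100.0,
             seed: int = 0) -> "CCDFrame":
        counts = tifffile.imread(f"{prefix}.tiff")
        layout = []
        with open(f"{prefix}_layout.csv") as fh:
            for row in csv.DictReader(fh):
                layout.append(TrackAssignment(
                    member_idx=int(row["beam_id"]), row1=int(row["row1"]),
                    row2=int(row["row2"]), col_offset=int(row["col_offset"]),
                    order=int(row["order"]), batch_id=int(row["batch_id"])))
        return cls(counts=counts, layout=layout, full_well=full_well,
                   bias=bias, seed=seed)


@dataclass(frozen=True)
class BeamSpec:
    """One beam of a batch, resolved to a sample class and FOV offsets."""

    member_idx: int
    x_local: float          # um from the FOV centre (dispersion direction)
    y_local: float          # um from the FOV centre (CCD row direction)
    class_name: str
    zero_order: bool = False
    dyed: bool = False
    batch_id: int = -1
    weight_override: float | None = None


def equalize_beam_weights(beams, cfg) -> list["BeamSpec"]:
    """Blazing-equalized power sharing: redistribute the batch's total
    throughput evenly over its beams (what an optimized blazing level
    achieves for <= 10 beams)."""
    from dataclasses import replace as _replace

    total = sum(cfg.beam_weight(b.x_local, b.y_local, b.zero_order)
                for b in beams)
    w = total / len(beams)
    return [_replace(b, weight_override=w) for b in beams]


def beams_from_batch(batch, phantom) -> list[BeamSpec]:
    """Resolve a planned batch against a phantom into beam specifications."""
    tx, ty = batch.stage_target
    beams = []
    for i, m in enumerate(batch.members):
        cid = phantom.class_at(m.x_um, m.y_um)
        beams.append(BeamSpec(
            member_idx=i,
            x_local=m.x_um - tx,
            y_local=m.y_um - ty,
            class_name=CLASS_NAMES[cid],
            zero_order=(i == batch.zero_order_index),
            dyed=phantom.dye_at(m.x_um, m.y_um),
            batch_id=batch.batch_id,
        ))
    return beams


def _slit_kernel(fwhm_cm1: float, step_cm1: float = 1.0) -> np.ndarray:
    """Normalized Gaussian broadening kernel on the 1 cm^-1 grid."""
    sigma = fwhm_cm1 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / step_cm1
    half = max(int(np.ceil(4 * sigma)), 1)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def emission_spectrum(class_name: str, lib: SpectralLibrary,
                      cfg: AcquisitionConfig, dyed: bool = False) -> np.ndarray:
    """Slit-broadened emission (basis units) on the library axis."""
    if class_name == "polystyrene":
        em = polystyrene_spectrum(lib.axis)
        em = em + 0.05 * cfg.fluorescence_scale
    else:
        if class_name not in lib.basis:
            raise ValueError(f"unknown class {class_name!r}")
        em = lib.basis[class_name].copy()
        em = em + cfg.fluorescence_scale * lib.fluorescence_baseline(class_name)
        if dyed:
            em = em + cfg.fluorescence_scale * lib.fluorescence_baseline("dye")
            em = em + lib.basis["dye"]
    if cfg.substrate_peak:
        em = em + mgf2_peak(lib.axis)
    return np.convolve(em, _slit_kernel(cfg.slit_fwhm_cm1), mode="same")


def expected_track_counts(beam: BeamSpec, lib: SpectralLibrary,
                          cfg: AcquisitionConfig, calib: CalibrationModel,
                          jitter_cm1: float = 0.0) -> np.ndarray:
    """Noise-free expected counts per track at each detector column.

    The emission is evaluated at the wavenumber each (offset-shifted) column
    disperses to; each of the two tracks receives half of the summed-track
    rate ``gain * weight * t_int * S(nu)``.
    """
    weight = (beam.weight_override if beam.weight_override is not None
              else cfg.beam_weight(beam.x_local, beam.y_local, beam.zero_order))
    col_offset = int(round(beam.x_local * cfg.cols_per_um))
    cols = np.arange(cfg.ccd_cols, dtype=float)
    nu = calib.wavenumber(cols - col_offset) + jitter_cm1
    em = emission_spectrum(beam.class_name, lib, cfg, beam.dyed)
    s = np.interp(nu, lib.axis, em, left=0.0, right=0.0)
    return 0.5 * cfg.gain * weight * cfg.integration_time * s


def assign_tracks(beams: Sequence[BeamSpec], cfg: AcquisitionConfig
                  ) -> list[TrackAssignment]:
    """Map FOV-local beam offsets onto disjoint CCD row pairs."""
    layout = []
    used_rows: dict[int, int] = {}
    for beam in beams:
        if abs(beam.x_local) > cfg.fov_width_um / 2 + 1e-9 or \
                abs(beam.y_local) > cfg.fov_height_um / 2 + 1e-9:
            raise ValueError(
                f"beam {beam.member_idx} at local offset "
                f"({beam.x_local:.1f}, {beam.y_local:.1f}) um outside the FOV")
        row = int(round(cfg.ccd_rows / 2 + beam.y_local * cfg.rows_per_um))
        row = int(np.clip(row, 0, cfg.ccd_rows - 2))
        for r in (row, row + 1):
            if r in used_rows:
                raise ValueError(
                    f"CCD row collision between beams {used_rows[r]} and "
                    f"{beam.member_idx} at row {r}")
            used_rows[r] = beam.member_idx
        layout.append(TrackAssignment(
            member_idx=beam.member_idx, row1=row, row2=row + 1,
            col_offset=int(round(beam.x_local * cfg.cols_per_um)),
            order=0 if beam.zero_order else 1, batch_id=beam.batch_id))
    return layout


def simulate_ccd_frame(beams: Sequence[BeamSpec], lib: SpectralLibrary,
                       cfg: AcquisitionConfig,
                       calib: CalibrationModel | None = None,
                       seed: int = 0) -> CCDFrame:
    """Simulate one multifocal exposure (all beams in a single frame).

    Deterministic for a fixed seed.  With ``cfg.noise`` disabled the frame
    holds the expected counts plus bias, exactly.
    """
    if calib is None:
        calib = default_true_calibration(cfg.ccd_cols)
    rng = np.random.default_rng(seed)
    layout = assign_tracks(beams, cfg)
    expected = np.zeros((cfg.ccd_rows, cfg.ccd_cols), dtype=float)
    for beam, tr in zip(beams, layout):
        jitter = (rng.uniform(-cfg.dispersion_jitter_cm1,
                              cfg.dispersion_jitter_cm1)
                  if cfg.noise and cfg.dispersion_jitter_cm1 > 0 else 0.0)
        per_track = expected_track_counts(beam, lib, cfg, calib, jitter)
        expected[tr.row1] += per_track
        expected[tr.row2] += per_track
    if cfg.noise:
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, cfg.read_noise, size=counts.shape)
        counts += cfg.bias
        n_cosmic = rng.poisson(cfg.cosmic_ray_rate)
        if n_cosmic:
            rr = rng.integers(0, cfg.ccd_rows, size=n_cosmic)
            cc = rng.integers(0, cfg.ccd_cols, size=n_cosmic)
            amp = rng.uniform(0.2, 1.0, size=n_cosmic) * cfg.full_well
            counts[rr, cc] += amp
    else:
        counts = expected + cfg.bias
    if cfg.inject_saturation and layout:
        tr = layout[0]
        col = int(np.argmax(expected[tr.row1]))
        counts[tr.row1, col] = cfg.full_well
    counts = np.clip(np.round(counts), 0, cfg.full_well)
    return CCDFrame(counts=counts.astype(np.uint16), layout=layout,
                    full_well=cfg.full_well, bias=cfg.bias, seed=seed)


def simulate_class_spectra(class_name: str, n: int, lib: SpectralLibrary,
                           cfg: AcquisitionConfig, seed: int = 0,
                           weight: float = 1.0, dyed: bool = False,
                           analysis_calib: CalibrationModel | None = None
                           ) -> list[Spectrum]:
    """Simulate n single-beam spectra of one class, skipping CCD geometry.

    The emission is sampled on the spectrometer's pixel columns through the
    instrument's true dispersion (so band shapes carry the same pixelization
    as frame-extracted spectra) and the detector noise model matches the
    frame simulator: two Poisson tracks plus read noise, summed.

    The returned wavenumber axis is assigned by ``analysis_calib`` — pass
    the calibration fitted from the polystyrene reference to put these
    spectra on exactly the same (slightly imperfect) axis as preprocessed
    measurements; the default is the true dispersion.
    """
    true = default_true_calibration(cfg.ccd_cols)
    if analysis_calib is None:
        analysis_calib = true
    rng = np.random.default_rng(seed)
    em = emission_spectrum(class_name, lib, cfg, dyed)
    cols = np.arange(cfg.ccd_cols, dtype=float)
    s = np.interp(true.wavenumber(cols), lib.axis, em, left=0.0, right=0.0)
    rate = 0.5 * cfg.gain * weight * cfg.integration_time * s
    nu = analysis_calib.wavenumber(cols)
    out = []
    for _ in range(n):
        if cfg.noise:
            a = rng.poisson(rate) + rng.normal(0, cfg.read_noise, rate.size)
            b = rng.poisson(rate) + rng.normal(0, cfg.read_noise, rate.size)
            y = a + b
        else:
            y = 2.0 * rate
        out.append(Spectrum(wavenumber=nu.copy(), intensity=y,
                            meta={"class": class_name, "weight": weight}))
    return out
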
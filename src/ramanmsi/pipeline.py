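"""End-to-end orchestration: simulate -> segment -> plan -> acquire ->
preprocess -> train -> diagnose, with one global seed and a run manifest.

Every stage writes its artifact in the package's standard formats (TIFF /
CSV / JSON / YAML / PNG) so stages can also be run individually from the
command line; the manifest records the batch accounting, per-batch SNR
summaries, the acquisition-time estimate, per-segment calls and the
confusion matrix against the phantom's ground truth.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as cl
from . import phantom as ph
from . import planner as pl
from . import readout as ro
from . import sampling as sm
from .acquisition import (AcquisitionConfig, beams_from_batch,
                          simulate_ccd_frame, simulate_class_spectra)
from .hologram import SpotPattern, optimize_uniformity

log = logging.getLogger("ramanmsi")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    layout: dict = field(default_factory=ph.default_layout)
    pixel_size_um: float = 4.0
    seed: int = 0
    outdir: str = "runs/demo"
    # segmentation
    n_levels: int = 3
    min_area_px: int = 50
    # sampling
    density_per_mm2: float = 60.0
    min_per_segment: int = 1
    priority_gamma: float = 1.0
    # planning
    geometry: pl.FOVGeometry = field(default_factory=pl.FOVGeometry)
    # acquisition
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    # classifier
    n_train_per_class: int = 300
    target_sensitivity: float = 0.95
    cv_folds: int = 5
    # diagnostics
    hologram_check: bool = False
    hologram_shape: int = 256

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        geom = pl.FOVGeometry(**raw.pop("geometry", {}))
        acq_cfg = AcquisitionConfig(**raw.pop("acquisition", {}))
        return cls(geometry=geom, acquisition=acq_cfg, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _stage_seed(seed: int, stage: int, item: int = 0) -> int:
    return int((seed * 1_000_003 + stage * 7919 + item) % (2**31 - 1))


def fit_instrument_calibration(cfg: AcquisitionConfig, seed: int = 0
                               ) -> tuple[ro.CalibrationModel, float]:
    """Calibrate the wavenumber axis from a simulated polystyrene exposure.

    A 0th-order-only polystyrene frame is simulated with the instrument's
    (hidden) true dispersion; the five reference peaks are located by
    quadratic sub-pixel interpolation around each expected position and a
    cubic is fitted through them.

    Returns the fitted model together with the *apparent* position of the
    MgF2 substrate band on the fitted axis.  The cubic extrapolates poorly
    below the lowest polystyrene peak, so the substrate band does not appear
    at exactly 320 cm^-1 on the fitted axis; per-beam shift correction must
    align to this apparent position, which cancels the extrapolation error
    instead of propagating it into every spectrum.
    """
    from .acquisition import BeamSpec

    true = ro.default_true_calibration(cfg.ccd_cols)
    lib = ph.build_spectral_library()
    beam = BeamSpec(member_idx=0, x_local=0.0, y_local=0.0,
                    class_name="polystyrene", zero_order=True)
    import dataclasses

    quiet = dataclasses.replace(cfg, dispersion_jitter_cm1=0.0,
                                cosmic_ray_rate=0.0)
    frame = simulate_ccd_frame([beam], lib, quiet, true,
                               seed=_stage_seed(seed, 1))
    spec = ro.despike(ro.extract_tracks(frame, bias=cfg.bias)[0],
                      read_noise=cfg.read_noise)
    px = []
    for nu_ref in ph.POLYSTYRENE_PEAKS_CM1:
        guess = int(round(float(true.column(nu_ref))))
        lo, hi = max(guess - 10, 1), min(guess + 11, cfg.ccd_cols - 1)
        window = spec.intensity[lo:hi]
        i = int(np.argmax(window)) + lo
        y0, y1, y2 = spec.intensity[i - 1:i + 2]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        px.append(i + delta)
    model = ro.calibrate_axis(px, ph.POLYSTYRENE_PEAKS_CM1, cfg.ccd_cols)
    ref = ro.apply_calibration(spec, model)
    ref_shifted = ro.correct_shift_mgf2(ref)
    if ref_shifted.no_substrate_peak:
        return model, ph.MGF2_PEAK_CM1
    # apparent position = nominal minus the shift that would move it there
    return model, ph.MGF2_PEAK_CM1 - ref_shifted.shift_cm1


def train_from_library(lib: ph.SpectralLibrary, cfg: AcquisitionConfig,
                       n_per_class: int = 300, seed: int = 0,
                       target_sensitivity: float = 0.95, folds: int = 5,
                       calib: ro.CalibrationModel | None = None,
                       mgf2_reference_cm1: float = ph.MGF2_PEAK_CM1
                       ) -> cl.ClassifierModel:
    """Fit the 3-class model on simulated spectra of the library classes.

    The training spectra are put through the same analysis chain as the
    multiplexed measurements — fitted wavenumber calibration, MgF2 shift
    correction, crop, SNV — so band windows land identically in both paths.
    """
    feats, labels = [], []
    for i, cls_name in enumerate(cl.MODEL_CLASSES):
        for s in simulate_class_spectra(cls_name, n_per_class, lib, cfg,
                                        seed=_stage_seed(seed, 2, i),
                                        analysis_calib=calib):
            s = ro.correct_shift_mgf2(s, reference_cm1=mgf2_reference_cm1)
            s = ro.crop_range(s, *ro.CLASSIFY_RANGE_CM1)
            s = ro.snv_normalize(s)
            feats.append(cl.spectrum_features(s))
            labels.append(cls_name)
    return cl.train_classifier(np.asarray(feats), labels, folds=folds,
                               target_sensitivity=target_sensitivity,
                               seed=_stage_seed(seed, 3))


def _segment_truth(seg: sm.SegmentMap, phantom: ph.TissuePhantom) -> dict[int, str]:
    """Majority phantom class per AF segment (the simulation ground truth)."""
    truth = {}
    for seg_id in range(1, seg.n_segments + 1):
        m = seg.labels == seg_id
        if not m.any():
            continue
        counts = np.bincount(phantom.label[m], minlength=len(ph.CLASS_NAMES))
        # dye contamination dominates a segment's spectra once most pixels
        # carry dye
        if phantom.dye_mask[m].mean() > 0.5:
            truth[seg_id] = "dye"
        else:
            truth[seg_id] = ph.CLASS_NAMES[int(np.argmax(counts))]
    return truth


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the whole workflow; returns (and writes) the run manifest."""
    t_start = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {"seed": seed, "outdir": str(out)}
    stage = "configure"
    try:
        config.to_yaml(out / "config.yaml")

        stage = "simulate-phantom"
        phantom = ph.render_phantom(config.layout, config.pixel_size_um,
                                    seed=_stage_seed(seed, 0))
        phantom.save(out / "phantom")
        lib = ph.build_spectral_library()
        lib.save_yaml(out / "spectral_library.yaml")

        stage = "calibrate"
        calib, mgf2_ref = fit_instrument_calibration(config.acquisition, seed)
        calib.to_json(out / "calibration.json")
        manifest["calibration_residual_rms_cm1"] = calib.residual_rms
        manifest["mgf2_apparent_cm1"] = mgf2_ref

        stage = "segment"
        seg = sm.segment_af_image(phantom.af, n_levels=config.n_levels,
                                  min_area_px=config.min_area_px,
                                  pixel_size=config.pixel_size_um,
                                  priority_gamma=config.priority_gamma)
        seg.save(out / "af")
        manifest["n_segments"] = seg.n_segments

        stage = "sample"
        points = sm.generate_sampling_points(
            seg, density_per_mm2=config.density_per_mm2,
            min_per_segment=config.min_per_segment,
            seed=_stage_seed(seed, 4))
        sm.points_to_csv(points, out / "sampling_points.csv")
        manifest["n_af_points"] = len(points)

        stage = "plan"
        plan = pl.plan_batches(points, config.geometry,
                               seed=_stage_seed(seed, 5),
                               integration_time=config.acquisition.integration_time)
        plan.to_csv(out / "batch_plan.csv")
        plan.to_json(out / "batch_plan.json")
        plan_summary = plan.summary()
        plan_summary["plan_seed"] = plan_summary.pop("seed")
        manifest.update(plan_summary)
        manifest["acquisition_time_s"] = pl.estimate_acquisition_time(plan)
        manifest["acquisition_time_with_overheads_s"] = \
            pl.estimate_acquisition_time(plan, overhead_multiplier=2.0)

        if config.hologram_check and plan.batches:
            stage = "hologram"
            b = plan.batches[0]
            scale = config.hologram_shape / 4.0 / (config.geometry.fov_width_um / 2)
            offsets = [((m.x_um - b.stage_target[0]) * scale,
                        (m.y_um - b.stage_target[1]) * scale)
                       for i, m in enumerate(b.members)
                       if i != b.zero_order_index]
            _, ratio = optimize_uniformity(SpotPattern.from_offsets(offsets),
                                           shape=config.hologram_shape)
            manifest["hologram_uniformity_ratio"] = float(ratio)

        stage = "acquire+preprocess"
        frames_dir = out / "frames"
        frames_dir.mkdir(exist_ok=True)
        spectra = []
        snr_mins = []
        for b in plan.batches:
            beams = beams_from_batch(b, phantom)
            frame = simulate_ccd_frame(beams, lib, config.acquisition,
                                       seed=_stage_seed(seed, 6, b.batch_id))
            frame.save(frames_dir / f"batch_{b.batch_id:04d}")
            batch_spectra = ro.preprocess_frame(
                frame, calib, read_noise=config.acquisition.read_noise,
                mgf2_reference_cm1=mgf2_ref)
            snrs = [ro.compute_snr(s) for s in batch_spectra]
            finite = [v for v in snrs if np.isfinite(v)]
            if finite:
                snr_mins.append(min(finite))
            for s, snr in zip(batch_spectra, snrs):
                m = b.members[s.meta["member_idx"]]
                s.meta.update(x_um=m.x_um, y_um=m.y_um,
                              segment_id=_segment_at(seg, m, config))
                s.meta["snr"] = snr
                spectra.append(s)
        manifest["n_spectra"] = len(spectra)
        manifest["snr_batch_min_mean"] = (float(np.mean(snr_mins))
                                          if snr_mins else None)
        manifest["n_saturated"] = int(sum(s.saturated for s in spectra))
        _write_spectra_tsv(spectra, out / "spectra.tsv")

        stage = "train"
        model = train_from_library(lib, config.acquisition,
                                   n_per_class=config.n_train_per_class,
                                   seed=seed,
                                   target_sensitivity=config.target_sensitivity,
                                   folds=config.cv_folds, calib=calib,
                                   mgf2_reference_cm1=mgf2_ref)
        model.to_json(out / "classifier.json")
        rep = model.cv_report[model.cv_report.C == model.C]
        manifest["cv_sensitivity"] = float(rep.sensitivity.mean())
        manifest["cv_specificity"] = float(rep.specificity.mean())

        stage = "diagnose"
        kept = [s for s in spectra if not s.saturated]
        norm = []
        for s in kept:
            c = ro.crop_range(s, *ro.CLASSIFY_RANGE_CM1)
            norm.append(ro.snv_normalize(c))
        screen = cl.pca_screen(np.array([s.intensity for s in norm]), lib,
                               axis=norm[0].wavenumber) if len(norm) >= 10 \
            else np.full(len(norm), "keep", dtype=object)
        # diagnosis covers the segments the AF planner targeted; spectra of
        # fill points landing elsewhere (e.g. bare substrate) are dropped
        sampled_segments = {p.segment_id for p in points}
        by_segment: dict[int, list] = {}
        screen_by_segment: dict[int, list] = {}
        for s, flag in zip(norm, screen):
            sid = int(s.meta["segment_id"])
            if sid not in sampled_segments:
                continue
            by_segment.setdefault(sid, []).append(s)
            screen_by_segment.setdefault(sid, []).append(flag)
        diag = cl.segment_average_classify(
            by_segment, model, segment_labels=seg.labels, lib=lib,
            screen_labels={k: np.array(v, dtype=object)
                           for k, v in screen_by_segment.items()})
        diag.save(out / "run")
        diag.render_png(out / "diagnosis.png")

        stage = "evaluate"
        truth = _segment_truth(seg, phantom)
        calls = {int(r.segment_id): r.call for r in diag.calls.itertuples()}
        measured = {sid: c for sid, c in calls.items()
                    if c != "none" and sid in truth}
        agree = sum(truth[sid] == c for sid, c in measured.items())
        manifest["n_measured_segments"] = len(measured)
        manifest["segment_accuracy"] = (agree / len(measured)
                                        if measured else None)
        confusion = pd.crosstab(
            pd.Series({sid: truth[sid] for sid in measured}, name="truth"),
            pd.Series(measured, name="call"), dropna=False)
        manifest["confusion"] = {str(t): {str(c): int(v) for c, v in row.items()}
                                 for t, row in confusion.iterrows()}
    except Exception as err:
        log.error("stage %r failed: %s", stage, err)
        raise PipelineError(stage, str(err)) from err

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


def _segment_at(seg: sm.SegmentMap, point, config: RunConfig) -> int:
    col = int(np.clip(point.x_um / config.pixel_size_um, 0,
                      seg.labels.shape[1] - 1))
    row = int(np.clip(point.y_um / config.pixel_size_um, 0,
                      seg.labels.shape[0] - 1))
    return int(seg.labels[row, col])


def _write_spectra_tsv(spectra, path) -> None:
    if not spectra:
        return
    nu = spectra[0].wavenumber
    cols = {"batch_id": [s.meta.get("batch_id", -1) for s in spectra],
            "member_idx": [s.meta.get("member_idx", -1) for s in spectra],
            "order": [s.meta.get("order", 1) for s in spectra],
            "segment_id": [s.meta.get("segment_id", -1) for s in spectra],
            "snr": [s.meta.get("snr", np.nan) for s in spectra],
            "saturated": [s.saturated for s in spectra],
            "shift_cm1": [s.shift_cm1 for s in spectra]}
    mat = pd.DataFrame(np.array([s.intensity for s in spectra]),
                       columns=[f"{v:.0f}" for v in nu])
    pd.concat([pd.DataFrame(cols), mat], axis=1).to_csv(path, sep="\t",
                                                        index=False)
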
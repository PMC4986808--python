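"""Band-area ratio features and the multinomial tissue classifier.

The diagnostic model works on seven band areas integrated after local
linear baseline subtraction:

    A1 = 772-800   cm^-1   (DNA O-P-O backbone; elevated in BCC)
    A2 = 843-865   cm^-1   (proline / collagen)
    A3 = 825-946   cm^-1   (collagen envelope; overlaps A2 as defined)
    A4 = 993-1022  cm^-1   (phenylalanine; shared reference band)
    A5 = 1070-1115 cm^-1   (PO2- / C-C stretch)
    A6 = 1235-1279 cm^-1   (amide III)
    A7 = 1279-1327 cm^-1   (CH2 twist region)

and the five ratios {A1/A4, A2/A4, A3/A4, A5/A4, A6/A7}, which are
invariant to positive scaling and to any additive straight line per
spectrum.  Saturated spectra are discarded by QC; dye- and fat-dominated
spectra are screened out on principal-component scores 2 and 3; the
remaining three classes (BCC, epidermis, dermis) are separated by a
multinomial logistic regression whose BCC decision threshold is tuned to a
target sensitivity (95% by default) under 5-fold cross-validation.
Spectra measured within one AF segment are averaged into a single spectrum
before classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .phantom import CLASS_IDS, SpectralLibrary
from .readout import Spectrum

BAND_WINDOWS_CM1: dict[str, tuple[float, float]] = {
    "A1": (772.0, 800.0),
    "A2": (843.0, 865.0),
    "A3": (825.0, 946.0),   # overlaps A2 as defined; used literally
    "A4": (993.0, 1022.0),
    "A5": (1070.0, 1115.0),
    "A6": (1235.0, 1279.0),
    "A7": (1279.0, 1327.0),
}

RATIO_DEFS = (("A1", "A4"), ("A2", "A4"), ("A3", "A4"), ("A5", "A4"),
              ("A6", "A7"))

MODEL_CLASSES = ("BCC", "epidermis", "dermis")


class UnclassifiableSpectrum(ValueError):
    """A ratio denominator band has zero area."""


@dataclass
class BandFeatureSet:
    """Band areas (intensity * cm^-1) plus the five diagnostic ratios."""

    areas: dict[str, float]

    def ratios(self) -> np.ndarray:
        out = []
        for num, den in RATIO_DEFS:
            d = self.areas[den]
            if d == 0:
                raise UnclassifiableSpectrum(
                    f"band {den} has zero area; ratio {num}/{den} undefined")
            out.append(self.areas[num] / d)
        return np.asarray(out)


def _local_baseline_area(nu: np.ndarray, y: np.ndarray, lo: float, hi: float,
                         n_edge: int = 3) -> float:
    m = (nu >= lo) & (nu <= hi)
    if m.sum() < 2 * n_edge:
        raise ValueError(f"axis does not cover band window {lo}-{hi} cm^-1")
    wn, wy = nu[m], y[m]
    x0, y0 = float(np.mean(wn[:n_edge])), float(np.mean(wy[:n_edge]))
    x1, y1 = float(np.mean(wn[-n_edge:])), float(np.mean(wy[-n_edge:]))
    slope = (y1 - y0) / (x1 - x0)
    resid = wy - (y0 + slope * (wn - x0))
    return float(np.trapezoid(resid, wn))


def band_areas(s: Spectrum) -> BandFeatureSet:
    """Integrate the seven diagnostic bands after local linear baselines.

    Each window's baseline is the straight line through the means of the 3
    samples at either window edge; the residual is trapezoid-integrated.
    Straight-line spectra therefore have zero area in every band.
    """
    areas = {}
    for name, (lo, hi) in BAND_WINDOWS_CM1.items():
        areas[name] = _local_baseline_area(s.wavenumber, s.intensity, lo, hi)
    return BandFeatureSet(areas=areas)


def feature_ratios(f: BandFeatureSet) -> np.ndarray:
    """The five ratios {A1/A4, A2/A4, A3/A4, A5/A4, A6/A7}, in order."""
    return f.ratios()


def spectrum_features(s: Spectrum) -> np.ndarray:
    return feature_ratios(band_areas(s))


# --------------------------------------------------------------------------
# PCA screen for dye / fat spectra


def pca_screen(spectra: np.ndarray, lib: SpectralLibrary | None = None,
               axis: np.ndarray | None = None, mad_factor: float = 3.0
               ) -> np.ndarray:
    """Label each (normalized) spectrum 'keep', 'dye' or 'fat'.

    With a spectral library available (the usual case in this simulated
    workflow), every spectrum is compared by normalized correlation against
    the dye-fluorescence signature, the lipid basis and the three modelled
    tissue classes; it is screened out as 'dye' or 'fat' when one of those
    contamination templates is its nearest match.  Principal-component
    scores 2 and 3 are always computed; without a library they are the sole
    screening mechanism: spectra whose PC2/PC3 score deviates from the
    component median by more than ``mad_factor`` robust standard deviations
    (1.4826 * MAD) are removed as unknown contamination ('dye').  Component
    signs are fixed by making each loading's largest-magnitude element
    positive, so labels are reproducible.
    """
    x = np.asarray(spectra, float)
    if x.ndim != 2:
        raise ValueError("spectra must be a 2-D matrix (n_spectra x n_points)")
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"PCA screen needs >= 10 spectra, got {n}")
    pca = PCA(n_components=3, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_
    # deterministic sign convention
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]

    labels = np.full(n, "keep", dtype=object)

    if lib is None:
        # no signatures available: PC2/PC3 outliers are removed as unknown
        # contamination
        for comp in (1, 2):
            sc = scores[:, comp]
            med = float(np.median(sc))
            mad = float(np.median(np.abs(sc - med))) * 1.4826 + 1e-12
            out = np.abs(sc - med) > mad_factor * mad
            labels[out & (labels == "keep")] = "dye"
        return labels

    grid = axis if axis is not None else lib.axis

    def _template(vec: np.ndarray) -> np.ndarray:
        t = np.interp(grid, lib.axis, vec)
        return (t - t.mean()) / (t.std() + 1e-12)

    t_fat = _template(lib.basis["fat"] + lib.fluorescence_baseline("fat"))
    t_dye = _template(lib.fluorescence_baseline("dye") + lib.basis["dye"])
    tissue = [_template(lib.basis[c] + lib.fluorescence_baseline(c))
              for c in MODEL_CLASSES]
    for i in range(n):
        v = x[i]
        v = (v - v.mean()) / (v.std() + 1e-12)
        c_fat = float(np.corrcoef(v, t_fat)[0, 1])
        c_dye = float(np.corrcoef(v, t_dye)[0, 1])
        c_tissue = max(float(np.corrcoef(v, t)[0, 1]) for t in tissue)
        best = max(c_fat, c_dye, c_tissue)
        if best == c_tissue:
            continue
        labels[i] = "fat" if c_fat >= c_dye else "dye"
    return labels


def cluster_reference_map(spectra: np.ndarray, k: int, seed: int = 0,
                          grid_shape: tuple[int, int] | None = None
                          ) -> np.ndarray:
    """k-means cluster labels for a raster-scanned reference map.

    ``spectra`` is (n_pixels x n_points), row-major over the raster grid
    (64 x 64 for a 960 x 960 um^2 map at 15 um steps); the labels are
    reshaped to ``grid_shape`` when given.  Used to build training labels by
    comparison against an adjacent annotated section.
    """
    x = np.asarray(spectra, float)
    if k == 1:
        lab = np.zeros(x.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(x)
    if grid_shape is not None:
        lab = lab.reshape(grid_shape)
    return lab


# --------------------------------------------------------------------------
# multinomial logistic model with sensitivity-targeted threshold


@dataclass
class ClassifierModel:
    """Multinomial logistic regression over the 5 band ratios.

    ``threshold``: a spectrum is called BCC iff P(BCC) >= threshold (tuned
    to the target sensitivity on training folds); otherwise the call is the
    argmax over the remaining classes.
    """

    coef: np.ndarray
    intercept: np.ndarray
    classes: tuple[str, ...]
    threshold: float
    C: float
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    cv_report: pd.DataFrame | None = None
    target_sensitivity: float = 0.95

    def _standardize(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(features)
        if self.feature_mean is not None:
            x = (x - self.feature_mean) / self.feature_scale
        return x

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = self._standardize(features) @ self.coef.T + self.intercept
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def classify(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Class calls and P(BCC) for a feature matrix."""
        p = self.predict_proba(features)
        i_bcc = self.classes.index("BCC")
        p_bcc = p[:, i_bcc]
        others = [i for i in range(len(self.classes)) if i != i_bcc]
        calls = np.empty(p.shape[0], dtype=object)
        is_bcc = p_bcc >= self.threshold
        calls[is_bcc] = "BCC"
        rest = np.argmax(p[:, others], axis=1)
        for r, i in enumerate(others):
            calls[(~is_bcc) & (rest == r)] = self.classes[i]
        return calls, p_bcc

    def to_json(self, path) -> None:
        payload = {"coef": self.coef.tolist(),
                   "intercept": self.intercept.tolist(),
                   "classes": list(self.classes), "threshold": self.threshold,
                   "C": self.C,
                   "feature_mean": (self.feature_mean.tolist()
                                    if self.feature_mean is not None else None),
                   "feature_scale": (self.feature_scale.tolist()
                                     if self.feature_scale is not None else None),
                   "target_sensitivity": self.target_sensitivity,
                   "cv_report": (self.cv_report.to_dict("records")
                                 if self.cv_report is not None else None)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(coef=np.asarray(d["coef"]),
                   intercept=np.asarray(d["intercept"]),
                   classes=tuple(d["classes"]), threshold=d["threshold"],
                   C=d["C"],
                   feature_mean=(np.asarray(d["feature_mean"])
                                 if d.get("feature_mean") is not None else None),
                   feature_scale=(np.asarray(d["feature_scale"])
                                  if d.get("feature_scale") is not None else None),
                   cv_report=(pd.DataFrame(d["cv_report"])
                              if d["cv_report"] else None),
                   target_sensitivity=d["target_sensitivity"])


def _tune_threshold(p_bcc: np.ndarray, is_bcc: np.ndarray,
                    target: float) -> float:
    """Largest threshold keeping BCC sensitivity >= target on these data."""
    pos = np.sort(p_bcc[is_bcc])
    if pos.size == 0:
        return 0.5
    # sensitivity >= target  <=>  threshold <= the (1-target) quantile
    idx = int(np.floor((1.0 - target) * pos.size))
    idx = min(idx, pos.size - 1)
    thr = float(pos[idx])
    return min(max(thr, 1e-6), 1.0 - 1e-6)


def _robust_standardizer(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median / MAD-based centre and scale (heavy ratio tails resistant)."""
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0) * 1.4826
    mad[mad == 0] = 1.0
    return med, mad


def _fit_logistic(x: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    return LogisticRegression(C=C, max_iter=2000).fit(x, y)


def train_classifier(features: np.ndarray, labels, folds: int = 5,
                     target_sensitivity: float = 0.95, seed: int = 0,
                     C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
                     ) -> ClassifierModel:
    """Train the 3-class model with sensitivity-targeted threshold tuning.

    For each regularization strength C, stratified 5-fold CV is run: on each
    fold the model is fitted to the training part, the BCC threshold is
    tuned on the *training* part to the target sensitivity, and fold
    sensitivity/specificity (BCC vs all others) are evaluated on the held
    out part.  The C maximizing mean fold specificity subject to mean fold
    sensitivity >= target wins (falling back to best sensitivity if no C
    qualifies).  The final model refits on all data with the winning C and
    tunes its threshold on all data.
    """
    x = np.asarray(features, float)
    y = np.asarray(labels, dtype=object)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    present = set(y)
    if len(present) < 3:
        raise ValueError(f"need all 3 classes present, got {sorted(present)}")
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise ValueError("a class has fewer samples than CV folds; "
                         "stratified folding impossible")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for C in C_grid:
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            mu, sc = _robust_standardizer(x[tr])
            xtr = (x[tr] - mu) / sc
            xte = (x[te] - mu) / sc
            clf = _fit_logistic(xtr, y[tr], C)
            i_bcc = list(clf.classes_).index("BCC")
            thr = _tune_threshold(clf.predict_proba(xtr)[:, i_bcc],
                                  y[tr] == "BCC", target_sensitivity)
            p_te = clf.predict_proba(xte)[:, i_bcc]
            is_bcc = y[te] == "BCC"
            sens = float(np.mean(p_te[is_bcc] >= thr)) if is_bcc.any() else np.nan
            spec = float(np.mean(p_te[~is_bcc] < thr)) if (~is_bcc).any() else np.nan
            rows.append({"C": C, "fold": fold, "sensitivity": sens,
                         "specificity": spec, "threshold": thr})
    report = pd.DataFrame(rows)
    means = report.groupby("C")[["sensitivity", "specificity"]].mean()
    ok = means[means["sensitivity"] >= target_sensitivity]
    if len(ok):
        best_C = float(ok["specificity"].idxmax())
    else:
        warnings.warn("no regularization strength reached the target "
                      "sensitivity in CV; choosing the most sensitive")
        best_C = float(means["sensitivity"].idxmax())
    mu, sc = _robust_standardizer(x)
    clf = _fit_logistic((x - mu) / sc, y, best_C)
    i_bcc = list(clf.classes_).index("BCC")
    thr = _tune_threshold(clf.predict_proba((x - mu) / sc)[:, i_bcc],
                          y == "BCC", target_sensitivity)
    return ClassifierModel(coef=clf.coef_, intercept=clf.intercept_,
                           classes=tuple(clf.classes_), threshold=thr,
                           C=best_C, feature_mean=mu, feature_scale=sc,
                           cv_report=report,
                           target_sensitivity=target_sensitivity)


def classify(model: ClassifierModel, features: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Class call and P(BCC) per feature row (threshold rule for BCC)."""
    return model.classify(features)


# --------------------------------------------------------------------------
# segment-averaged diagnosis


@dataclass
class DiagnosisMap:
    """Per-segment diagnosis rendered over an AF segment map."""

    calls: pd.DataFrame          # segment_id, call, p_bcc, n_spectra
    label_image: np.ndarray      # class id per pixel (0 where unmeasured)
    class_ids: dict = field(default_factory=lambda: dict(CLASS_IDS))

    def save(self, prefix) -> None:
        import tifffile

        self.calls.to_csv(f"{prefix}_diagnosis.csv", index=False)
        tifffile.imwrite(f"{prefix}_diagnosis.tiff",
                         self.label_image.astype(np.uint16))

    def render_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        cmap = ListedColormap(["black", "red", "orange", "steelblue",
                               "gold", "magenta"])
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(self.label_image, cmap=cmap, vmin=0, vmax=5,
                  interpolation="nearest")
        ax.set_title("segment-averaged diagnosis")
        ax.axis("off")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def segment_average_classify(spectra_by_segment: dict[int, list[Spectrum]],
                             model: ClassifierModel,
                             segment_labels: np.ndarray | None = None,
                             lib: SpectralLibrary | None = None,
                             screen_labels: dict[int, np.ndarray] | None = None,
                             ) -> DiagnosisMap:
    """Average each segment's surviving spectra and classify the mean.

    QC-failed (saturated) spectra are dropped first.  If a PCA screen
    labelling is provided and a majority of a segment's surviving spectra
    are flagged dye or fat, the segment is called that class directly (those
    spectra never reach the 3-class model, mirroring the screening order of
    the processing chain).  Segments with no surviving spectra are marked
    unmeasured (call 'none').
    """
    rows = []
    seg_class = {}
    for seg_id, spectra in sorted(spectra_by_segment.items()):
        alive = [s for s in spectra if not s.saturated]
        flags = None
        if screen_labels is not None and seg_id in screen_labels:
            flags = np.asarray(screen_labels[seg_id], dtype=object)
            if flags.size != len(alive):
                raise ValueError(
                    f"screen labels for segment {seg_id} do not match its "
                    f"surviving spectra")
        if not alive:
            rows.append({"segment_id": seg_id, "call": "none",
                         "p_bcc": np.nan, "n_spectra": 0})
            continue
        if flags is not None:
            for special in ("dye", "fat"):
                if np.mean(flags == special) >= 0.5:
                    rows.append({"segment_id": seg_id, "call": special,
                                 "p_bcc": np.nan, "n_spectra": len(alive)})
                    seg_class[seg_id] = special
                    break
            else:
                special = None
            if special is not None and seg_class.get(seg_id) == special:
                continue
            kept = [s for s, f in zip(alive, flags) if f == "keep"]
            alive = kept or alive
        mean = np.mean([s.intensity for s in alive], axis=0)
        avg = replace(alive[0], intensity=mean)
        try:
            feats = spectrum_features(avg)
        except UnclassifiableSpectrum:
            rows.append({"segment_id": seg_id, "call": "none",
                         "p_bcc": np.nan, "n_spectra": len(alive)})
            continue
        call, p_bcc = model.classify(feats[None, :])
        rows.append({"segment_id": seg_id, "call": str(call[0]),
                     "p_bcc": float(p_bcc[0]), "n_spectra": len(alive)})
        seg_class[seg_id] = str(call[0])
    calls = pd.DataFrame(rows)
    if segment_labels is not None:
        img = np.zeros_like(segment_labels, dtype=int)
        for seg_id, cls in seg_class.items():
            img[segment_labels == seg_id] = CLASS_IDS.get(cls, 0)
    else:
        img = np.zeros((1, 1), dtype=int)
    return DiagnosisMap(calls=calls, label_image=img)
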
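"""Phase-only hologram synthesis for multifocal beam patterns.

A liquid-crystal spatial light modulator (SLM) displays a phase pattern
:math:`\\phi(x, y)`; the sample plane sees the optical Fourier transform of
the unit-amplitude field :math:`e^{i\\phi}`.  The undiffracted 0th-order
beam sits at the origin of the far field and is kept as a fixed sampling
point; reconfigurable 1st-order beams are steered around it by linear phase
ramps ("gratings") with optional quadratic terms ("lenses").  A blazing
level ``b`` scales the modulation depth of the pattern about its circular
mean, trading 1st-order power against the 0th order so that all beams can
excite the sample with similar power.

The far-field model used throughout (and by the tests as an independent
oracle) is a single centred discrete Fourier transform: no aberrations and
no device look-up-table nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import tifffile

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Spot:
    """One requested far-field spot, in far-field pixel offsets from the origin."""

    x: float
    y: float
    power: float = 1.0
    order: int = 1  # 0 for the undiffracted beam, 1 for steered beams


@dataclass
class SpotPattern:
    """Target beam pattern: a fixed 0th-order spot at the origin plus 1st orders.

    The 0th order is always present; constructing a pattern never removes it.
    """

    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(s.order == 0 for s in self.spots):
            self.spots = [Spot(0.0, 0.0, 1.0, order=0)] + list(self.spots)
        seen: set[tuple[float, float]] = set()
        for s in self.spots:
            key = (round(s.x, 9), round(s.y, 9))
            if key in seen:
                raise ValueError(f"duplicate spot at ({s.x}, {s.y})")
            seen.add(key)

    @property
    def first_orders(self) -> list[Spot]:
        return [s for s in self.spots if s.order != 0]

    @classmethod
    def from_offsets(cls, offsets: Sequence[tuple[float, float]],
                     powers: Sequence[float] | None = None) -> "SpotPattern":
        if powers is None:
            powers = [1.0] * len(offsets)
        return cls([Spot(x, y, p, order=1) for (x, y), p in zip(offsets, powers)])


@dataclass
class PhaseHologram:
    """Phase matrix in radians wrapped to [0, 2pi), on a square grid."""

    phase: np.ndarray
    pixel_pitch: float = 1.0
    blazing: float = 1.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2 or self.phase.shape[0] != self.phase.shape[1]:
            raise ValueError("hologram phase matrix must be square")
        self.phase = np.mod(self.phase, TWO_PI)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    def field(self) -> np.ndarray:
        """Unit-amplitude complex field the SLM imposes."""
        return np.exp(1j * self.phase)

    def save_tiff(self, path) -> None:
        scaled = np.round(self.phase / TWO_PI * 65535).astype(np.uint16)
        tifffile.imwrite(path, scaled)

    @classmethod
    def load_tiff(cls, path) -> "PhaseHologram":
        raw = tifffile.imread(path).astype(float)
        return cls(raw / 65535.0 * TWO_PI)


def far_field_intensity(holo: PhaseHologram) -> np.ndarray:
    """Far-field intensity |FFT(e^{i phi})|^2, origin at the array centre.

    Normalized so that total far-field power equals the SLM-plane power
    (Parseval): sum(intensity) == N^2 for an N x N unit-amplitude field.
    """
    f = np.fft.fftshift(np.fft.fft2(holo.field(), norm="ortho"))
    return np.abs(f) ** 2


def _centre(n: int) -> int:
    return n // 2


def spot_power(intensity: np.ndarray, spot: Spot, window: int = 3) -> float:
    """Summed far-field intensity in a centred window around the nominal offset."""
    n = intensity.shape[0]
    cy, cx = _centre(n), _centre(n)
    iy = int(round(cy + spot.y))
    ix = int(round(cx + spot.x))
    h = window // 2
    ys = slice(max(iy - h, 0), min(iy + h + 1, n))
    xs = slice(max(ix - h, 0), min(ix + h + 1, n))
    return float(intensity[ys, xs].sum())


def gratings_and_lenses(spots: SpotPattern, shape: int = 512,
                        lens_curvature: float = 0.0) -> PhaseHologram:
    """Superposition hologram: phase = arg of the sum of per-spot ramps.

    Each spot at far-field offset ``(u, v)`` contributes a linear phase ramp
    ``exp(2 pi i (u x + v y) / N)`` weighted by the square root of its
    requested power (the 0th-order spot contributes a constant term); an
    optional common quadratic lens term defocuses all 1st orders together.

    Raises ``ValueError`` for offsets at or beyond the Nyquist limit (N/2).
    """
    n = int(shape)
    nyq = n / 2
    for s in spots.spots:
        if abs(s.x) >= nyq or abs(s.y) >= nyq:
            raise ValueError(
                f"spot offset ({s.x}, {s.y}) beyond Nyquist range +/-{nyq}")
    if not spots.first_orders:
        return PhaseHologram(np.zeros((n, n)))
    # coordinates matching an fftshifted far field: frequency u maps to
    # far-field pixel offset u from the centre
    y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    total = np.zeros((n, n), dtype=complex)
    r2 = ((x - n / 2) ** 2 + (y - n / 2) ** 2) / n ** 2
    for s in spots.spots:
        ramp = TWO_PI * (s.x * x + s.y * y) / n
        if lens_curvature != 0.0 and s.order != 0:
            ramp = ramp + TWO_PI * lens_curvature * r2
        total += np.sqrt(max(s.power, 0.0)) * np.exp(1j * ramp)
    return PhaseHologram(np.angle(total))


def support_correlation(holo: PhaseHologram, target_intensity: np.ndarray) -> float:
    """Normalized correlation of achieved vs target intensity on the target support."""
    target = np.asarray(target_intensity, dtype=float)
    support = target > 0
    ach = far_field_intensity(holo)
    a, t = ach[support], target[support]
    denom = np.linalg.norm(a) * np.linalg.norm(t)
    return float(a @ t / denom) if denom > 0 else 0.0


def gerchberg_saxton(target_intensity: np.ndarray, iterations: int = 30,
                     seed: int = 0) -> tuple[PhaseHologram, np.ndarray]:
    """2-D Gerchberg-Saxton phase retrieval for an arbitrary far-field target.

    Alternates projections between the SLM plane (unit amplitude, phase free)
    and the far-field plane (amplitude sqrt(target), phase free), starting
    from a seeded random far-field phase.  Returns the hologram and the
    per-iteration error sequence.

    The error tracked is the normalized far-field amplitude mismatch
    ``||A_k - sqrt(target)|| / ||sqrt(target)||``: the error-reduction
    distance of the alternating projections, which is guaranteed
    non-increasing; intensity-correlation quality on the target support is
    available separately via :func:`support_correlation`.
    """
    target = np.asarray(target_intensity, dtype=float)
    if target.ndim != 2 or target.shape[0] != target.shape[1]:
        raise ValueError("target must be a square 2-D intensity image")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not np.any(target > 0):
        raise ValueError("target intensity is all zero")
    # normalize target power to the unit-amplitude SLM-plane power so the two
    # amplitude constraints are mutually reachable
    n2 = target.size
    amp = np.sqrt(target / target.sum() * n2)
    amp_norm = float(np.linalg.norm(amp))
    rng = np.random.default_rng(seed)
    ff_phase = rng.uniform(0.0, TWO_PI, size=target.shape)
    errors = []
    slm_phase = np.zeros_like(target)
    for _ in range(iterations):
        ff_field = amp * np.exp(1j * ff_phase)
        slm_field = np.fft.ifft2(np.fft.ifftshift(ff_field), norm="ortho")
        slm_phase = np.angle(slm_field)
        achieved = np.fft.fftshift(
            np.fft.fft2(np.exp(1j * slm_phase), norm="ortho"))
        ff_phase = np.angle(achieved)
        errors.append(float(np.linalg.norm(np.abs(achieved) - amp)) / amp_norm)
    return PhaseHologram(slm_phase), np.asarray(errors)


def apply_blazing(holo: PhaseHologram, b: float) -> PhaseHologram:
    """Scale the modulation depth of the phase about its circular mean.

    ``b = 1`` leaves the hologram unchanged; ``b = 0`` collapses it to a
    uniform phase (all power undiffracted into the 0th order).  Intermediate
    values transfer power from the 1st orders into the 0th order
    monotonically, which is how per-beam powers are equalized.
    """
    if not (0.0 <= b <= 1.0):
        raise ValueError(f"blazing level must be in [0, 1], got {b}")
    mean = float(np.angle(np.exp(1j * holo.phase).mean()))
    dev = np.angle(np.exp(1j * (holo.phase - mean)))  # wrapped to (-pi, pi]
    out = replace(holo, phase=np.mod(mean + b * dev, TWO_PI))
    out.blazing = b
    return out


def uniformity_ratio(holo: PhaseHologram, spots: SpotPattern,
                     window: int = 3) -> float:
    """(max spot power) / (min spot power) over all spots, 0th order included."""
    intensity = far_field_intensity(holo)
    powers = [spot_power(intensity, s, window) for s in spots.spots]
    lo = min(powers)
    if lo <= 0:
        return np.inf
    return max(powers) / lo


def optimize_uniformity(spots: SpotPattern, b_grid: Sequence[float] | None = None,
                        shape: int = 512) -> tuple[PhaseHologram, float]:
    """Choose the blazing level that most evenly shares power among beams.

    Scans ``b_grid`` (default 1.0 down to 0.05 in steps of 0.05), evaluating
    each blazed hologram's far field, and returns the hologram minimizing the
    max/min spot-power ratio together with the achieved ratio.
    """
    if len(spots.spots) < 2:
        holo = gratings_and_lenses(spots, shape)
        return holo, 1.0
    if b_grid is None:
        b_grid = np.arange(1.0, 0.049, -0.05)
    b_grid = list(b_grid)
    if not b_grid:
        raise ValueError("blazing grid is empty")
    base = gratings_and_lenses(spots, shape)
    best: tuple[float, PhaseHologram] | None = None
    for b in b_grid:
        cand = apply_blazing(base, b)
        ratio = uniformity_ratio(cand, spots)
        if best is None or ratio < best[0]:
            best = (ratio, cand)
    assert best is not None
    return best[1], best[0]


def save_spot_pattern_csv(spots: SpotPattern, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"x": s.x, "y": s.y, "order": s.order, "requested_power": s.power}
         for s in spots.spots]
    ).to_csv(path, index=False)


def load_spot_pattern_csv(path) -> SpotPattern:
    import pandas as pd

    df = pd.read_csv(path)
    return SpotPattern([
        Spot(r.x, r.y, r.requested_power, int(r.order)) for r in df.itertuples()
    ])
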
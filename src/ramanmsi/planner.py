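"""Grouping of sampling points into power-shared batches of 6.

All beams of a batch are excited simultaneously inside one 180 x 60 um
field of view (FOV), so batches must be spatially compact; and because each
beam's spectrum occupies two CCD rows, members of a batch need a minimum
vertical separation (10 um at default) to avoid cross-talk between the
dispersed tracks.  Batches always hold exactly 6 points: short batches are
padded with random in-FOV fill points so that the fixed laser power is
always shared the same way (fewer beams would concentrate more power per
point, potentially above the tissue damage threshold).

Clustering is an iterated k-means: k starts at ceil(N/6) and grows, with
deterministic re-seeding, until every cluster has at most 6 members and
fits inside a single FOV placement centred on its 0th-order point (the
member closest to the cluster centroid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .sampling import SamplingPoint


@dataclass(frozen=True)
class FOVGeometry:
    """Field-of-view and CCD-separation constraints for one batch."""

    fov_width_um: float = 180.0
    fov_height_um: float = 60.0
    min_vertical_sep_um: float = 10.0
    batch_size: int = 6

    def __post_init__(self) -> None:
        if self.fov_height_um / self.min_vertical_sep_um < self.batch_size - 1:
            raise ValueError(
                f"{self.batch_size} points at {self.min_vertical_sep_um} um "
                f"separation cannot fit a {self.fov_height_um} um FOV height")


@dataclass
class Batch:
    """Six sampling points measured in one exposure.

    ``stage_target`` is where the microscope stage puts the FOV centre: the
    0th-order member sits exactly there.
    """

    members: list[SamplingPoint]
    stage_target: tuple[float, float] = (0.0, 0.0)
    zero_order_index: int = 0
    padding_count: int = 0
    batch_id: int = -1

    @property
    def af_members(self) -> list[SamplingPoint]:
        return [m for m in self.members if m.origin == "af"]


@dataclass
class BatchPlan:
    """Ordered batches plus bookkeeping for the whole acquisition."""

    batches: list[Batch]
    n_af_points: int
    n_fill_points: int
    integration_time: float = 2.0
    seed: int = 0

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    @property
    def total_points(self) -> int:
        return sum(len(b.members) for b in self.batches)

    def to_csv(self, path) -> None:
        rows = []
        for b in self.batches:
            for i, m in enumerate(b.members):
                rows.append({"batch_id": b.batch_id, "member_idx": i,
                             "x_um": m.x_um, "y_um": m.y_um,
                             "origin": m.origin, "segment_id": m.segment_id,
                             "zero_order": i == b.zero_order_index})
        pd.DataFrame(rows).to_csv(path, index=False)

    def summary(self) -> dict:
        return {"n_batches": self.n_batches, "n_af_points": self.n_af_points,
                "n_fill_points": self.n_fill_points,
                "total_points": self.total_points,
                "integration_time_s": self.integration_time,
                "seed": self.seed}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def assign_zero_order(batch: Batch) -> Batch:
    """Flag the member closest to the centroid of the AF-derived members.

    Random fills are excluded from the centroid so padding cannot move the
    measurement anchor; ties break to the lowest member index.  The stage
    target is set so this member sits at the FOV centre.
    """
    if not batch.members:
        raise ValueError("cannot assign a zero order in an empty batch")
    anchors = batch.af_members or batch.members
    cx = float(np.mean([m.x_um for m in anchors]))
    cy = float(np.mean([m.y_um for m in anchors]))
    candidates = [i for i, m in enumerate(batch.members)
                  if m.origin == "af"] or list(range(len(batch.members)))
    best = min(candidates,
               key=lambda i: ((batch.members[i].x_um - cx) ** 2
                              + (batch.members[i].y_um - cy) ** 2, i))
    zo = batch.members[best]
    out = replace(batch, zero_order_index=best,
                  stage_target=(zo.x_um, zo.y_um))
    out.members = [replace(m, zero_order=(i == best))
                   for i, m in enumerate(out.members)]
    return out


def _vertical_slots(ys: Sequence[float], lo: float, hi: float,
                    sep: float) -> list[float]:
    """Canonical fill positions keeping >= sep from all existing ys.

    Slots are packed outward from each existing member and inward from the
    FOV edges; any subset of them is mutually >= sep apart.
    """
    ys = sorted(ys)
    slots: list[float] = []
    if not ys:
        y = lo
        while y <= hi + 1e-9:
            slots.append(y)
            y += sep
        return slots
    # below the first member (packed downward from it)
    y = ys[0] - sep
    while y >= lo - 1e-9:
        slots.append(y)
        y -= sep
    # between members (packed upward from the lower one)
    for a, b in zip(ys, ys[1:]):
        y = a + sep
        while y <= b - sep + 1e-9:
            slots.append(y)
            y += sep
    # above the last member
    y = ys[-1] + sep
    while y <= hi + 1e-9:
        slots.append(y)
        y += sep
    return slots


def _fits_fov(group: Sequence[SamplingPoint], anchor: SamplingPoint,
              geom: FOVGeometry) -> bool:
    hw, hh = geom.fov_width_um / 2, geom.fov_height_um / 2
    return all(abs(m.x_um - anchor.x_um) <= hw + 1e-9
               and abs(m.y_um - anchor.y_um) <= hh + 1e-9 for m in group)


def _group_feasible(group: Sequence[SamplingPoint], geom: FOVGeometry) -> bool:
    """Can this AF group anchor one batch: size, FOV fit around the
    0th-order member, pairwise vertical separation, and room to pad to 6."""
    if len(group) > geom.batch_size:
        return False
    anchor = _centroid_closest(group)
    if not _fits_fov(group, anchor, geom):
        return False
    ys = sorted(m.y_um for m in group)
    if any(b - a < geom.min_vertical_sep_um - 1e-9 for a, b in zip(ys, ys[1:])):
        return False
    lo = anchor.y_um - geom.fov_height_um / 2
    hi = anchor.y_um + geom.fov_height_um / 2
    slots = _vertical_slots(ys, lo, hi, geom.min_vertical_sep_um)
    return len(slots) >= geom.batch_size - len(group)


def _centroid_closest(group: Sequence[SamplingPoint]) -> SamplingPoint:
    cx = float(np.mean([m.x_um for m in group]))
    cy = float(np.mean([m.y_um for m in group]))
    return min(group, key=lambda m: ((m.x_um - cx) ** 2 + (m.y_um - cy) ** 2))


def _split_by_separation(group: Sequence[SamplingPoint],
                         geom: FOVGeometry) -> list[list[SamplingPoint]]:
    """Greedy first-fit split of AF members into vertically separable groups."""
    ordered = sorted(group, key=lambda m: m.y_um)
    groups: list[list[SamplingPoint]] = []
    for m in ordered:
        placed = False
        for g in groups:
            if m.y_um - g[-1].y_um >= geom.min_vertical_sep_um - 1e-9:
                g.append(m)
                placed = True
                break
        if not placed:
            groups.append([m])
    return groups


def _pad_group(group: list[SamplingPoint], geom: FOVGeometry,
               rng: np.random.Generator) -> Batch:
    """Pad a feasible AF group to the full batch size with random fills.

    Fills are drawn uniformly in the FOV, rejection-sampled against the
    vertical-separation constraint; if rejection fails, the fill's vertical
    position snaps to the nearest canonical free slot.
    """
    anchor = _centroid_closest(group)
    hw, hh = geom.fov_width_um / 2, geom.fov_height_um / 2
    lo, hi = anchor.y_um - hh, anchor.y_um + hh
    sep = geom.min_vertical_sep_um
    members = list(group)
    ys = [m.y_um for m in members]
    n_fill = geom.batch_size - len(members)
    remaining = n_fill
    while remaining > 0:
        placed = None
        for _try in range(60):
            x = anchor.x_um + rng.uniform(-hw, hw)
            y = anchor.y_um + rng.uniform(-hh, hh)
            if not all(abs(y - yy) >= sep for yy in ys):
                continue
            # accept only if the remaining fills can still be packed
            if len(_vertical_slots(ys + [y], lo, hi, sep)) >= remaining - 1:
                placed = (x, y)
                break
        if placed is None:
            # fall back to canonical slots for all remaining fills (any
            # subset of them is mutually separated)
            slots = _vertical_slots(ys, lo, hi, sep)
            if len(slots) < remaining:
                raise RuntimeError("no vertical slot left for padding "
                                   "(infeasible group slipped through)")
            take = rng.choice(len(slots), size=remaining, replace=False)
            for j in take:
                members.append(SamplingPoint(
                    x_um=anchor.x_um + rng.uniform(-hw, hw),
                    y_um=float(slots[int(j)]), origin="fill"))
            remaining = 0
            break
        ys.append(placed[1])
        members.append(SamplingPoint(x_um=placed[0], y_um=placed[1],
                                     origin="fill"))
        remaining -= 1
    return assign_zero_order(Batch(members=members, padding_count=n_fill))


def _build_batches(af_group: list[SamplingPoint], geom: FOVGeometry,
                   rng: np.random.Generator) -> list[Batch]:
    """Turn one cluster of AF points into one or more padded batches."""
    if not af_group:
        return []
    if _group_feasible(af_group, geom):
        return [_pad_group(af_group, geom, rng)]
    # first resolve vertical-separation conflicts, then FOV/packing overflow
    pieces = _split_by_separation(af_group, geom)
    if len(pieces) == 1:
        ordered = sorted(af_group, key=lambda m: (m.y_um, m.x_um))
        half = len(ordered) // 2 or 1
        pieces = [ordered[:half], ordered[half:]]
    out: list[Batch] = []
    for piece in pieces:
        if piece:
            out.extend(_build_batches(piece, geom, rng))
    return out


def enforce_separation(batch: Batch, geom: FOVGeometry,
                       seed: int = 0) -> list[Batch]:
    """Re-establish the vertical-separation invariant for one batch.

    AF-derived members are never moved: fill members are re-drawn (and
    snapped to free vertical slots if needed); if two AF members themselves
    sit closer than the minimum separation, the batch is split and each part
    re-padded to the full size.
    """
    rng = np.random.default_rng(seed)
    return _build_batches(list(batch.af_members), geom, rng)


def plan_batches(points: Sequence[SamplingPoint],
                 geom: FOVGeometry | None = None, seed: int = 0,
                 integration_time: float = 2.0) -> BatchPlan:
    """Group AF-derived sampling points into power-shared batches of 6.

    Iterated k-means: k starts at ceil(N/6) and grows (by the number of
    currently infeasible clusters, re-seeding centroids deterministically a
    few times per k) until every cluster is a feasible batch anchor; each
    cluster is then padded to 6 members, vertical separation enforced, and
    the 0th order assigned.  No AF point is ever dropped.
    """
    if geom is None:
        geom = FOVGeometry()
    pts = [replace(p, origin="af") if p.origin != "af" else p for p in points]
    for p in pts:
        if not (np.isfinite(p.x_um) and np.isfinite(p.y_um)):
            raise ValueError("non-finite sampling point")
    rng = np.random.default_rng(seed)
    n = len(pts)
    if n == 0:
        return BatchPlan(batches=[], n_af_points=0, n_fill_points=0,
                         integration_time=integration_time, seed=seed)
    coords = np.array([[p.x_um, p.y_um] for p in pts])
    k = ceil(n / geom.batch_size)
    clusters: list[list[SamplingPoint]] | None = None
    while k < n:
        accepted = None
        attempts = 2
        for attempt in range(8):
            state = int((seed * 100003 + k * 131 + attempt) % (2**31 - 1))
            km = KMeans(n_clusters=k, n_init=2, random_state=state)
            lab = km.fit_predict(coords)
            groups = [[pts[i] for i in np.flatnonzero(lab == c)]
                      for c in range(k)]
            groups = [g for g in groups if g]
            bad = sum(not _group_feasible(g, geom) for g in groups)
            if bad == 0:
                accepted = groups
                break
            # close to feasibility: worth re-seeding a few more times
            # before paying for an extra cluster
            attempts = 8 if bad <= 3 else 2
            if attempt + 1 >= attempts:
                break
        if accepted is not None:
            clusters = accepted
            break
        k += 1
    if clusters is None:
        clusters = [[p] for p in pts]
    # deterministic batch order: by smallest original point index in cluster
    order_key = {id(p): i for i, p in enumerate(pts)}
    clusters.sort(key=lambda g: min(order_key[id(p)] for p in g))
    batches: list[Batch] = []
    for group in clusters:
        batches.extend(_build_batches(group, geom, rng))
    for i, b in enumerate(batches):
        b.batch_id = i
        b.members = [replace(m, batch_id=i) for m in b.members]
    n_fill = sum(b.padding_count for b in batches)
    return BatchPlan(batches=batches, n_af_points=n,
                     n_fill_points=n_fill,
                     integration_time=integration_time, seed=seed)


def estimate_acquisition_time(plan: BatchPlan, t_int: float | None = None,
                              overhead_multiplier: float = 1.0) -> float:
    """Total measurement time in seconds: batches x integration x overhead.

    Stage moves, CCD readout and hologram computation are folded into the
    multiplier (1 ignores them; ~2 is typical in practice).
    """
    t = plan.integration_time if t_int is None else t_int
    if t <= 0:
        raise ValueError("integration time must be positive")
    return plan.n_batches * t * overhead_multiplier


def per_beam_power(total_power_w: float = 3.6, transmission: float = 0.33,
                   n_beams: int = 10) -> float:
    """Power available per beam (W) after optics, shared over the beams."""
    if n_beams < 1:
        raise ValueError("need at least one beam")
    return total_power_w * transmission / n_beams


def isolated_cluster_points(n_clusters: int = 318, n_points: int = 794,
                            seed: int = 1, spacing_um: float = 500.0,
                            jitter_x_um: float = 40.0,
                            geom: FOVGeometry | None = None
                            ) -> list[SamplingPoint]:
    """Synthetic acquisition scenario: well-separated FOV-compatible clusters.

    Emulates the point layout of a sparse tissue section: ``n_clusters``
    groups of 1-6 AF-derived points each (sizes as even as possible,
    shuffled), anchored on a coarse grid ``spacing_um`` apart, with members
    stacked on the minimum-separation vertical lattice so that every cluster
    can be padded to a full batch.
    """
    if geom is None:
        geom = FOVGeometry()
    if not n_clusters <= n_points <= n_clusters * geom.batch_size:
        raise ValueError("n_points must allow 1-6 points per cluster")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_clusters, n_points // n_clusters)
    sizes[: n_points - int(sizes.sum())] += 1
    rng.shuffle(sizes)
    grid = int(np.ceil(np.sqrt(n_clusters)))
    pts: list[SamplingPoint] = []
    for i, s in enumerate(sizes):
        ax = spacing_um * (i % grid) + 200.0
        ay = spacing_um * (i // grid) + 200.0
        offsets = geom.min_vertical_sep_um * (np.arange(s) - (s - 1) / 2)
        for o in offsets:
            pts.append(SamplingPoint(
                x_um=ax + rng.uniform(-jitter_x_um, jitter_x_um),
                y_um=ay + float(o), origin="af"))
    return pts
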
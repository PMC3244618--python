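"""Deformation-comparison metrics: arc-length resampling, RMS and maximum displacement.

A simulated catheter curve is compared against a reference curve by index:
the reference is first resampled at the simulation's segment length, then
per-node Euclidean distances dist_i = ||x_i_sim - x_i_ref|| are reduced to

    RMS = sqrt( (1/n) sum_i dist_i^2 )        and        max_i dist_i .

Both curves are assumed to share a frame (same base pose); no registration
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class CurveComparison:
    rms: float
    max_displacement: float
    per_node_distances: np.ndarray
    n: int


def resample_polyline(points, spacing: float) -> np.ndarray:
    """Arc-length-uniform resampling of a polyline by linear interpolation.

    Starts at the first point and returns floor(total_length / spacing) + 1
    points at arc-length multiples of ``spacing`` (measured along the input
    polyline).  A small relative tolerance keeps the count stable when the
    total length is a near-exact multiple of the spacing.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    if len(points) < 2:
        raise ValidationError("need at least two points to resample")
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arc[-1])
    if spacing > total:
        raise ValidationError(f"spacing {spacing} exceeds polyline length {total}")
    count = int(np.floor(total / spacing + 1e-9)) + 1
    s = np.minimum(spacing * np.arange(count), total)
    out = np.empty((count, 3))
    for k in range(3):
        out[:, k] = np.interp(s, arc, points[:, k])
    return out


def compare_curves(sim, ref) -> CurveComparison:
    """Per-node RMS and maximum displacement between two equally-sampled curves."""
    sim = np.asarray(sim, float).reshape(-1, 3)
    ref = np.asarray(ref, float).reshape(-1, 3)
    if len(sim) != len(ref):
        raise ValidationError(f"curve point counts differ ({len(sim)} vs {len(ref)})")
    if len(sim) == 0:
        raise ValidationError("cannot compare empty curves")
    dist = np.linalg.norm(sim - ref, axis=1)
    return CurveComparison(
        rms=float(np.sqrt(np.mean(dist**2))),
        max_displacement=float(dist.max()),
        per_node_distances=dist,
        n=len(dist),
    )
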
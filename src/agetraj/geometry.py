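"""Spine-centerline geometry and scan-log QC.

Kyphosis is scored as the tortuosity of the spinal centerline between the
C1 and L2 landmarks::

    tortuosity = 1 - chord / arc

where ``chord`` is the straight-line distance between the endpoints and
``arc`` is the distance along the centerline.  A straight spine scores 0;
the score approaches 1 as the spine curls up.  The statistic is invariant
under rigid motion and uniform scaling, so it can be compared across
animals and scanners without registration.

The module also provides the inverse construction (a circular-arc
centerline with a prescribed tortuosity), the 2-mm mid-diaphysis window
used for femoral cortical morphometry, and a checker that flags scans
whose acquisition/reconstruction log parameters deviate from a reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpineCenterline",
    "FemurScan",
    "ScanLog",
    "LogDeviation",
    "compute_tortuosity",
    "resample_centerline",
    "arc_centerline",
    "femur_midshaft_window",
    "check_scan_logs",
]


@dataclass(frozen=True)
class SpineCenterline:
    """Ordered 3D points (mm) from the C1 landmark to the L2 landmark."""

    points: np.ndarray  # (n, 3) float array
    voxel_size_mm: float = 0.035

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("centerline points must be an (n, 3) array")
        if pts.shape[0] < 3:
            raise ValueError("centerline needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("centerline contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive centerline points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class FemurScan:
    """Axial extent of a scanned femur, in mm."""

    proximal_end_mm: float
    distal_end_mm: float
    pixel_size_mm: float = 0.03516

    def __post_init__(self) -> None:
        if not self.distal_end_mm > self.proximal_end_mm:
            raise ValueError("distal end must lie beyond the proximal end")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel size must be positive")

    @property
    def length_mm(self) -> float:
        return self.distal_end_mm - self.proximal_end_mm


#: acquisition/reconstruction parameters that affect downstream morphometry
DEFAULT_QC_KEYS = (
    "resolution_um",
    "source_voltage_kv",
    "source_current_ua",
    "filter",
    "frame_averaging",
    "smoothing",
    "ring_artifact_correction",
    "beam_hardening_pct",
    "histogram_min",
    "histogram_max",
)


@dataclass
class ScanLog:
    """Key/value map parsed from a scanner or reconstruction log file."""

    values: dict[str, str]
    scan_id: str = ""

    def get(self, key: str) -> str | None:
        return self.values.get(key)


@dataclass(frozen=True)
class LogDeviation:
    scan_id: str
    key: str
    kind: str          # "mismatch" or "absent"
    value: str | None
    reference: str | None


def compute_tortuosity(spine: SpineCenterline) -> float:
    """Tortuosity = 1 - chord/arc of the centerline polyline.

    Returns a value in [0, 1).  Raises on degenerate (zero arc length)
    input; the SpineCenterline constructor already rejects repeated
    consecutive points, so this only triggers on pathological input.
    """
    pts = spine.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = float(seg.sum())
    if arc <= 0.0:
        raise ValueError("degenerate centerline: zero arc length")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    # rounding can push an exactly-straight polyline a few ulp negative
    return max(1.0 - chord / arc, 0.0)


def _cumulative_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_centerline(spine: SpineCenterline, step_mm: float) -> SpineCenterline:
    """Resample to points uniformly spaced in arc length (linear interp).

    The endpoints (landmarks) are preserved exactly, so the chord is
    unchanged; the polyline arc length of the resampled curve converges to
    that of the original as ``step_mm`` shrinks.
    """
    if step_mm <= 0:
        raise ValueError("resampling step must be positive")
    pts = spine.points
    s = _cumulative_arclength(pts)
    total = s[-1]
    n_new = max(int(np.ceil(total / step_mm)) + 1, 3)
    s_new = np.linspace(0.0, total, n_new)
    new = np.column_stack([np.interp(s_new, s, pts[:, k]) for k in range(3)])
    return SpineCenterline(points=new, voxel_size_mm=spine.voxel_size_mm)


def _half_angle_for_polyline_tortuosity(target: float, n_segments: int) -> float:
    """Half-angle phi of a circular arc whose *inscribed polyline* (equal
    angular steps, n_segments chords) has the requested tortuosity.

    For an arc of half-angle phi the chord is 2r sin(phi) and the
    inscribed-polyline length is 2 r n sin(phi/n), so the polyline
    tortuosity is 1 - sin(phi) / (n sin(phi/n)), strictly increasing in
    phi on (0, pi).
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("target tortuosity must lie in [0, 1)")
    if target == 0.0:
        return 0.0
    n = n_segments

    def f(phi: float) -> float:
        return 1.0 - np.sin(phi) / (n * np.sin(phi / n)) - target

    return float(brentq(f, 1e-12, np.pi - 1e-12, xtol=1e-15, rtol=8.9e-16))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def arc_centerline(
    tortuosity: float,
    n_points: int = 100,
    arc_length_mm: float = 70.0,
    rng: np.random.Generator | None = None,
    voxel_size_mm: float = 0.035,
) -> SpineCenterline:
    """Planar circular-arc centerline whose polyline tortuosity equals
    ``tortuosity`` to machine precision.

    The arc family is the geometric model behind the synthetic kyphosis
    phenotype: as the arc's central angle grows from 0 to 2*pi the score
    sweeps [0, 1).  ``arc_length_mm`` defaults to roughly a mouse C1-L2
    span.  When ``rng`` is given the arc is embedded at a random rigid
    pose (the score is pose-invariant by construction).
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    m = n_points - 1
    phi = _half_angle_for_polyline_tortuosity(tortuosity, m)
    if phi == 0.0:
        t = np.linspace(0.0, arc_length_mm, n_points)
        pts = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
    else:
        radius = arc_length_mm / (2.0 * phi)
        ang = np.linspace(-phi, phi, n_points)
        pts = np.column_stack(
            [radius * np.sin(ang), radius * np.cos(ang), np.zeros_like(ang)]
        )
    if rng is not None:
        pts = pts @ _random_rotation(rng).T + rng.uniform(-50.0, 50.0, size=3)
    return SpineCenterline(points=pts, voxel_size_mm=voxel_size_mm)


def femur_midshaft_window(scan: FemurScan, window_mm: float = 2.0) -> tuple[float, float]:
    """Axial window of width ``window_mm`` centered on the diaphysis midpoint.

    This is the subvolume over which cortical metrics are computed; the
    femur must be at least as long as the window.
    """
    if window_mm <= 0:
        raise ValueError("window width must be positive")
    if scan.length_mm < window_mm:
        raise ValueError(
            f"femur length {scan.length_mm:g} mm shorter than window {window_mm:g} mm"
        )
    mid = 0.5 * (scan.proximal_end_mm + scan.distal_end_mm)
    return (mid - window_mm / 2.0, mid + window_mm / 2.0)


def _values_differ(a: str, b: str, rel_tol: float) -> bool:
    try:
        fa, fb = float(a), float(b)
    except (TypeError, ValueError):
        return a.strip() != b.strip()
    if fa == fb:
        return False
    denom = max(abs(fa), abs(fb))
    return abs(fa - fb) > rel_tol * denom


def check_scan_logs(
    logs: list[ScanLog],
    reference: ScanLog,
    keys: tuple[str, ...] = DEFAULT_QC_KEYS,
    rel_tol: float = 1e-6,
) -> list[LogDeviation]:
    """Flag scans whose key parameters deviate from the reference log.

    Numeric values are compared with relative tolerance ``rel_tol``;
    everything else by exact string match.  A key missing from a scan's
    log is reported with kind "absent".
    """
    deviations: list[LogDeviation] = []
    for log in logs:
        for key in keys:
            ref_val = reference.get(key)
            if ref_val is None:
                continue  # parameter not tracked by this reference
            val = log.get(key)
            if val is None:
                deviations.append(LogDeviation(log.scan_id, key, "absent", None, ref_val))
            elif _values_differ(val, ref_val, rel_tol):
                deviations.append(
                    LogDeviation(log.scan_id, key, "mismatch", val, ref_val)
                )
    return deviations
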
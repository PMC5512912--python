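"""Image-quality metrics: RMS spot radius, Seidel third-order sums,
geometric MTF, and the improvement-rate comparison statistic.

Conventions
-----------
* RMS spot radius: sqrt( sum[(xi-x0)^2 + (yi-y0)^2] / n ) over the image
  intersections of a pupil-filling fan; the reference (x0, y0) defaults to
  the spot centroid (chief-ray mode available).
* Seidel sums are computed surface by surface from the paraxial marginal and
  chief rays with the refraction invariants A = n(u + y c) and
  Abar = n(ubar + ybar c):

      S_I   = -sum A^2    y Delta(u/n) + K c^3 (n'-n) y^4
      S_II  = -sum A Abar y Delta(u/n) + K c^3 (n'-n) y^3 ybar
      S_III = -sum Abar^2 y Delta(u/n) + K c^3 (n'-n) y^2 ybar^2
      S_IV  = -sum H^2 c Delta(1/n)
      S_V   = -sum (Abar^3/A) y Delta(u/n) - (Abar/A) H^2 c Delta(1/n)
              + K c^3 (n'-n) y ybar^3

  The conic (aspheric) terms are the fourth-order departure from the
  osculating sphere; the sign convention makes a single positive refracting
  surface contribute positive S_I, and makes the exactly stigmatic Cartesian
  ellipsoid (K = -(n/n')^2, collimated input) sum to zero.  Spherical
  aberration is reported as SA = S_I and tangential coma as TCO = 3 S_II,
  with the chief ray scaled to the requested field angle.
* Geometric MTF: modulus of the discrete Fourier transform of the ray-based
  point spread, |mean exp(-2 pi i f u)| along the chosen orientation, with
  frequencies in cycles/mm (lp/mm).
* Improvement rate D compares a proposed value X against a reference Y:
  aberration mode (smaller is better) D = (|Y|-|X|)/|Y| * 100; resolution
  mode (larger is better, used for MTF) D = (X-Y)/X * 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eye_model import EyePrescription
from .trace_engine import (
    GridSpec,
    ParaxialTrace,
    TraceError,
    paraxial_trace,
    pupil_ray_fan,
    trace_ray,
)

__all__ = [
    "SpotDiagram",
    "SeidelSummary",
    "MTFCurve",
    "ImprovementReport",
    "rms_spot",
    "seidel_aberrations",
    "geometric_mtf",
    "improvement_rate",
    "improvement_report",
    "trace_spot",
    "evaluate_design",
    "DEFAULT_FREQUENCIES",
]

DEFAULT_FREQUENCIES = (10.0, 20.0, 30.0)

SEIDEL_CONVENTION = (
    "Seidel sums with marginal ray filling the stated pupil at the stop and "
    "chief ray at the stated field angle; surface term -A^2 y Delta(u/n) "
    "plus conic term K c^3 (n'-n) y^4; SA = S_I, TCO = 3 S_II; lengths in mm."
)


@dataclass
class SpotDiagram:
    """Image-plane intersections of a ray fan, with bookkeeping."""

    points: np.ndarray              # (n, 2) image-plane (x, y), mm
    reference: tuple[float, float]  # (x0, y0), mm
    reference_mode: str             # 'centroid' or 'chief'
    pupil_diameter: float
    field_deg: float
    n_launched: int = 0
    n_vignetted: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1:
            raise ValueError("spot diagram needs at least one point")


def rms_spot(spot: SpotDiagram) -> float:
    """RMS spot radius about the spot's reference point, in mm."""
    dx = spot.points[:, 0] - spot.reference[0]
    dy = spot.points[:, 1] - spot.reference[1]
    return float(np.sqrt(np.mean(dx * dx + dy * dy)))


@dataclass
class SeidelSummary:
    """Per-surface and total Seidel third-order sums."""

    per_surface: np.ndarray  # (n_surfaces, 5): S_I..S_V per refracting surface
    totals: np.ndarray       # (5,)
    sa: float                # spherical aberration (S_I)
    tco: float               # tangential coma (3 S_II)
    field_deg: float
    convention: str = SEIDEL_CONVENTION


def seidel_aberrations(p: EyePrescription, par: ParaxialTrace | None = None,
                       field_deg: float = 5.0) -> SeidelSummary:
    """Surface-by-surface Seidel sums for the prescription.

    The paraxial trace's chief ray (unit field tangent) is scaled to
    ``field_deg``; the image surface is excluded (no refraction there).
    """
    if par is None:
        par = paraxial_trace(p)
    t = math.tan(math.radians(field_deg))
    n_ref = len(p.surfaces) - 1  # refracting surfaces (image surface excluded)
    out = np.zeros((n_ref, 5))
    for i in range(n_ref):
        s = p.surfaces[i]
        c = s.curvature
        n1, n2 = par.n_in[i], par.n_out[i]
        y, u, u2 = par.y_marginal[i], par.u_marginal_in[i], par.u_marginal_out[i]
        yb = par.y_chief[i] * t
        ub = par.u_chief_in[i] * t
        A = n1 * (u + y * c)
        Ab = n1 * (ub + yb * c)
        d_un = u2 / n2 - u / n1
        d_in = 1.0 / n2 - 1.0 / n1
        H = n1 * (ub * y - u * yb)
        asph = s.conic * c ** 3 * (n2 - n1)
        s1 = -A * A * y * d_un + asph * y ** 4
        s2 = -A * Ab * y * d_un + asph * y ** 3 * yb
        s3 = -Ab * Ab * y * d_un + asph * y ** 2 * yb ** 2
        s4 = -H * H * c * d_in
        if abs(A) > 1e-14:
            s5 = (-(Ab ** 3 / A) * y * d_un - (Ab / A) * H * H * c * d_in
                  + asph * y * yb ** 3)
        else:
            s5 = 0.0  # distortion term undefined at normal incidence
        out[i] = (s1, s2, s3, s4, s5)
    totals = out.sum(axis=0)
    return SeidelSummary(
        per_surface=out,
        totals=totals,
        sa=float(totals[0]),
        tco=float(3.0 * totals[1]),
        field_deg=field_deg,
    )


@dataclass
class MTFCurve:
    """Geometric modulation transfer along one orientation."""

    frequencies: np.ndarray  # cycles/mm
    modulation: np.ndarray   # in [0, 1]
    orientation: str         # 'tangential' (y) or 'sagittal' (x)

    def at(self, f: float) -> float:
        i = int(np.argmin(np.abs(self.frequencies - f)))
        if not math.isclose(self.frequencies[i], f, rel_tol=1e-9, abs_tol=1e-9):
            raise KeyError(f"frequency {f} not sampled")
        return float(self.modulation[i])


def geometric_mtf(spot: SpotDiagram, frequencies, orientation: str = "tangential") -> MTFCurve:
    """Geometric (spot-based) MTF: |characteristic function| of the PSF sample.

    ``modulation(f) = |mean_k exp(-2 pi i f u_k)|`` with ``u`` the spot
    coordinate along the orientation.  Exactly 1 at f = 0 and invariant to
    rigid translation of the spot.
    """
    if orientation == "tangential":
        u = spot.points[:, 1]
    elif orientation == "sagittal":
        u = spot.points[:, 0]
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(f < 0):
        raise ValueError("spatial frequencies must be >= 0")
    u = u - u.mean()  # translation invariance, explicit
    phase = -2.0j * math.pi * np.outer(f, u)
    m = np.abs(np.exp(phase).mean(axis=1))
    m = np.clip(m, 0.0, 1.0)
    return MTFCurve(frequencies=f, modulation=m, orientation=orientation)


@dataclass(frozen=True)
class ImprovementReport:
    """Eq.-style comparison of a proposed value X against a reference Y."""

    metric: str
    proposed: float    # X
    reference: float   # Y
    mode: str          # 'aberration' (smaller better) or 'resolution' (larger better)
    difference: float  # | |X| - |Y| |
    percent: float     # improvement rate D


def improvement_rate(X: float, Y: float, mode: str = "aberration") -> float:
    """Improvement rate D (%) of a proposed value X over a reference Y.

    ``aberration`` mode (smaller is better): D = (|Y| - |X|) / |Y| * 100.
    ``resolution`` mode (larger is better, MTF): D = (X - Y) / X * 100.
    Positive D means the proposed value is the better one in either mode.
    """
    if mode == "aberration":
        if Y == 0:
            raise ZeroDivisionError("aberration-mode reference Y must be nonzero")
        return (abs(Y) - abs(X)) / abs(Y) * 100.0
    if mode == "resolution":
        if X == 0:
            raise ZeroDivisionError("resolution-mode proposed X must be nonzero")
        return (X - Y) / X * 100.0
    raise ValueError(f"mode must be 'aberration' or 'resolution', got {mode!r}")


def improvement_report(metric: str, X: float, Y: float, mode: str = "aberration") -> ImprovementReport:
    return ImprovementReport(
        metric=metric, proposed=X, reference=Y, mode=mode,
        difference=abs(abs(X) - abs(Y)),
        percent=improvement_rate(X, Y, mode),
    )


# ---------------------------------------------------------------------------
# Whole-design evaluation
# ---------------------------------------------------------------------------

def trace_spot(p: EyePrescription, grid: GridSpec | None = None,
               field_deg: float = 0.0, reference: str = "centroid") -> SpotDiagram:
    """Trace a pupil fan to the image surface and collect the spot diagram.

    Vignetted rays are excluded from the spot (and counted); raises
    :class:`~iolens.trace_engine.TraceError` when no ray reaches the image.
    """
    rays = pupil_ray_fan(p, grid, field_deg)
    pts = []
    lost = 0
    chief_pt = None
    for k, ray in enumerate(rays):
        res = trace_ray(p, ray)
        if res.ok:
            pts.append(res.image_point)
            if k == 0:
                chief_pt = res.image_point
        else:
            lost += 1
    if not pts:
        raise TraceError(f"{p.name!r}: every ray vignetted at field {field_deg} deg")
    pts = np.array(pts)
    if reference == "centroid":
        ref = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    elif reference == "chief":
        if chief_pt is None:
            raise TraceError(f"{p.name!r}: chief ray vignetted; no chief reference")
        ref = chief_pt
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    return SpotDiagram(
        points=pts, reference=ref, reference_mode=reference,
        pupil_diameter=p.pupil_diameter, field_deg=field_deg,
        n_launched=len(rays), n_vignetted=lost,
    )


def evaluate_design(
    p: EyePrescription,
    grid: GridSpec | None = None,
    fields: tuple[float, ...] = (0.0, 5.0),
    frequencies=DEFAULT_FREQUENCIES,
    mtf_orientation: str = "tangential",
    reference: str = "centroid",
) -> dict:
    """Bundle the standard metrics for one prescription.

    SA/TCO come from the Seidel sums at the largest listed field angle
    (coma needs an off-axis field); RMS and the geometric MTF come from a
    real-ray fan at the first listed field (on-axis by default).  The result
    is deterministic for a fixed grid.
    """
    grid = grid or GridSpec("hexapolar", 10)
    par = paraxial_trace(p)
    seidel = seidel_aberrations(p, par, field_deg=max(fields))
    spot = trace_spot(p, grid, field_deg=fields[0], reference=reference)
    mtf = geometric_mtf(spot, frequencies, orientation=mtf_orientation)
    return {
        "name": p.name,
        "pupil_mm": p.pupil_diameter,
        "SA": seidel.sa,
        "TCO": seidel.tco,
        "RMS": rms_spot(spot),
        "MTF": {float(f): float(m) for f, m in zip(mtf.frequencies, mtf.modulation)},
        "field_deg_aberrations": seidel.field_deg,
        "field_deg_spot": spot.field_deg,
        "n_rays": spot.n_launched,
        "n_vignetted": spot.n_vignetted,
        "seidel_totals": seidel.totals.tolist(),
        "convention": seidel.convention,
    }
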
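"""Sequential ray tracing through conic surfaces: exact (real) and paraxial.

Real rays are traced surface by surface with a closed-form quadratic
intersection against each conic's implicit equation

    F(x, y, z) = c (x^2 + y^2) - 2 s + (1 + K) c s^2 = 0,   s = z - z_vertex,

followed by vector-form Snell refraction.  Rays that miss a surface's real
extent, land outside its semi-aperture, or undergo total internal reflection
are flagged vignetted with the offending surface index.

The paraxial path is the standard y-nu recursion (refraction
n'u' = nu - y c (n' - n), transfer y' = y + t u).  The marginal ray is
scaled so its height at the stop equals the prescription's pupil radius —
pupil sizes of 5/6 mm are realised by scaling the traced beam at the stop,
not by editing the stop's semi-aperture.  The chief ray is launched at unit
paraxial field angle and solved to cross the stop centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eye_model import ConicSurface, EyePrescription

__all__ = [
    "Ray",
    "TraceResult",
    "ParaxialTrace",
    "GridSpec",
    "TraceError",
    "TotalInternalReflection",
    "AfocalSystem",
    "intersect_conic",
    "refract",
    "trace_ray",
    "trace_geometry",
    "pupil_ray_fan",
    "paraxial_trace",
    "entrance_scale",
    "chief_entrance_height",
]


class TraceError(RuntimeError):
    pass


class TotalInternalReflection(TraceError):
    """Snell's law has no real solution: the design is nonphysical here."""


class AfocalSystem(TraceError):
    """The paraxial marginal ray never crosses the axis (zero power)."""


@dataclass(frozen=True)
class Ray:
    """A geometric ray: origin (mm), unit direction, wavelength (nm)."""

    origin: np.ndarray
    direction: np.ndarray
    wavelength: float = 555.0

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if not math.isclose(norm, 1.0, abs_tol=1e-9):
            d = d / norm
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    @classmethod
    def parallel(cls, x: float, y: float, field_deg: float = 0.0, z: float = 0.0,
                 wavelength: float = 555.0) -> "Ray":
        """Ray from an infinitely distant object at the given field angle
        (rotation in the y-z meridian), starting on the plane ``z``."""
        th = math.radians(field_deg)
        return cls(np.array([x, y, z]), np.array([0.0, math.sin(th), math.cos(th)]),
                   wavelength)


@dataclass
class TraceResult:
    """Per-surface intersection history of one ray."""

    points: np.ndarray                 # (k, 3) intersections actually reached
    image_point: tuple[float, float] | None
    vignetted: bool
    vignette_index: int | None         # surface index where the ray was lost
    total_path: float                  # geometric path length, mm

    @property
    def ok(self) -> bool:
        return not self.vignetted


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

# Minimum propagation distance to accept an intersection.  Slightly negative
# so that zero-thickness gaps (e.g. a stop coincident with the next vertex)
# accept the t = 0 hit; the sag-branch check rejects spurious roots.
_EPS_T = -1e-12
_PLANE_C = 1e-12    # |curvature| below this is treated as an exact plane


def _intersect(origin, direction, c, K, vertex_z):
    """Intersection point and *unnormalised* outward gradient, or None."""
    ox, oy, oz = origin
    dx, dy, dz = direction
    s0 = oz - vertex_z
    if abs(c) < _PLANE_C:
        if abs(dz) < 1e-15:
            return None
        t = -s0 / dz
        if t < _EPS_T:
            return None
        p = origin + t * direction
        return p, np.array([0.0, 0.0, -1.0]), t
    # Quadratic A t^2 + B t + C = 0 from the implicit conic
    A = c * (dx * dx + dy * dy) + (1.0 + K) * c * dz * dz
    B = 2.0 * (c * (ox * dx + oy * dy) - dz + (1.0 + K) * c * s0 * dz)
    C = c * (ox * ox + oy * oy) - 2.0 * s0 + (1.0 + K) * c * s0 * s0
    if abs(A) < 1e-14:
        if abs(B) < 1e-15:
            return None
        roots = [-C / B]
    else:
        disc = B * B - 4.0 * A * C
        if disc < 0.0:
            return None
        sq = math.sqrt(disc)
        # numerically stable pair
        q = -0.5 * (B + math.copysign(sq, B)) if B != 0.0 else 0.5 * sq
        roots = []
        if q != 0.0:
            roots = [q / A, C / q]
        else:
            roots = [0.0, 0.0]
    # keep forward roots on the sag branch (the sheet through the vertex)
    best = None
    for t in roots:
        if not math.isfinite(t) or t < _EPS_T:
            continue
        p = origin + t * direction
        s = p[2] - vertex_z
        # sag-branch check: s must satisfy the single-valued sag expression
        r2 = p[0] * p[0] + p[1] * p[1]
        radicand = 1.0 - (1.0 + K) * c * c * r2
        if radicand < -1e-12:
            continue
        sag = c * r2 / (1.0 + math.sqrt(max(radicand, 0.0)))
        if abs(s - sag) > 1e-8 * (1.0 + abs(s)):
            continue
        if best is None or t < best[2]:
            grad = np.array([c * p[0], c * p[1], (1.0 + K) * c * s - 1.0])
            best = (p, grad, t)
    return best


def intersect_conic(ray: Ray, surface: ConicSurface, vertex_z: float):
    """Intersect a ray with a conic surface placed at ``vertex_z``.

    Returns ``(point, unit_normal)`` with the normal oriented against the
    ray (suitable for refraction), or ``None`` when the ray misses the
    surface's real extent.
    """
    hit = _intersect(ray.origin, ray.direction, surface.curvature, surface.conic, vertex_z)
    if hit is None:
        return None
    p, grad, _ = hit
    n = grad / np.linalg.norm(grad)
    if float(np.dot(n, ray.direction)) > 0.0:
        n = -n
    return p, n


def refract(direction: np.ndarray, normal: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Vector Snell refraction.  ``normal`` may point either way.

    Raises :class:`TotalInternalReflection` when no transmitted ray exists.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    if float(np.dot(n, d)) > 0.0:
        n = -n
    if n1 == n2:
        return d
    eta = n1 / n2
    cosi = -float(np.dot(n, d))
    sin2t = eta * eta * (1.0 - cosi * cosi)
    if sin2t > 1.0:
        raise TotalInternalReflection(
            f"total internal reflection (n1={n1}, n2={n2}, cos_i={cosi:.6f})"
        )
    t = eta * d + (eta * cosi - math.sqrt(1.0 - sin2t)) * n
    return t / np.linalg.norm(t)


# ---------------------------------------------------------------------------
# Sequential trace
# ---------------------------------------------------------------------------

def _geometry(p: EyePrescription):
    """Flatten a prescription into per-surface trace records."""
    vz = p.vertex_positions()
    rows = []
    n_in = 1.0  # object space is air
    for i, s in enumerate(p.surfaces):
        rows.append((vz[i], s.curvature, s.conic, s.semi_aperture, n_in, s.medium_index))
        n_in = s.medium_index
    return rows


def trace_geometry(rows, ray: Ray, last_is_image: bool = True) -> TraceResult:
    """Trace through explicit geometry rows
    ``(vertex_z, curvature, conic, semi_aperture, n_in, n_out)``.

    Exposed separately from :func:`trace_ray` so callers can trace reversed
    or ad-hoc surface stacks (e.g. the reversibility check).
    """
    origin = np.asarray(ray.origin, dtype=float)
    direction = np.asarray(ray.direction, dtype=float)
    pts = []
    path = 0.0
    n_surf = len(rows)
    for i, (vz, c, K, sa, n1, n2) in enumerate(rows):
        hit = _intersect(origin, direction, c, K, vz)
        if hit is None:
            return TraceResult(np.array(pts).reshape(-1, 3), None, True, i, path)
        p, grad, t = hit
        if math.hypot(p[0], p[1]) > sa + 1e-9:
            return TraceResult(np.array(pts).reshape(-1, 3), None, True, i, path)
        pts.append(p)
        path += t
        if i == n_surf - 1 and last_is_image:
            return TraceResult(np.array(pts), (float(p[0]), float(p[1])), False, None, path)
        normal = grad / np.linalg.norm(grad)
        try:
            direction = refract(direction, normal, n1, n2)
        except TotalInternalReflection:
            return TraceResult(np.array(pts), None, True, i, path)
        origin = p
    return TraceResult(np.array(pts), (float(pts[-1][0]), float(pts[-1][1])), False, None, path)


def trace_ray(p: EyePrescription, ray: Ray) -> TraceResult:
    """Trace one real ray through the prescription to the image surface."""
    return trace_geometry(_geometry(p), ray)


# ---------------------------------------------------------------------------
# Paraxial trace
# ---------------------------------------------------------------------------

@dataclass
class ParaxialTrace:
    """Marginal and chief y-nu traces plus first-order system properties.

    ``u_*_in[i]`` / ``u_*_out[i]`` are the paraxial angles immediately before
    and after refraction at surface ``i``; the marginal ray is scaled to the
    prescription's pupil radius at the stop; the chief ray corresponds to a
    unit paraxial field angle (tan 1) and crosses the stop centre.
    """

    y_marginal: np.ndarray
    u_marginal_in: np.ndarray
    u_marginal_out: np.ndarray
    y_chief: np.ndarray
    u_chief_in: np.ndarray
    u_chief_out: np.ndarray
    n_in: np.ndarray
    n_out: np.ndarray
    focal_length: float
    image_distance: float
    stop_index: int
    pupil_radius: float
    entrance_height: float        # marginal entrance height at surface-1 plane
    chief_entrance_height: float  # chief entrance height per unit field tangent


def _paraxial_basis(p: EyePrescription, y0: float, u0: float):
    """y-nu recursion from the first-surface tangent plane (z=0)."""
    ns = len(p.surfaces)
    y = np.empty(ns)
    uin = np.empty(ns)
    uout = np.empty(ns)
    nin = np.empty(ns)
    nout = np.empty(ns)
    cy, cu, n1 = y0, u0, 1.0
    for i, s in enumerate(p.surfaces):
        if i > 0:
            cy = cy + p.surfaces[i - 1].thickness * cu
        y[i] = cy
        uin[i] = cu
        nin[i] = n1
        n2 = s.medium_index
        cu = (n1 * cu - cy * s.curvature * (n2 - n1)) / n2
        uout[i] = cu
        nout[i] = n2
        n1 = n2
    return y, uin, uout, nin, nout


def paraxial_trace(p: EyePrescription, allow_afocal: bool = False) -> ParaxialTrace:
    """First-order trace of the prescription's marginal and chief rays.

    An afocal system (marginal ray never crosses the axis) is an explicit
    error unless ``allow_afocal`` is set, in which case the image distance
    is reported as infinite (aberration sums remain well defined).
    """
    stop = p.stop_index
    pupil_r = p.pupil_diameter / 2.0
    if math.isinf(p.object_distance):
        # marginal: parallel basis ray, scaled to the pupil radius at the stop
        yb, uib, uob, nin, nout = _paraxial_basis(p, 1.0, 0.0)
        if yb[stop] == 0.0:
            raise AfocalSystem(f"{p.name!r}: marginal ray vanishes at the stop")
        m = pupil_r / yb[stop]
        ym, uim, uom = yb * m, uib * m, uob * m
        h_ent = m
        # chief: unit field tangent; combine height/angle basis rays so that
        # the chief height at the stop is zero
        ya, uia, uoa = _paraxial_basis(p, 0.0, 1.0)[:3]
        if yb[stop] == 0.0:
            raise AfocalSystem(f"{p.name!r}: cannot solve chief ray")
        h_chief = -ya[stop] / yb[stop]
        yc = ya + h_chief * yb
        uic = uia + h_chief * uib
        uoc = uoa + h_chief * uob
    else:
        # finite object on axis at distance d in front of surface 1:
        # marginal from the axial object point, chief from the object edge
        d = p.object_distance
        yb, uib, uob, nin, nout = _paraxial_basis(p, d, 1.0)  # through axial point
        if yb[stop] == 0.0:
            raise AfocalSystem(f"{p.name!r}: marginal ray vanishes at the stop")
        m = pupil_r / yb[stop]
        ym, uim, uom = yb * m, uib * m, uob * m
        h_ent = d * m
        ya, uia, uoa = _paraxial_basis(p, 0.0, 1.0)[:3]
        hb, uibb, uobb = _paraxial_basis(p, 1.0, 0.0)[:3]
        k = -ya[stop] / hb[stop]
        yc = ya + k * hb
        uic = uia + k * uibb
        uoc = uoa + k * uobb
        h_chief = k
    # first-order properties from the last *refracting* surface
    last = len(p.surfaces) - 2
    u_final = uom[last]
    if abs(u_final) < 1e-14:
        # marginal never converges: no image can be located
        if not allow_afocal:
            raise AfocalSystem(f"{p.name!r}: afocal system (zero marginal power)")
        image_dist = math.inf
    else:
        image_dist = -ym[last] / u_final
    uo_par = _paraxial_basis(p, 1.0, 0.0)[2]
    focal = -1.0 / uo_par[last] if abs(uo_par[last]) > 1e-14 else math.inf
    return ParaxialTrace(
        y_marginal=ym, u_marginal_in=uim, u_marginal_out=uom,
        y_chief=yc, u_chief_in=uic, u_chief_out=uoc,
        n_in=nin, n_out=nout,
        focal_length=float(focal), image_distance=float(image_dist),
        stop_index=stop, pupil_radius=pupil_r,
        entrance_height=float(h_ent), chief_entrance_height=float(h_chief),
    )


def entrance_scale(p: EyePrescription) -> float:
    """Entrance-plane height producing unit paraxial height at the stop."""
    stop = p.stop_index
    yb = _paraxial_basis(p, 1.0, 0.0)[0]
    if yb[stop] == 0.0:
        raise AfocalSystem(f"{p.name!r}: marginal ray vanishes at the stop")
    return 1.0 / yb[stop]


def _stop_height(p: EyePrescription, rows, stop: int, h: float, field_deg: float) -> float:
    """Real-ray y at the stop surface for an entrance height h; inf if lost."""
    ray = Ray.parallel(0.0, h, field_deg, wavelength=p.wavelength_nm)
    res = trace_geometry(rows[: stop + 1], ray, last_is_image=True)
    if res.vignetted:
        return math.inf
    return float(res.points[-1][1])


def chief_entrance_height(p: EyePrescription, field_deg: float,
                          tol: float = 1e-10, max_iter: int = 50) -> float:
    """Entrance height of the real chief ray (crosses the stop centre).

    One-dimensional secant iteration seeded by the paraxial solution.
    """
    if field_deg == 0.0:
        return 0.0
    stop = p.stop_index
    rows = _geometry(p)
    t = math.tan(math.radians(field_deg))
    yb = _paraxial_basis(p, 1.0, 0.0)[0]
    ya = _paraxial_basis(p, 0.0, 1.0)[0]
    h0 = -t * ya[stop] / yb[stop]
    h1 = h0 * 1.0 + 1e-4
    f0 = _stop_height(p, rows, stop, h0, field_deg)
    f1 = _stop_height(p, rows, stop, h1, field_deg)
    for _ in range(max_iter):
        if abs(f1) < tol:
            return h1
        if not (math.isfinite(f0) and math.isfinite(f1)) or f1 == f0:
            raise TraceError(f"{p.name!r}: chief-ray solve failed at {field_deg} deg")
        h0, h1 = h1, h1 - f1 * (h1 - h0) / (f1 - f0)
        f0, f1 = f1, _stop_height(p, rows, stop, h1, field_deg)
    raise TraceError(f"{p.name!r}: chief-ray solve did not converge")


# ---------------------------------------------------------------------------
# Pupil sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Pupil sampling grid: 'hexapolar' rings or a 'square' n-by-n raster."""

    pattern: str = "hexapolar"
    rings_or_n: int = 10

    def unit_points(self) -> np.ndarray:
        """Sample points of the unit disk, shape (n, 2); deterministic."""
        if self.pattern == "hexapolar":
            r = self.rings_or_n
            pts = [(0.0, 0.0)]
            for k in range(1, r + 1):
                rad = k / r
                for j in range(6 * k):
                    a = 2.0 * math.pi * j / (6 * k)
                    pts.append((rad * math.cos(a), rad * math.sin(a)))
            return np.array(pts)
        if self.pattern == "square":
            n = self.rings_or_n
            ax = np.linspace(-1.0, 1.0, n)
            xx, yy = np.meshgrid(ax, ax)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            return pts[np.hypot(pts[:, 0], pts[:, 1]) <= 1.0 + 1e-12]
        raise ValueError(f"unknown grid pattern {self.pattern!r}")


def pupil_ray_fan(p: EyePrescription, grid: GridSpec | None = None,
                  field_deg: float = 0.0) -> list[Ray]:
    """Rays uniformly sampling the stop aperture at the given field angle.

    The fan fills the prescription's ``pupil_diameter`` at the stop surface
    (paraxial scaling from the entrance plane); for off-axis fields the fan
    is centred on the real chief ray.
    """
    grid = grid or GridSpec()
    pts = grid.unit_points()
    if pts.size == 0:
        raise ValueError("empty pupil grid")
    scale = entrance_scale(p) * (p.pupil_diameter / 2.0)
    h_chief = chief_entrance_height(p, field_deg)
    return [
        Ray.parallel(x * scale, y * scale + h_chief, field_deg,
                     wavelength=p.wavelength_nm)
        for x, y in pts
    ]
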
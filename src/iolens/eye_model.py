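"""Schematic-eye optical model: conic surfaces, prescriptions, refractive error.

The optical system is an ordered sequence of rotationally symmetric conic
refracting surfaces (cornea, aqueous chamber, aperture stop, the three
surfaces of an intraocular lens or crystalline lens, and a curved retinal
image surface).  Light travels in +z; all lengths are millimetres; a
surface's ``curvature`` is 1/R in mm^-1 with positive curvature meaning the
centre of curvature lies on the image side.  Each surface carries the medium
*following* it, so the prescription fully determines the index sequence.

Refractive errors are expressed in the ophthalmic "degrees" scale
(100 degrees = 1 dioptre): M degrees of myopia and N degrees of astigmatism
map onto two scalar perturbations, one for the cornea and one for the
aqueous humor:

    cornea_modifier = (N / 100) * 0.1
    humor_modifier  = (M + N / 2) / 100 * 0.37

How the two scalars perturb the prescription is convention-selectable (see
:func:`apply_refractive_error`), because the scalars themselves carry no
units.  Astigmatism is treated as a rotationally symmetric (scalar)
perturbation; there is no cylinder axis in this model.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConicSurface",
    "EyePrescription",
    "RefractiveErrorSpec",
    "PrescriptionError",
    "ConicDomainError",
    "DEFAULT_MEDIA",
    "DEFAULT_WAVELENGTH_NM",
    "BUILTIN_NAMES",
    "conic_sag",
    "builtin_prescription",
    "refractive_error_modifiers",
    "apply_refractive_error",
    "apply_modifiers",
    "ERROR_MODES",
    "STUDY_ERROR",
    "load_prescription",
    "save_prescription",
    "load_media",
    "save_media",
]

#: Refractive indices by medium name.  The design wavelength is 555 nm
#: (photopic peak); cornea/humor are the standard schematic-eye values,
#: "acrylic" is PMMA, and "lens" is an equivalent homogeneous index for the
#: crystalline lens.
DEFAULT_MEDIA: dict[str, float] = {
    "air": 1.0,
    "cornea": 1.376,
    "humor": 1.336,
    "acrylic": 1.4918,
    "lens": 1.42,
}

DEFAULT_WAVELENGTH_NM = 555.0


class PrescriptionError(ValueError):
    """An optical prescription violates a structural invariant."""


class ConicDomainError(ValueError):
    """Radial height outside the real extent of a conic surface."""


def conic_sag(x, curvature: float, conic: float = 0.0):
    """Axial sag z(x) of a conic surface at radial height ``x`` (mm).

    Uses the curvature form ``z = c x^2 / (1 + sqrt(1 - (1+K) c^2 x^2))``,
    equivalent to the vertex-radius form ``x^2 / (R + sqrt(R^2 - (1+K) x^2))``.
    ``K`` is the conic constant (0 sphere, -1 paraboloid).  Accepts scalars or
    arrays; raises :class:`ConicDomainError` where the radicand is negative.
    """
    x = np.asarray(x, dtype=float)
    c = float(curvature)
    if c == 0.0:
        out = np.zeros_like(x)
        return out if out.ndim else float(out)
    radicand = 1.0 - (1.0 + conic) * c * c * x * x
    if np.any(radicand < -1e-14):
        raise ConicDomainError(
            f"radial height outside the real extent of conic "
            f"(c={c}, K={conic})"
        )
    radicand = np.clip(radicand, 0.0, None)
    out = c * x * x / (1.0 + np.sqrt(radicand))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConicSurface:
    """One refracting interface.

    ``medium_name``/``medium_index`` describe the medium *after* the surface;
    ``thickness`` is the axial gap to the next surface's vertex.
    """

    curvature: float
    conic: float
    thickness: float
    medium_name: str
    medium_index: float
    semi_aperture: float
    is_stop: bool = False
    label: str = ""

    def validate(self, strict: bool = False) -> None:
        if not math.isfinite(self.thickness) or self.thickness < 0:
            raise PrescriptionError(f"surface {self.label!r}: bad thickness {self.thickness}")
        if not 1.0 <= self.medium_index <= 2.5:
            raise PrescriptionError(
                f"surface {self.label!r}: refractive index {self.medium_index} outside [1, 2.5]"
            )
        if self.semi_aperture <= 0:
            raise PrescriptionError(f"surface {self.label!r}: semi-aperture must be > 0")
        # Sag coverage: the conic's real extent should span the aperture.
        # A violation is physically meaningful (rays beyond the extent miss
        # the surface and vignette), so by default it only warns.
        if self.curvature != 0.0 and (1.0 + self.conic) > 0.0:
            lim = (1.0 + self.conic) * (self.curvature * self.semi_aperture) ** 2
            if lim > 1.0:
                msg = (
                    f"surface {self.label!r}: real conic extent "
                    f"({1.0 / (abs(self.curvature) * math.sqrt(1.0 + self.conic)):.3f} mm) "
                    f"smaller than semi-aperture {self.semi_aperture} mm"
                )
                if strict:
                    raise PrescriptionError(msg)
                warnings.warn(msg, stacklevel=2)

    def sag(self, x):
        return conic_sag(x, self.curvature, self.conic)


@dataclass(frozen=True)
class EyePrescription:
    """An ordered surface list (object side -> image side) plus trace settings.

    ``surfaces`` excludes the object plane; ``object_distance`` (mm, may be
    ``inf``) locates the object in front of the first surface.  The last
    surface is the image (retina) surface with thickness 0.  Exactly one
    surface is flagged as the stop.
    """

    name: str
    surfaces: tuple[ConicSurface, ...]
    object_distance: float = math.inf
    pupil_diameter: float = 6.0
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    error_mode: str = ""  # set when a refractive error has been applied

    def __post_init__(self):
        object.__setattr__(self, "surfaces", tuple(self.surfaces))

    @property
    def stop_index(self) -> int:
        idx = [i for i, s in enumerate(self.surfaces) if s.is_stop]
        if len(idx) != 1:
            raise PrescriptionError(
                f"{self.name!r}: expected exactly one stop surface, found {len(idx)}"
            )
        return idx[0]

    @property
    def image_index(self) -> int:
        return len(self.surfaces) - 1

    def vertex_positions(self) -> np.ndarray:
        """z of each surface vertex, with surface 0 at z = 0."""
        t = np.array([s.thickness for s in self.surfaces[:-1]], dtype=float)
        return np.concatenate([[0.0], np.cumsum(t)])

    def validate(self, strict: bool = False) -> None:
        if len(self.surfaces) < 3:
            raise PrescriptionError(f"{self.name!r}: need at least 3 surfaces")
        self.stop_index  # raises unless exactly one
        if self.surfaces[-1].thickness != 0.0:
            raise PrescriptionError(f"{self.name!r}: image surface must have thickness 0")
        if self.pupil_diameter <= 0:
            raise PrescriptionError(f"{self.name!r}: pupil diameter must be > 0")
        for s in self.surfaces:
            s.validate(strict=strict)

    def replace_surface(self, index: int, **changes) -> "EyePrescription":
        surfaces = list(self.surfaces)
        surfaces[index] = replace(surfaces[index], **changes)
        return replace(self, surfaces=tuple(surfaces))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "wavelength_nm": self.wavelength_nm,
            "pupil_diameter_mm": self.pupil_diameter,
            "object_distance": self.object_distance,
            "error_mode": self.error_mode,
            "surfaces": [
                {
                    "type": "sphere" if s.conic == 0.0 else "conic",
                    "curvature": s.curvature,
                    "conic": s.conic,
                    "thickness": s.thickness,
                    "medium": s.medium_name,
                    "semi_aperture": s.semi_aperture,
                    "stop": s.is_stop,
                    "label": s.label,
                }
                for s in self.surfaces
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping, media: Mapping[str, float] | None = None) -> "EyePrescription":
        media = dict(DEFAULT_MEDIA, **(media or {}))
        surfaces = []
        for i, row in enumerate(d["surfaces"]):
            name = row["medium"]
            if name not in media:
                raise PrescriptionError(f"surface {i}: unknown medium {name!r}")
            surfaces.append(
                ConicSurface(
                    curvature=float(row["curvature"]),
                    conic=float(row.get("conic", 0.0)),
                    thickness=float(row["thickness"]),
                    medium_name=name,
                    medium_index=float(media[name]),
                    semi_aperture=float(row["semi_aperture"]),
                    is_stop=bool(row.get("stop", False)),
                    label=str(row.get("label", f"#{i + 1}")),
                )
            )
        return cls(
            name=str(d["name"]),
            surfaces=tuple(surfaces),
            object_distance=float(d.get("object_distance", math.inf)),
            pupil_diameter=float(d.get("pupil_diameter_mm", 6.0)),
            wavelength_nm=float(d.get("wavelength_nm", DEFAULT_WAVELENGTH_NM)),
            error_mode=str(d.get("error_mode", "")),
        )


@dataclass(frozen=True)
class RefractiveErrorSpec:
    """Refractive error in ophthalmic degrees (100 degrees = 1 dioptre)."""

    myopia_degrees: float = 0.0
    astigmatism_degrees: float = 0.0

    def __post_init__(self):
        for v, what in ((self.myopia_degrees, "myopia"), (self.astigmatism_degrees, "astigmatism")):
            if not math.isfinite(v) or v < 0:
                raise PrescriptionError(f"{what} degrees must be finite and >= 0, got {v}")


def refractive_error_modifiers(spec: RefractiveErrorSpec) -> tuple[float, float]:
    """Map (M, N) degrees to the (cornea, humor) scalar perturbations."""
    cornea = spec.astigmatism_degrees / 100.0 * 0.1
    humor = (spec.myopia_degrees + spec.astigmatism_degrees / 2.0) / 100.0 * 0.37
    return cornea, humor


def _find_surface(p: EyePrescription, medium: str) -> int:
    for i, s in enumerate(p.surfaces):
        if s.medium_name == medium:
            return i
    raise PrescriptionError(f"{p.name!r}: no surface with medium {medium!r}")


ERROR_MODES = ("axial", "curvature", "hybrid")


def apply_refractive_error(
    p: EyePrescription,
    spec: RefractiveErrorSpec,
    mode: str = "axial",
) -> EyePrescription:
    """Perturb the cornea and humor surfaces to express a refractive error.

    The two scalar modifiers carry no units in their source form, so the
    parameter they perturb is convention-selectable:

    - ``"axial"`` (default): both modifiers are read as millimetres and added
      to the corneal thickness and the aqueous-depth thickness respectively.
      This is the axial-elongation model of myopia — the humor coefficient
      0.37 is the classical axial-length-to-refraction ratio (~0.37 mm of
      eye growth per dioptre), and it reproduces the order of magnitude of
      the reported third-order aberrations for the myopic eye.
    - ``"curvature"``: both modifiers are read as mm^-1 and added to the
      cornea and humor surface curvatures (a refractive-power model; note
      the humor modifier 2.36 mm^-1 for the 550/175-degree condition bends
      the aqueous surface to R ~ 0.4 mm, which vignettes most of the pupil).
    - ``"hybrid"``: cornea modifier to the anterior-cornea curvature
      (mm^-1), humor modifier to the aqueous-depth thickness (mm).

    All conventions are additive, so re-applying with negated modifiers
    restores the original prescription exactly.
    """
    cornea_mod, humor_mod = refractive_error_modifiers(spec)
    out = apply_modifiers(p, cornea_mod, humor_mod, mode)
    tag = f"M{spec.myopia_degrees:g}N{spec.astigmatism_degrees:g}"
    return replace(out, name=f"{p.name}+{tag}", error_mode=mode)


def apply_modifiers(p: EyePrescription, cornea_mod: float, humor_mod: float,
                    mode: str = "axial") -> EyePrescription:
    """Additively perturb the cornea/humor surfaces by explicit modifiers.

    The building block of :func:`apply_refractive_error`; accepts signed
    modifiers, so applying and then re-applying with negated values restores
    the original prescription.
    """
    if mode not in ERROR_MODES:
        raise ValueError(f"error mode must be one of {ERROR_MODES}, got {mode!r}")
    ic = _find_surface(p, "cornea")
    ih = _find_surface(p, "humor")
    if mode == "axial":
        out = p.replace_surface(ic, thickness=p.surfaces[ic].thickness + cornea_mod)
        out = out.replace_surface(ih, thickness=out.surfaces[ih].thickness + humor_mod)
    elif mode == "curvature":
        out = p.replace_surface(ic, curvature=p.surfaces[ic].curvature + cornea_mod)
        out = out.replace_surface(ih, curvature=out.surfaces[ih].curvature + humor_mod)
    else:  # hybrid
        out = p.replace_surface(ic, curvature=p.surfaces[ic].curvature + cornea_mod)
        out = out.replace_surface(ih, thickness=out.surfaces[ih].thickness + humor_mod)
    return out


# ---------------------------------------------------------------------------
# Packaged reference prescriptions
# ---------------------------------------------------------------------------
# Rows are (curvature mm^-1, conic K, thickness mm, medium, semi-aperture mm,
# is_stop).  "Y Radius" columns of the source design tables are read as
# curvature in mm^-1 (0.1287 mm^-1 <-> R = 7.77 mm, the Liou-Brennan anterior
# corneal radius); this reading is applied uniformly.

_ANTERIOR = [
    (0.1287, 0.0, 0.6, "cornea", 4.6712, False),
    (0.1563, 0.0, 5.195, "humor", 4.3066, False),
    (0.0, 0.0, 0.0, "humor", 3.0, True),
]

_BUILTIN_ROWS: dict[str, list[tuple]] = {
    # Natural crystalline lens, transcribed verbatim under the curvature
    # reading (anterior surface plane, posterior curvature 0.0806 mm^-1);
    # vitreous gap and retina adopted from the IOL design tables.
    "initial_eye": _ANTERIOR + [
        (0.0, 0.0, 1.59, "lens", 4.0, False),
        (0.0, 0.0, 2.43, "lens", 4.0, False),
        (0.0806, 0.0, 16.27, "humor", 4.0, False),
        (-0.0909, 0.0, 0.0, "humor", 7.7009, False),
    ],
    # Built-in (damped-least-squares) optimizer result, 5 mm pupil analysis.
    "codev_5mm": _ANTERIOR + [
        (0.0707, -24.88, 0.0915, "acrylic", 2.0413, False),
        (0.0, 0.0, 1.2623, "acrylic", 2.2640, False),
        (-0.0853, 1.37, 16.27, "humor", 2.6105, False),
        (-0.0909, 0.0, 0.0, "humor", 7.7009, False),
    ],
    # Genetic-algorithm result, 5 mm pupil analysis.
    "ga_5mm": _ANTERIOR + [
        (0.0755, -27.2, 0.9283, "acrylic", 2.0408, False),
        (0.0, 0.0, 1.0016, "acrylic", 2.2688, False),
        (-0.0849, 1.69, 16.27, "humor", 2.5282, False),
        (-0.0909, 0.0, 0.0, "humor", 7.6499, False),
    ],
    # Built-in optimizer result, 6 mm pupil analysis.
    "codev_6mm": _ANTERIOR + [
        (0.0819, -11.24, 0.9763, "acrylic", 2.0413, False),
        (0.0, 0.0, 1.2627, "acrylic", 2.2640, False),
        (-0.0702, -3.85, 16.27, "humor", 2.6105, False),
        (-0.0909, 0.0, 0.0, "humor", 7.7009, False),
    ],
    # Genetic-algorithm result, 6 mm pupil analysis.
    "ga_6mm": _ANTERIOR + [
        (0.0791, -12.68, 1.1739, "acrylic", 2.0408, False),
        (0.0, 0.0, 1.1021, "acrylic", 2.2688, False),
        (-0.0723, -4.32, 16.27, "humor", 2.5282, False),
        (-0.0909, 0.0, 0.0, "humor", 7.6499, False),
    ],
}

#: The myopic/astigmatic study condition: 550 degrees myopia (-5.50 D) with
#: 175 degrees astigmatism.
STUDY_ERROR = RefractiveErrorSpec(myopia_degrees=550.0, astigmatism_degrees=175.0)

BUILTIN_NAMES = ("initial_eye", "myopic_eye", "codev_5mm", "ga_5mm", "codev_6mm", "ga_6mm")

_LABELS = ("#1", "#2", "#Stop", "#4", "#5", "#6", "#Image")


def builtin_prescription(
    name: str,
    pupil_diameter: float | None = None,
    media: Mapping[str, float] | None = None,
    error_mode: str = "axial",
) -> EyePrescription:
    """Return one of the packaged schematic-eye prescriptions.

    ``initial_eye`` is the unperturbed eye with its crystalline lens;
    ``myopic_eye`` is the initial eye with the 550-degree-myopia /
    175-degree-astigmatism study condition applied under ``error_mode``;
    ``codev_5mm``/``ga_5mm``/``codev_6mm``/``ga_6mm`` are the two optimized
    IOL designs per analysis pupil.  ``pupil_diameter`` defaults to the
    design's native pupil (6 mm for the initial/myopic eye).
    """
    if name == "myopic_eye":
        base = builtin_prescription("initial_eye", pupil_diameter, media)
        p = apply_refractive_error(base, STUDY_ERROR, mode=error_mode)
        return replace(p, name="myopic_eye")
    if name not in _BUILTIN_ROWS:
        raise KeyError(f"unknown builtin prescription {name!r}; choose from {BUILTIN_NAMES}")
    media = dict(DEFAULT_MEDIA, **(media or {}))
    if pupil_diameter is None:
        pupil_diameter = 5.0 if name.endswith("5mm") else 6.0
    surfaces = tuple(
        ConicSurface(
            curvature=c, conic=k, thickness=t, medium_name=m,
            medium_index=media[m], semi_aperture=sa, is_stop=stop, label=lbl,
        )
        for (c, k, t, m, sa, stop), lbl in zip(_BUILTIN_ROWS[name], _LABELS)
    )
    return EyePrescription(
        name=name,
        surfaces=surfaces,
        object_distance=math.inf,
        pupil_diameter=float(pupil_diameter),
    )


# ---------------------------------------------------------------------------
# Structured-text (YAML) prescription and media-table I/O
# ---------------------------------------------------------------------------

def save_prescription(p: EyePrescription, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)


def load_prescription(path, media: Mapping[str, float] | None = None) -> EyePrescription:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping) or "surfaces" not in d:
        raise PrescriptionError(f"{path}: not a prescription file (missing 'surfaces')")
    return EyePrescription.from_dict(d, media=media)


def save_media(media: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(media), fh, sort_keys=True)


def load_media(path) -> dict[str, float]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise PrescriptionError(f"{path}: not a media table")
    return {str(k): float(v) for k, v in d.items()}
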
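"""Analytic geometry of dividing-cell shapes.

The model shape is a solid of revolution: two spheres (the daughter-cell
"lobes") optionally bridged by a neck whose meridian profile is a circular
arc externally tangent to both sphere cross-sections, with waist radius
``neck_radius``.  A single parameter therefore controls how far the cleavage
furrow has ingressed: at the waist radius that degenerates the arc into the
common tangent line the shape is convex (a spherocylinder for equal lobes),
and at waist 0 with tangent spheres it is two spheres touching at a point.

All lengths are in micrometres.  Coordinates are (z, y, x) to match the
array axis order used throughout the package.

Closed forms used here:

* volume of a solid of revolution, ``pi * integral f(x)^2 dx``, integrated
  piecewise over sphere segments (polynomial) and the arc segment
  (polynomial + arcsin terms);
* lateral surface of a spherical zone, ``2 pi r h``, and of the revolved
  arc, ``2 pi R (yc asin(u/R) - u)``;
* convex hull of two spheres: two spherical caps joined by the tangent
  conical frustum (a cylinder for equal radii).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LobePair",
    "CellGeometry",
    "AxialProfile",
    "axial_profile",
    "analytic_geometry",
    "numeric_volume",
    "hull_volume_two_spheres",
    "lobes_for_volume",
    "neck_radius_for_chvr",
    "max_neck_radius",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LobePair:
    """Two lobes of a dividing cell plus the neck waist radius.

    ``center_1``/``center_2`` are (z, y, x) positions in µm; ``radius_1``
    is the larger (or equal) lobe by convention.  ``neck_radius`` is the
    waist radius of the bridging neck; 0 together with externally tangent
    spheres gives two spheres touching at a point.
    """

    center_1: tuple[float, float, float]
    center_2: tuple[float, float, float]
    radius_1: float
    radius_2: float
    neck_radius: float = 0.0

    def __post_init__(self):
        if not (self.radius_1 >= self.radius_2 > 0):
            raise ValueError(
                f"require radius_1 >= radius_2 > 0, got "
                f"{self.radius_1!r}, {self.radius_2!r}"
            )
        if not (0 <= self.neck_radius <= self.radius_2 + 1e-9):
            raise ValueError(
                f"neck_radius must lie in [0, radius_2], got {self.neck_radius!r}"
            )
        object.__setattr__(self, "center_1", tuple(float(c) for c in self.center_1))
        object.__setattr__(self, "center_2", tuple(float(c) for c in self.center_2))

    @property
    def separation(self) -> float:
        """Distance between lobe centers (µm)."""
        return float(
            math.dist(self.center_1, self.center_2)
        )

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from lobe 1 to lobe 2 ((z,y,x)); +x if centers coincide."""
        d = np.asarray(self.center_2, float) - np.asarray(self.center_1, float)
        n = np.linalg.norm(d)
        if n < _EPS:
            return np.array([0.0, 0.0, 1.0])
        return d / n


@dataclass
class CellGeometry:
    """Per-cell, per-frame shape descriptors (µm-based units)."""

    cell_id: int
    frame_index: int
    volume: float
    surface_area: float
    aspect_ratio: float
    hull_volume: float
    chvr: float
    furrow_diameter: float | None = None


# ---------------------------------------------------------------------------
# meridian profile: piecewise description of rho_max(x) along the lobe axis
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    kind: str  # "sphere" | "arc" | "line"
    x0: float
    x1: float
    # sphere: (cx, r); arc: (xc, yc, R); line: (rho0, rho1)
    params: tuple


@dataclass
class AxialProfile:
    """Meridian profile of the revolved shape in the (axis, radius) plane.

    Lobe-1 center sits at axial coordinate 0, lobe 2 at ``separation``.
    ``segments`` partition [x_min, x_max]; between disjoint spheres the
    radius is 0 (only possible at neck_radius 0).
    """

    segments: list[_Segment]
    x_min: float
    x_max: float

    def radius(self, x) -> np.ndarray:
        """Profile radius at axial coordinate(s) ``x`` (vectorized)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for seg in self.segments:
            m = (x >= seg.x0 - _EPS) & (x <= seg.x1 + _EPS)
            if not m.any():
                continue
            xs = x[m]
            if seg.kind == "sphere":
                cx, r = seg.params
                v = r * r - (xs - cx) ** 2
                out[m] = np.maximum(out[m], np.sqrt(np.clip(v, 0, None)))
            elif seg.kind == "arc":
                xc, yc, R = seg.params
                v = R * R - (xs - xc) ** 2
                out[m] = np.maximum(out[m], yc - np.sqrt(np.clip(v, 0, None)))
            else:  # line
                rho0, rho1 = seg.params
                t = (xs - seg.x0) / max(seg.x1 - seg.x0, _EPS)
                out[m] = np.maximum(out[m], rho0 + t * (rho1 - rho0))
        return out

    # -- closed-form integrals ---------------------------------------------

    def volume(self) -> float:
        """Exact volume of the solid of revolution (µm³)."""
        v = 0.0
        for seg in self.segments:
            a, b = seg.x0, seg.x1
            if b <= a:
                continue
            if seg.kind == "sphere":
                cx, r = seg.params

                def F(x, cx=cx, r=r):
                    u = x - cx
                    return r * r * u - u ** 3 / 3.0

                v += F(b) - F(a)
            elif seg.kind == "arc":
                xc, yc, R = seg.params

                def F(x, xc=xc, yc=yc, R=R):
                    u = min(max(x - xc, -R), R)
                    return (
                        (yc * yc + R * R) * u
                        - u ** 3 / 3.0
                        - 2.0
                        * yc
                        * (0.5 * u * math.sqrt(max(R * R - u * u, 0.0))
                           + 0.5 * R * R * math.asin(u / R))
                    )

                v += F(b) - F(a)
            else:  # linear frustum
                rho0, rho1 = seg.params
                v += (b - a) * (rho0 * rho0 + rho0 * rho1 + rho1 * rho1) / 3.0
        return math.pi * v

    def surface_area(self) -> float:
        """Exact lateral surface area of the revolved profile (µm²)."""
        s = 0.0
        for seg in self.segments:
            a, b = seg.x0, seg.x1
            if b <= a:
                continue
            if seg.kind == "sphere":
                _, r = seg.params
                s += 2.0 * math.pi * r * (b - a)  # spherical zone
            elif seg.kind == "arc":
                xc, yc, R = seg.params
                ua = min(max(a - xc, -R), R)
                ub = min(max(b - xc, -R), R)

                def F(u, yc=yc, R=R):
                    return yc * math.asin(u / R) - u

                s += 2.0 * math.pi * R * (F(ub) - F(ua))
            else:
                rho0, rho1 = seg.params
                slant = math.hypot(b - a, rho1 - rho0)
                s += math.pi * (rho0 + rho1) * slant
        return s


def _neck_arc(r1: float, r2: float, d: float, a: float):
    """Solve the bridging-arc circle for waist radius ``a``.

    Returns (xc, yc, R, t1, t2): arc center/radius and the axial tangency
    coordinates on lobes 1 and 2.  The arc circle is externally tangent to
    both meridian circles, its lowest point (the waist) at height a.
    """

    def waist_stable(R):
        # sqrt((R+r1)^2 - xc^2) - R, written to survive R >> r1
        xc = (d * d + (r1 - r2) * (2.0 * R + r1 + r2)) / (2.0 * d)
        disc = (R + r1) ** 2 - xc * xc
        if disc <= 0:
            return -1.0 - R
        return (disc - R * R) / (math.sqrt(disc) + R)

    g = lambda R: waist_stable(R) - a

    # bracket the root on a log grid
    Rs = np.geomspace(1e-18 * r1, 1e9 * r1, 600)  # waist ~ sqrt(R) near tangency
    vals = [g(R) for R in Rs]
    lo = hi = None
    for i in range(len(Rs) - 1):
        if vals[i] <= 0 <= vals[i + 1]:
            lo, hi = Rs[i], Rs[i + 1]
            break
    if lo is None:
        raise ValueError(
            f"no bridging arc with waist {a} for lobes r1={r1}, r2={r2}, d={d}"
        )
    R = brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)
    xc = (d * d + (r1 - r2) * (2.0 * R + r1 + r2)) / (2.0 * d)
    yc = math.sqrt(max((R + r1) ** 2 - xc * xc, 0.0))
    t1 = r1 * xc / (R + r1)
    t2 = d + r2 * (xc - d) / (R + r2)
    return xc, yc, R, t1, t2


def max_neck_radius(r1: float, r2: float, d: float) -> float:
    """Waist radius of the convex (common-tangent-line) fill between the lobes.

    This is the largest meaningful neck radius: at this waist the bridging
    arc degenerates into the external tangent line and the shape equals the
    convex hull of the two spheres (a spherocylinder for equal lobes).
    """
    if d < _EPS:
        return r2
    sin_a = (r1 - r2) / d
    if abs(sin_a) >= 1:
        return r2
    # tangent line height at the small-lobe tangency (minimum along the fill)
    return r2 * math.sqrt(1.0 - sin_a * sin_a)


def _crease_radius(r1: float, r2: float, d: float) -> float:
    """Radius of the intersection circle of two overlapping spheres (0 if apart)."""
    if d >= r1 + r2 or d < _EPS:
        return 0.0
    xp = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    v = r1 * r1 - xp * xp
    return math.sqrt(v) if v > 0 else 0.0


def axial_profile(lobes: LobePair) -> AxialProfile:
    """Build the piecewise meridian profile of a :class:`LobePair`."""
    r1, r2, d = lobes.radius_1, lobes.radius_2, lobes.separation
    a = lobes.neck_radius

    # engulfed or coincident: a single sphere of radius r1
    if d + r2 <= r1 + _EPS or d < 1e-9 * r1:
        return AxialProfile(
            segments=[_Segment("sphere", -r1, r1, (0.0, r1))], x_min=-r1, x_max=r1
        )

    crease = _crease_radius(r1, r2, d)
    a_max = max_neck_radius(r1, r2, d)
    segs: list[_Segment]

    if a >= a_max * (1.0 - 1e-9):
        # convex fill: caps + tangent frustum
        sin_a = (r1 - r2) / d
        t1 = r1 * sin_a
        t2 = d + r2 * sin_a
        segs = [
            _Segment("sphere", -r1, t1, (0.0, r1)),
            _Segment("line", t1, t2, (r1 * math.sqrt(1 - sin_a ** 2),
                                      r2 * math.sqrt(1 - sin_a ** 2))),
            _Segment("sphere", t2, d + r2, (d, r2)),
        ]
    elif a > crease + 1e-9 * r1:
        xc, yc, R, t1, t2 = _neck_arc(r1, r2, d, a)
        segs = [
            _Segment("sphere", -r1, t1, (0.0, r1)),
            _Segment("arc", t1, t2, (xc, yc, R)),
            _Segment("sphere", t2, d + r2, (d, r2)),
        ]
    elif d < r1 + r2:
        # overlapping spheres, crease not smoothed (neck at/below crease radius)
        xp = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
        segs = [
            _Segment("sphere", -r1, xp, (0.0, r1)),
            _Segment("sphere", xp, d + r2, (d, r2)),
        ]
    else:
        # tangent or separated spheres, no neck
        segs = [
            _Segment("sphere", -r1, r1, (0.0, r1)),
            _Segment("sphere", d - r2, d + r2, (d, r2)),
        ]
    return AxialProfile(segments=segs, x_min=-r1, x_max=d + r2)


# ---------------------------------------------------------------------------
# closed-form descriptors
# ---------------------------------------------------------------------------


def hull_volume_two_spheres(r1: float, r2: float, d: float) -> float:
    """Convex hull volume of two spheres: caps + tangent frustum (µm³).

    The bridging neck never protrudes beyond the tangent line, so this is
    also the hull volume of the full dumbbell.
    """
    if d + r2 <= r1:
        return 4.0 / 3.0 * math.pi * r1 ** 3
    sin_a = (r1 - r2) / d
    cos_a = math.sqrt(max(1.0 - sin_a * sin_a, 0.0))
    h1 = r1 * (1.0 + sin_a)
    h2 = r2 * (1.0 - sin_a)
    cap1 = math.pi * h1 * h1 * (3.0 * r1 - h1) / 3.0
    cap2 = math.pi * h2 * h2 * (3.0 * r2 - h2) / 3.0
    rho1, rho2 = r1 * cos_a, r2 * cos_a
    L = d - (r1 - r2) * sin_a
    frustum = math.pi * L * (rho1 * rho1 + rho1 * rho2 + rho2 * rho2) / 3.0
    return cap1 + cap2 + frustum


def _furrow_from_profile(prof: AxialProfile, n_samples: int = 2001) -> float:
    """Furrow diameter from a meridian profile.

    The furrow is the global minimum of the cross-section diameter along the
    major axis; if that minimum sits outside the middle 60% of the axis (as
    for convex cells, whose profile minima are the end caps), the mid-axis
    width is reported instead.
    """
    xs = np.linspace(prof.x_min, prof.x_max, n_samples)
    rho = prof.radius(xs)
    i = int(np.argmin(rho))
    span = prof.x_max - prof.x_min
    lo, hi = prof.x_min + 0.2 * span, prof.x_max - 0.2 * span
    if not (lo <= xs[i] <= hi):
        i = int(np.argmin(np.abs(xs - 0.5 * (prof.x_min + prof.x_max))))
    return 2.0 * float(rho[i])


def analytic_geometry(lobes: LobePair, cell_id: int = 1,
                      frame_index: int = 0) -> CellGeometry:
    """Exact shape descriptors of a lobe-pair shape.

    Volume and surface area come from piecewise closed-form integrals of the
    meridian profile; the convex hull is the two-sphere hull closed form;
    the aspect ratio follows the max-caliper / largest-inscribed-sphere
    definition (major = axial extent or big-lobe diameter, whichever is
    larger; minor = 2·radius_1).
    """
    prof = axial_profile(lobes)
    vol = prof.volume()
    surf = prof.surface_area()
    r1, r2, d = lobes.radius_1, lobes.radius_2, lobes.separation
    major = max(2.0 * r1, r1 + d + r2 if d + r2 > r1 else 2.0 * r1)
    minor = 2.0 * r1
    hull = hull_volume_two_spheres(r1, r2, d)
    hull = max(hull, vol)
    return CellGeometry(
        cell_id=cell_id,
        frame_index=frame_index,
        volume=vol,
        surface_area=surf,
        aspect_ratio=major / minor,
        hull_volume=hull,
        chvr=hull / vol,
        furrow_diameter=_furrow_from_profile(prof),
    )


def numeric_volume(lobes: LobePair, spacing: float | None = None) -> float:
    """Fine-grid voxel-counting volume oracle, independent of the closed forms.

    ``spacing`` defaults to radius_2/40 (isotropic).  Counts grid-cell
    centers inside the meridian-profile solid.
    """
    if spacing is None:
        spacing = lobes.radius_2 / 40.0
    prof = axial_profile(lobes)
    d = lobes.separation
    r1, r2 = lobes.radius_1, lobes.radius_2
    rmax = max(r1, r2, lobes.neck_radius)
    xs = np.arange(prof.x_min - spacing, prof.x_max + spacing, spacing)
    rho_prof = prof.radius(xs)
    # rotational symmetry: per axial slab, area = pi * rho^2 exactly; but a
    # voxel-counting oracle should not reuse pi*rho^2 — count 2-D grid cells
    ys = np.arange(-rmax - spacing, rmax + spacing, spacing)
    yy, zz = np.meshgrid(ys, ys, indexing="ij")
    rr = np.hypot(yy, zz)
    counts = np.array([(rr <= p).sum() for p in rho_prof], dtype=float)
    return float(counts.sum() * spacing ** 3)


# ---------------------------------------------------------------------------
# inverse problems used by the synthetic-scene generator
# ---------------------------------------------------------------------------


def _equal_lobes(r: float, sep_frac: float, neck_frac: float,
                 center: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 axis: tuple[float, float, float] = (0.0, 0.0, 1.0)) -> LobePair:
    """Equal-lobe pair from normalized separation/neck parameters.

    ``sep_frac`` in [0, 1] maps to center distance d = 2·r·sep_frac (1 =
    externally tangent); ``neck_frac`` in [0, 1] interpolates the waist
    between the sphere-union crease radius (0) and the convex fill (1).
    """
    d = 2.0 * r * sep_frac
    crease = _crease_radius(r, r, d)
    a_max = max_neck_radius(r, r, d)
    a = crease + neck_frac * (a_max - crease)
    c = np.asarray(center, float)
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    c1 = c - 0.5 * d * u
    c2 = c + 0.5 * d * u
    return LobePair(tuple(c1), tuple(c2), r, r, min(a, r))


def lobes_for_volume(volume: float, sep_frac: float, neck_frac: float,
                     center: tuple[float, float, float] = (0.0, 0.0, 0.0),
                     axis: tuple[float, float, float] = (0.0, 0.0, 1.0)) -> LobePair:
    """Equal-lobe pair with the given normalized shape and exact total volume.

    Solves the lobe radius by bisection so the analytic volume matches
    ``volume``; this is how the generator enforces volume conservation
    across a division time course.
    """
    r_sphere = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    def f(r):
        lp = _equal_lobes(r, sep_frac, neck_frac, center, axis)
        return axial_profile(lp).volume() - volume

    r = brentq(f, 0.3 * r_sphere, 1.2 * r_sphere, xtol=1e-12, rtol=1e-14)
    return _equal_lobes(r, sep_frac, neck_frac, center, axis)


def neck_radius_for_chvr(target_chvr: float, radius: float,
                         sep_frac: float = 1.0) -> LobePair:
    """Equal tangent-lobe pair whose analytic CHVR equals ``target_chvr``.

    CHVR decreases monotonically from the no-neck value (1.25 for tangent
    equal spheres) to 1 as the neck fills in; the waist is solved by
    bisection.  Used to construct calibration shapes such as the
    10%-concavity dumbbell (CHVR 1.1).
    """

    def f(neck_frac):
        lp = _equal_lobes(radius, sep_frac, neck_frac)
        g = analytic_geometry(lp)
        return g.chvr - target_chvr

    lo, hi = 1e-6, 1.0 - 1e-9
    if not (f(lo) > 0 > f(hi)):
        raise ValueError(f"CHVR {target_chvr} out of reachable range")
    nf = brentq(f, lo, hi, xtol=1e-12)
    return _equal_lobes(radius, sep_frac, nf)
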
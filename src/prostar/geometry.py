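"""Tetrahedron geometry for predictive coordinate coding.

Coordinates live as signed integers in milli-Ångström (mÅ), the native
fixed-point unit of PDB/mmCIF files (3 printed decimals).  All floating
point geometry happens in Å; the conversion occurs only at this module's
boundary.

An atom is predicted from three already-decoded *reference* atoms plus a
trained 6-tuple of distances ``(r12, r13, r23, f1, f2, f3)``: the base
triangle edge lengths and the distances from the apex to the three base
vertices.  Trilateration (intersecting three spheres) yields two
mirror-image apex candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

Coord3 = tuple[int, int, int]          # mÅ
Coord3f = tuple[float, float, float]   # mÅ, real-valued

#: base triangles flatter than this (Å^2) are treated as degenerate
COLLINEAR_AREA_TOL = 1e-6

_MA = 1000.0  # mÅ per Å


@dataclass(frozen=True)
class Observation:
    """Distance 6-tuple describing one tetrahedron instance (Å)."""

    r12: float
    r13: float
    r23: float
    f1: float
    f2: float
    f3: float

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.r12, self.r13, self.r23, self.f1, self.f2, self.f3)

    def is_degenerate(self, tol: float = 1e-9) -> bool:
        """True if any distance is non-positive or a triangle inequality
        fails beyond *tol* for either the base or the apex triples."""
        v = self.as_tuple()
        if any(d <= 0.0 for d in v):
            return True
        for a, b, c in ((self.r12, self.r13, self.r23),
                        (self.r12, self.f1, self.f2),
                        (self.r13, self.f1, self.f3),
                        (self.r23, self.f2, self.f3)):
            if a > b + c + tol or b > a + c + tol or c > a + b + tol:
                return True
        return False


@dataclass(frozen=True)
class RoundingSpec:
    """Lossy coordinate grid: step ``r`` (mÅ) guaranteeing a maximum
    Euclidean error ``m`` (mÅ); ``sqrt(3)*ceil(r/2) <= m`` by construction."""

    m: int
    r: int

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("grid step must be >= 1 mÅ")
        if self.r > 1 and math.sqrt(3.0) * math.ceil(self.r / 2) > self.m:
            raise ValueError("grid step violates the Euclidean error bound")


LOSSLESS_SPEC = RoundingSpec(m=0, r=1)


def rounding_step(m: int) -> RoundingSpec:
    """Largest grid step whose worst-case Euclidean rounding error stays
    within ``m`` mÅ.

    Starts from ``floor(2*m/sqrt(3))`` (per-axis error r/2 puts the grid
    cell corner at ``sqrt(3)*r/2 = m``) and shrinks until the integer
    half-step bound ``sqrt(3)*ceil(r/2) <= m`` holds.  ``m = 0`` means
    lossless (unit grid).
    """
    if m < 0:
        raise ValueError("max error must be >= 0")
    if m == 0:
        return LOSSLESS_SPEC
    r = max(1, int(2 * m / math.sqrt(3.0)))
    while r > 1 and math.sqrt(3.0) * math.ceil(r / 2) > m:
        r -= 1
    return RoundingSpec(m=m, r=r)


def round_coord(c: Coord3, spec: RoundingSpec) -> Coord3:
    """Snap each component to the grid: ``floor((x + floor(r/2)) / r) * r``
    with floor division toward -infinity."""
    r = spec.r
    if r == 1:
        return c
    h = r // 2
    return (((c[0] + h) // r) * r, ((c[1] + h) // r) * r, ((c[2] + h) // r) * r)


def eq1_cost(dx: int, dy: int, dz: int) -> float:
    """Estimated bit cost of a residual:
    ``log2(1+|dx|) + log2(1+|dy|) + log2(1+|dz|)``."""
    return (math.log2(1 + abs(dx)) + math.log2(1 + abs(dy))
            + math.log2(1 + abs(dz)))


def dist(a: Coord3, b: Coord3) -> float:
    """Euclidean distance in Å between two mÅ points."""
    return math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2
                     + (a[2] - b[2]) ** 2) / _MA


def observation_of(p1: Coord3, p2: Coord3, p3: Coord3, p4: Coord3) -> Observation:
    """Distance 6-tuple of the tetrahedron with base ``p1 p2 p3`` and apex
    ``p4`` (rigid-motion invariant)."""
    return Observation(
        r12=dist(p1, p2), r13=dist(p1, p3), r23=dist(p2, p3),
        f1=dist(p1, p4), f2=dist(p2, p4), f3=dist(p3, p4),
    )


def trilaterate(p1: Coord3, p2: Coord3, p3: Coord3,
                f1: float, f2: float, f3: float,
                ) -> tuple[Coord3f, Coord3f] | None:
    """Intersect spheres of radius ``f1,f2,f3`` (Å) around the three base
    points (mÅ).

    Returns the two mirror-image solutions (mÅ, real-valued) ordered as
    (+normal, -normal) where the normal is ``(p2-p1) x (p3-p1)``, or
    ``None`` when the base is degenerate or the spheres cannot meet
    (negative discriminant beyond tolerance).  Degenerate-apex cases
    (discriminant ~ 0) return two equal points.
    """
    ax, ay, az = p1[0] / _MA, p1[1] / _MA, p1[2] / _MA
    bx, by, bz = p2[0] / _MA - ax, p2[1] / _MA - ay, p2[2] / _MA - az
    cx, cy, cz = p3[0] / _MA - ax, p3[1] / _MA - ay, p3[2] / _MA - az

    d = math.sqrt(bx * bx + by * by + bz * bz)
    if d <= 0.0:
        return None
    exx, exy, exz = bx / d, by / d, bz / d
    i = exx * cx + exy * cy + exz * cz
    tyx, tyy, tyz = cx - i * exx, cy - i * exy, cz - i * exz
    j = math.sqrt(tyx * tyx + tyy * tyy + tyz * tyz)
    # triangle area = d*j/2
    if d * j / 2.0 < COLLINEAR_AREA_TOL:
        return None
    eyx, eyy, eyz = tyx / j, tyy / j, tyz / j
    ezx = exy * eyz - exz * eyy
    ezy = exz * eyx - exx * eyz
    ezz = exx * eyy - exy * eyx

    x = (f1 * f1 - f2 * f2 + d * d) / (2.0 * d)
    y = (f1 * f1 - f3 * f3 + i * i + j * j - 2.0 * i * x) / (2.0 * j)
    z2 = f1 * f1 - x * x - y * y
    if z2 < 0.0:
        if z2 < -1e-9 * max(1.0, f1 * f1):
            return None
        z2 = 0.0
    z = math.sqrt(z2)

    px = ax + x * exx + y * eyx
    py = ay + x * exy + y * eyy
    pz = az + x * exz + y * eyz
    q_plus = ((px + z * ezx) * _MA, (py + z * ezy) * _MA, (pz + z * ezz) * _MA)
    q_minus = ((px - z * ezx) * _MA, (py - z * ezy) * _MA, (pz - z * ezz) * _MA)
    return q_plus, q_minus


def round_prediction(q: Coord3f) -> Coord3:
    """Round a real-valued prediction to integer mÅ, half away from zero.

    Encoder and decoder both apply this before computing/adding residuals
    so that floating-point trilateration never leaks into the stream.
    """
    return (_half_away(q[0]), _half_away(q[1]), _half_away(q[2]))


def _half_away(v: float) -> int:
    return math.floor(v + 0.5) if v >= 0 else math.ceil(v - 0.5)


def canonical_base(r12: float, r13: float, r23: float,
                   ) -> tuple[Coord3, Coord3, Coord3] | None:
    """Embed a base triangle canonically: p1 at the origin, p2 on +x,
    p3 in the xy half-plane (y > 0).  Returns mÅ integer points, or None
    for a degenerate triple.  Used when an observation must be turned back
    into coordinates (training cost estimation, centroid pruning)."""
    if r12 <= 0.0:
        return None
    x3 = (r12 * r12 + r13 * r13 - r23 * r23) / (2.0 * r12)
    y3sq = r13 * r13 - x3 * x3
    if y3sq <= 0.0:
        return None
    y3 = math.sqrt(y3sq)
    p1 = (0, 0, 0)
    p2 = (_half_away(r12 * _MA), 0, 0)
    p3 = (_half_away(x3 * _MA), _half_away(y3 * _MA), 0)
    return p1, p2, p3
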
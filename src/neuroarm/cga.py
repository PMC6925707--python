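"""Conformal geometric algebra G(4,1) over the null basis (e0, e1, e2, e3, einf).

The 3-D Euclidean space {e1, e2, e3} is extended with two null directions:
e0 (the point at the origin) and einf (the point at infinity), satisfying

    e1^2 = e2^2 = e3^2 = +1,    e0^2 = einf^2 = 0,    e0 . einf = -1.

In this algebra the classical geometric primitives are algebraic elements:
a Euclidean position x embeds as the null vector P = x + (1/2)x^2 einf + e0,
spheres and planes are grade-1 vectors, and intersections (meets) are wedge
products.  Every multivector is a vector of 32 real coefficients, one per
basis blade.

Internally the product tables are derived once, at import time, from the
diagonal basis (e1, e2, e3, e+, e-) with signature (+,+,+,+,-), where
e0 = (e- - e+)/2 and einf = e- + e+.  All public coefficients are expressed
on the null basis, with blades ordered by bitmask over (e0, e1, e2, e3,
einf) = bits (0, 1, 2, 3, 4); a blade is the wedge of its set bits in
ascending order.  Index 0 is the scalar, index 1 is e0, index 2 is e1,
index 3 is e0^e1, ... index 31 is e0^e1^e2^e3^einf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Multivector",
    "GeometricEntity",
    "OrientedAngleFrame",
    "DegenerateEntityError",
    "ImaginaryEntityError",
    "BLADE_NAMES",
    "blade",
    "scalar",
    "e0",
    "e1",
    "e2",
    "e3",
    "einf",
    "product",
    "dual",
    "undual",
    "embed_point",
    "extract_euclidean",
    "euclidean_vector",
    "make_sphere",
    "make_plane",
    "make_entity",
    "meet",
    "point_pair_points",
    "line_direction",
    "plane_normal",
    "oriented_angle",
    "sphere_params",
    "circle_params",
]

N_BLADES = 32
_VEC_NAMES = ("e0", "e1", "e2", "e3", "einf")

#: Human-readable name of each of the 32 basis blades, in coefficient order.
BLADE_NAMES: tuple[str, ...] = tuple(
    "1" if m == 0 else "^".join(_VEC_NAMES[i] for i in range(5) if m & (1 << i))
    for m in range(N_BLADES)
)

GRADES = np.array([bin(m).count("1") for m in range(N_BLADES)])


class DegenerateEntityError(ValueError):
    """A geometric construction collapsed (vanishing wedge, zero direction...)."""


class ImaginaryEntityError(ValueError):
    """An intersection has negative squared radius: no real solution."""


# --------------------------------------------------------------------------
# product tables, built once from the diagonal basis (e1,e2,e3,e+,e-)
# --------------------------------------------------------------------------

def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sig = (1.0, 1.0, 1.0, 1.0, -1.0)

    def gp_basis(a: int, b: int) -> tuple[int, float]:
        # canonical-reordering sign, then metric contraction of shared vectors
        s = 0
        t = a >> 1
        while t:
            s += bin(t & b).count("1")
            t >>= 1
        sign = -1.0 if s & 1 else 1.0
        for i in range(5):
            if a & b & (1 << i):
                sign *= sig[i]
        return a ^ b, sign

    # dense geometric-product tensor on the diagonal basis
    D = np.zeros((N_BLADES, N_BLADES, N_BLADES))
    for a in range(N_BLADES):
        for b in range(N_BLADES):
            m, s = gp_basis(a, b)
            D[a, b, m] = s

    grades_diag = GRADES  # popcount works for either basis ordering

    def outer_diag(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # outer product = grade-(r+s) part, blade pair by blade pair
        out = np.zeros(N_BLADES)
        for a in np.nonzero(x)[0]:
            for b in np.nonzero(y)[0]:
                if a & b:
                    continue
                m, s = gp_basis(a, b)
                out[m] += x[a] * y[b] * s
        return out

    # images of the null basis vectors on the diagonal basis
    # diagonal bit order: (e1,e2,e3,e+,e-) = bits (0,1,2,3,4)
    img = np.zeros((5, N_BLADES))
    img[0, 1 << 3] = -0.5  # e0 = (e- - e+)/2
    img[0, 1 << 4] = 0.5
    img[1, 1 << 0] = 1.0
    img[2, 1 << 1] = 1.0
    img[3, 1 << 2] = 1.0
    img[4, 1 << 3] = 1.0  # einf = e+ + e-
    img[4, 1 << 4] = 1.0

    # change of basis T: null-blade coefficients -> diagonal coefficients
    T = np.zeros((N_BLADES, N_BLADES))
    for m in range(N_BLADES):
        acc = np.zeros(N_BLADES)
        acc[0] = 1.0
        for i in range(5):
            if m & (1 << i):
                acc = outer_diag(acc, img[i])
        T[:, m] = acc
    Tinv = np.linalg.inv(T)

    # geometric product on the null basis: G[a,b,c]
    G = np.einsum("ia,jb,ijk,ck->abc", T, T, D, Tinv, optimize=True)
    G[np.abs(G) < 1e-12] = 0.0

    # grade masks for blade-wise inner/outer products
    ga = GRADES[:, None, None]
    gb = GRADES[None, :, None]
    gc = GRADES[None, None, :]
    O = np.where(gc == ga + gb, G, 0.0)
    I = np.where(gc == np.abs(ga - gb), G, 0.0)
    return G, O, I


_GP, _OP, _IP = _build_tables()


# --------------------------------------------------------------------------
# Multivector
# --------------------------------------------------------------------------

class Multivector:
    """Dense element of G(4,1): 32 coefficients on the null blade basis.

    Operators: ``*`` geometric product, ``^`` outer product, ``|`` inner
    product (grade |r-s| part, blade-wise), ``+``/``-``, and scalar
    multiplication/division.
    """

    __slots__ = ("coeffs",)
    __array_priority__ = 100  # keep numpy scalars from hijacking operators

    def __init__(self, coeffs: Iterable[float] | None = None):
        if coeffs is None:
            self.coeffs = np.zeros(N_BLADES)
        else:
            self.coeffs = np.asarray(coeffs, dtype=float).copy()
            if self.coeffs.shape != (N_BLADES,):
                raise ValueError("a multivector has exactly 32 coefficients")

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        return Multivector(self.coeffs + _as_mv(other).coeffs)

    __radd__ = __add__

    def __sub__(self, other):
        return Multivector(self.coeffs - _as_mv(other).coeffs)

    def __rsub__(self, other):
        return Multivector(_as_mv(other).coeffs - self.coeffs)

    def __neg__(self):
        return Multivector(-self.coeffs)

    def __mul__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return Multivector(self.coeffs * float(other))
        return Multivector(
            np.einsum("a,b,abc->c", self.coeffs, _as_mv(other).coeffs, _GP)
        )

    def __rmul__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return Multivector(self.coeffs * float(other))
        return _as_mv(other) * self

    def __truediv__(self, s: float):
        return Multivector(self.coeffs / float(s))

    def __xor__(self, other):
        return Multivector(
            np.einsum("a,b,abc->c", self.coeffs, _as_mv(other).coeffs, _OP)
        )

    def __or__(self, other):
        return Multivector(
            np.einsum("a,b,abc->c", self.coeffs, _as_mv(other).coeffs, _IP)
        )

    # -- structure ------------------------------------------------------
    def grade(self, k: int) -> "Multivector":
        out = np.where(GRADES == k, self.coeffs, 0.0)
        return Multivector(out)

    def grades(self, tol: float = 1e-12) -> list[int]:
        scale = max(np.abs(self.coeffs).max(), 1.0)
        return sorted({int(g) for g, c in zip(GRADES, self.coeffs)
                       if abs(c) > tol * scale})

    @property
    def scalar_part(self) -> float:
        return float(self.coeffs[0])

    def norm(self) -> float:
        return float(np.linalg.norm(self.coeffs))

    def normalized_by_max(self) -> "Multivector":
        m = np.abs(self.coeffs).max()
        if m == 0:
            raise DegenerateEntityError("cannot normalize the zero multivector")
        return Multivector(self.coeffs / m)

    def inverse(self) -> "Multivector":
        """Inverse for versor-like elements satisfying X*X = scalar."""
        sq = (self * self).coeffs
        s = sq[0]
        if abs(s) < 1e-300 or np.abs(sq[1:]).max() > 1e-9 * max(abs(s), 1.0):
            raise ValueError("multivector has no simple scalar-square inverse")
        return self / s

    def is_zero(self, tol: float = 1e-10, ref: float = 1.0) -> bool:
        return bool(np.abs(self.coeffs).max() <= tol * ref)

    def close_to(self, other: "Multivector", tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.coeffs, _as_mv(other).coeffs, atol=tol))

    def __repr__(self) -> str:
        terms = [
            f"{c:+.6g}*{BLADE_NAMES[i]}"
            for i, c in enumerate(self.coeffs)
            if abs(c) > 1e-12
        ]
        return "Multivector(" + (" ".join(terms) if terms else "0") + ")"


def _as_mv(x) -> Multivector:
    if isinstance(x, Multivector):
        return x
    if isinstance(x, (int, float, np.floating, np.integer)):
        c = np.zeros(N_BLADES)
        c[0] = float(x)
        return Multivector(c)
    raise TypeError(f"cannot interpret {type(x).__name__} as a multivector")


def blade(mask: int, coeff: float = 1.0) -> Multivector:
    c = np.zeros(N_BLADES)
    c[mask] = coeff
    return Multivector(c)


def scalar(v: float) -> Multivector:
    return blade(0, v)


e0 = blade(1 << 0)
e1 = blade(1 << 1)
e2 = blade(1 << 2)
e3 = blade(1 << 3)
einf = blade(1 << 4)

# paper-ordered inverse pseudoscalar: e0 ^ e3 ^ e2 ^ e1 ^ einf
_IC_INV = ((((e0 ^ e3) ^ e2) ^ e1) ^ einf)
_IC = _IC_INV.inverse()
#: sign of dual(dual(A)) relative to A -- uniform over all 32 blades
DUAL_SQUARE_SIGN = float((_IC_INV * _IC_INV).scalar_part)


def product(a: Multivector, b: Multivector,
            mode: Literal["geometric", "inner", "outer"] = "geometric") -> Multivector:
    """Geometric, inner or outer product; geometric = inner + outer on vectors."""
    if mode == "geometric":
        return a * b
    if mode == "inner":
        return a | b
    if mode == "outer":
        return a ^ b
    raise ValueError(f"unknown product mode {mode!r}")


def dual(A: Multivector) -> Multivector:
    """A* = A Ic^-1 with Ic^-1 = e0^e3^e2^e1^einf."""
    return A * _IC_INV


def undual(A: Multivector) -> Multivector:
    """Inverse of :func:`dual` (multiplication by Ic)."""
    return A * _IC


# --------------------------------------------------------------------------
# entities
# --------------------------------------------------------------------------

EntityKind = Literal["point", "point_pair", "line", "circle", "plane", "sphere"]

#: grade of each kind in standard (inner-product) representation
_STANDARD_GRADE = {
    "point": 1,
    "sphere": 1,
    "plane": 1,
    "circle": 2,
    "line": 2,
    "point_pair": 3,
}


@dataclass
class GeometricEntity:
    """A classified multivector: a point, point pair, line, circle, plane or sphere.

    ``representation`` records whether ``mv`` is the standard (inner-product
    null space) form or the dual (outer-product / wedge-of-points) form.
    """

    mv: Multivector
    kind: EntityKind
    representation: Literal["standard", "dual"] = "standard"

    def as_standard(self) -> "GeometricEntity":
        if self.representation == "standard":
            return self
        return GeometricEntity(dual(self.mv), self.kind, "standard")

    def as_dual(self) -> "GeometricEntity":
        if self.representation == "dual":
            return self
        return GeometricEntity(dual(self.mv), self.kind, "dual")

    def contains(self, p: "GeometricEntity | np.ndarray", tol: float = 1e-7) -> bool:
        """Incidence test: X lies on the entity.

        Standard form: X | A = 0; dual form: X ^ A = 0 (scale-relative).
        """
        if not isinstance(p, GeometricEntity):
            p = embed_point(p)
        X = p.mv
        ref = max(X.norm() * self.mv.norm(), 1e-30)
        if self.representation == "standard":
            r = X | self.mv
        else:
            r = X ^ self.mv
        return bool(np.abs(r.coeffs).max() <= tol * ref)

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "representation": self.representation,
            "coeffs": self.mv.coeffs.tolist(),
        }

    @staticmethod
    def from_json_dict(d: dict) -> "GeometricEntity":
        return GeometricEntity(Multivector(d["coeffs"]), d["kind"], d["representation"])


@dataclass
class OrientedAngleFrame:
    """Two direction vectors plus the reference bivector fixing the CCW sense."""

    alpha: np.ndarray
    beta: np.ndarray
    orientation: Multivector  # unit Euclidean bivector

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)


def euclidean_vector(x: Sequence[float]) -> Multivector:
    x = np.asarray(x, dtype=float)
    return e1 * x[0] + e2 * x[1] + e3 * x[2]


def embed_point(x: Sequence[float]) -> GeometricEntity:
    """Conformal embedding P = x + (1/2) x^2 einf + e0 of a Euclidean position."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("point coordinates must be finite")
    mv = euclidean_vector(x) + einf * (0.5 * float(x @ x)) + e0
    return GeometricEntity(mv, "point", "standard")


def extract_euclidean(P: GeometricEntity | Multivector) -> np.ndarray:
    """Euclidean position of a conformal point (normalizes the e0 coefficient)."""
    mv = P.mv if isinstance(P, GeometricEntity) else P
    w = mv.coeffs[1]  # e0 coefficient
    scale = np.abs(mv.coeffs).max()
    if scale == 0 or abs(w) < 1e-10 * scale:
        raise DegenerateEntityError("point at infinity (zero e0 coefficient)")
    return mv.coeffs[[2, 4, 8]] / w  # e1, e2, e3 coefficients


def make_sphere(center: Sequence[float], r: float) -> GeometricEntity:
    """Standard-form sphere s = P - (1/2) r^2 einf; r = 0 gives the point itself."""
    if r < 0:
        raise ValueError("sphere radius must be nonnegative")
    P = embed_point(center).mv
    return GeometricEntity(P - einf * (0.5 * r * r), "sphere", "standard")


def make_plane(normal: Sequence[float], d: float) -> GeometricEntity:
    """Standard-form plane pi = n_hat + d einf (d = signed distance, mm)."""
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise DegenerateEntityError("plane normal must be nonzero")
    n = n / nn
    return GeometricEntity(euclidean_vector(n) + einf * d, "plane", "standard")


_POINT_COUNT = {"line": 2, "point_pair": 2, "circle": 3, "plane": 3, "sphere": 4}


def make_entity(points: Sequence[Sequence[float]], kind: EntityKind) -> GeometricEntity:
    """Wedge-of-points construction (dual representation, Table-style).

    line: x1^x2^einf, point_pair: x1^x2, circle: x1^x2^x3,
    plane: x1^x2^x3^einf, sphere: x1^x2^x3^x4.
    """
    if kind not in _POINT_COUNT:
        raise ValueError(f"unknown entity kind {kind!r}")
    need = _POINT_COUNT[kind]
    if len(points) != need:
        raise ValueError(f"{kind} needs {need} points, got {len(points)}")
    mvs = [embed_point(p).mv for p in points]
    acc = mvs[0]
    for m in mvs[1:]:
        acc = acc ^ m
    if kind in ("line", "plane"):
        acc = acc ^ einf
    ref = float(np.prod([m.norm() for m in mvs]))
    if acc.is_zero(tol=1e-10, ref=max(ref, 1e-30)):
        raise DegenerateEntityError(f"degenerate entity: {kind} from coplanar/coincident points")
    return GeometricEntity(acc, kind, "dual")


# meet result kinds for standard-form wedges
_MEET_KIND = {
    frozenset(("sphere", "sphere")): "circle",
    frozenset(("sphere", "plane")): "circle",
    frozenset(("plane", "plane")): "line",
    frozenset(("circle", "plane")): "point_pair",
    frozenset(("circle", "sphere")): "point_pair",
    frozenset(("line", "sphere")): "point_pair",
    frozenset(("line", "plane")): "point",
}


def meet(A: GeometricEntity, B: GeometricEntity) -> GeometricEntity:
    """Intersection of two entities: the wedge of their standard forms.

    (Equivalently the dual of the wedge of the dual forms.)  Raises
    ``ImaginaryEntityError`` when the intersection has negative squared
    radius (disjoint/non-touching inputs); tangency gives a zero-radius
    result.
    """
    key = frozenset((A.kind, B.kind)) if A.kind != B.kind else frozenset((A.kind,))
    kind = _MEET_KIND.get(frozenset((A.kind, B.kind)))
    if kind is None:
        raise ValueError(f"unsupported meet: {A.kind} with {B.kind}")
    M = A.as_standard().mv ^ B.as_standard().mv
    ref = max(A.mv.norm() * B.mv.norm(), 1e-30)
    if M.is_zero(tol=1e-12, ref=ref):
        raise DegenerateEntityError("meet vanishes: coincident or dependent entities")
    ent = GeometricEntity(M, kind, "standard")
    if kind == "circle":
        _, r2 = _circle_center_r2(ent)
        if r2 < -_imag_tol(ent):
            raise ImaginaryEntityError("imaginary circle: entities do not intersect")
    elif kind == "point_pair":
        pp = ent.as_dual().mv
        if (pp * pp).scalar_part < -_imag_tol(ent):
            raise ImaginaryEntityError("imaginary point pair: no real intersection")
    return ent


def _imag_tol(ent: GeometricEntity) -> float:
    return 1e-10 * max(ent.mv.norm() ** 2, 1.0)


def point_pair_points(Pp: GeometricEntity) -> tuple[np.ndarray, np.ndarray]:
    """Extract the two points: P = (Pp +/- sqrt(Pp^2)) / (-einf . Pp).

    Operates on the dual (wedge-of-two-points, grade-2) form.  The first
    returned point is the branch with the larger e3 (z) coordinate after
    normalization; ties are broken toward the larger e1 (x) coordinate.
    Tangent pairs (Pp^2 = 0) return two equal points.
    """
    if Pp.kind != "point_pair":
        raise ValueError("entity is not a point pair")
    pp = Pp.as_dual().mv
    sq = (pp * pp).scalar_part
    scale = pp.norm() ** 2
    if sq < -1e-10 * max(scale, 1.0):
        raise ImaginaryEntityError("no real intersection: imaginary point pair")
    root = np.sqrt(max(sq, 0.0))
    denom = -(einf | pp)
    d2 = (denom * denom).scalar_part
    if d2 <= 1e-20 * max(scale, 1.0):
        raise DegenerateEntityError("degenerate point pair (contains the point at infinity)")
    dinv = denom / d2
    pa = extract_euclidean((pp + scalar(root)) * dinv)
    pb = extract_euclidean((pp - scalar(root)) * dinv)
    key = lambda p: (round(p[2], 9), round(p[0], 9))
    return (pa, pb) if key(pa) >= key(pb) else (pb, pa)


def line_direction(l: GeometricEntity) -> np.ndarray:
    """Unit direction of a line via (l . e0) . einf on the dual (point-wedge) form.

    Sign follows the order of the two construction points (x1 -> x2).
    """
    if l.kind != "line":
        raise ValueError("entity is not a line")
    ld = l.as_dual().mv
    d = (ld | e0) | einf
    v = d.coeffs[[2, 4, 8]]
    n = np.linalg.norm(v)
    if n < 1e-12 * max(ld.norm(), 1.0):
        raise DegenerateEntityError("degenerate line")
    # the raw contraction yields x1 - x2; flip to the construction order
    return -v / n


def plane_normal(pi: GeometricEntity) -> np.ndarray:
    """Unit normal of a plane via (pi* ^ einf) . e0.

    Sign convention fixed so the base plane e0^e1^e2^einf has normal +e3.
    """
    if pi.kind != "plane":
        raise ValueError("entity is not a plane")
    ps = pi.as_standard().mv  # standard form n + d einf is the dual of the wedge form
    d = (ps ^ einf) | e0
    v = d.coeffs[[2, 4, 8]]
    n = np.linalg.norm(v)
    if n < 1e-12 * max(ps.norm(), 1.0):
        raise DegenerateEntityError("degenerate plane")
    return v / n  # fixed module convention (see docstring)


def oriented_angle(frame: OrientedAngleFrame) -> float:
    """Signed angle from alpha to beta in (-pi, pi].

    theta = atan2(-<(alpha ^ beta) N>_0, alpha . beta) for the unit
    orientation bivector N; reversing N flips the sign.
    """
    a, b = frame.alpha, frame.beta
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateEntityError("oriented_angle needs nonzero vectors")
    A = euclidean_vector(a / na)
    B = euclidean_vector(b / nb)
    N = frame.orientation
    nn = np.sqrt(abs((N * N).scalar_part))
    if nn == 0:
        raise DegenerateEntityError("orientation bivector must be nonzero")
    N = N / nn
    sin_part = -((A ^ B) * N).scalar_part
    cos_part = (A | B).scalar_part
    ang = float(np.arctan2(sin_part, cos_part))
    if ang == -np.pi:  # documented: theta in (-pi, pi]
        ang = np.pi
    return ang


# --------------------------------------------------------------------------
# round-entity parameters (used by the IK construction and its tests)
# --------------------------------------------------------------------------

def sphere_params(s: GeometricEntity) -> tuple[np.ndarray, float]:
    """(center, radius) of a standard-form sphere."""
    mv = s.as_standard().mv
    w = mv.coeffs[1]
    if abs(w) < 1e-12 * max(np.abs(mv.coeffs).max(), 1e-30):
        raise DegenerateEntityError("not a proper sphere (zero e0 coefficient)")
    mv = mv / w
    c = mv.coeffs[[2, 4, 8]]
    r2 = float(c @ c) - 2.0 * mv.coeffs[16]  # x^2/2 - einf-coeff = r^2/2
    return c, float(np.sqrt(max(r2, 0.0)))


def _circle_center_r2(c: GeometricEntity) -> tuple[np.ndarray, float]:
    """Center and squared radius of a standard-form circle C = s ^ pi (grade 2).

    Center from the sandwich C einf C; squared radius from
    r^2 = - C C~ ... computed via the two defining spheres recovered from
    the carrier decomposition; here via the standard formula
    r^2 = (C * C).scalar / (einf | C)^2 with sign fixed by the algebra.
    """
    mv = c.as_standard().mv
    ctr_mv = mv * einf * mv
    center = extract_euclidean(ctr_mv.grade(1))
    carrier = einf | mv  # grade-1 plane (radical plane of the two spheres)
    num = (mv * mv).scalar_part
    den = (carrier * carrier).scalar_part
    if abs(den) < 1e-20:
        raise DegenerateEntityError("degenerate circle carrier")
    r2 = -num / den
    return center, float(r2)


def circle_params(c: GeometricEntity) -> tuple[np.ndarray, float, np.ndarray]:
    """(center, radius, unit plane normal) of a circle entity."""
    if c.kind != "circle":
        raise ValueError("entity is not a circle")
    center, r2 = _circle_center_r2(c)
    if r2 < -_imag_tol(c):
        raise ImaginaryEntityError("imaginary circle")
    carrier = einf | c.as_standard().mv
    n = carrier.coeffs[[2, 4, 8]]
    n = n / np.linalg.norm(n)
    return center, float(np.sqrt(max(r2, 0.0))), n
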
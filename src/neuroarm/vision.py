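"""Tabletop artificial vision: colored-marker localization on a 400x400 mm plane.

Four 30x30 mm corner markers (cyan, orange, magenta, yellow, with centroids
at fixed table coordinates) anchor a planar homography between raw image
pixels and table millimeters.  Item centroids (a blue disk and two target
stickers) are detected by HSV color segmentation, mapped through the
homography to table coordinates, and finally expressed in the robot frame,
where the robot sits at the origin on the table edge nearest to it:
x in [-200, 200] mm, y in [0, 400] mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure as skmeasure

__all__ = [
    "Homography",
    "FrameTransform",
    "TableScene",
    "ColorSpec",
    "DEFAULT_COLOR_SPECS",
    "MARKER_WORLD_MM",
    "ColorNotFoundError",
    "MarkerSetIncompleteError",
    "detect_blobs",
    "estimate_homography",
    "map_point",
    "table_to_robot",
    "robot_to_table",
    "locate_scene",
]

#: fixed table-frame centroids of the four corner markers, mm
MARKER_WORLD_MM: dict[str, tuple[float, float]] = {
    "cyan": (15.0, 15.0),
    "orange": (385.0, 15.0),
    "magenta": (15.0, 385.0),
    "yellow": (385.0, 385.0),
}

MIN_BLOB_AREA_PX = 50


class ColorNotFoundError(ValueError):
    """No sufficiently large connected component matched the color window."""


class MarkerSetIncompleteError(ValueError):
    """At least one corner marker is missing: no homography can be estimated."""


@dataclass(frozen=True)
class ColorSpec:
    """HSV window: hue in [0,1) (lo > hi wraps around red), min saturation/value."""

    hue_lo: float
    hue_hi: float
    sat_min: float = 0.35
    val_min: float = 0.25

    def mask(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        if self.hue_lo <= self.hue_hi:
            hm = (h >= self.hue_lo) & (h <= self.hue_hi)
        else:  # wrap-around (red)
            hm = (h >= self.hue_lo) | (h <= self.hue_hi)
        return hm & (s >= self.sat_min) & (v >= self.val_min)


DEFAULT_COLOR_SPECS: dict[str, ColorSpec] = {
    "cyan": ColorSpec(0.44, 0.56),
    "orange": ColorSpec(0.06, 0.13),
    "magenta": ColorSpec(0.78, 0.90),
    "yellow": ColorSpec(0.13, 0.20),
    "blue": ColorSpec(0.58, 0.72),
    "green": ColorSpec(0.25, 0.42),
    "red": ColorSpec(0.95, 0.03),
}


def detect_blobs(image: np.ndarray, spec: ColorSpec,
                 min_area: int = MIN_BLOB_AREA_PX):
    """Largest connected component matching an HSV window.

    Returns ``(mask, centroid_uv, contour)`` where ``centroid_uv`` is the
    intensity-weighted first moment in (u, v) = (column, row) pixels and
    ``contour`` is the component's boundary polyline in the same convention.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    rgb = img[..., :3].astype(float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hsv = skcolor.rgb2hsv(rgb)
    raw = spec.mask(hsv)
    if not raw.any():
        raise ColorNotFoundError("color not found")
    labels = skmeasure.label(raw)
    props = skmeasure.regionprops(labels)
    props = [p for p in props if p.area >= min_area]
    if not props:
        raise ColorNotFoundError("color not found (all components below min area)")
    best = max(props, key=lambda p: p.area)
    mask = labels == best.label
    weight = hsv[..., 2] * mask
    total = weight.sum()
    vv, uu = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    centroid = np.array([(uu * weight).sum() / total, (vv * weight).sum() / total])
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)[:, ::-1] if contours else np.empty((0, 2))
    return mask, centroid, contour


# --------------------------------------------------------------------------
# homography
# --------------------------------------------------------------------------

@dataclass
class Homography:
    """3x3 projective map, defined up to scale; here image (u,v) -> table (x,y) mm."""

    H: np.ndarray

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(self.H)) < 1e-15:
            raise ValueError("degenerate homography (rank < 3)")
        if abs(self.H[2, 2]) > 1e-12:
            self.H = self.H / self.H[2, 2]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H))


def _hartley_normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    homog = np.column_stack([pts, np.ones(len(pts))]) @ T.T
    return homog, T


def estimate_homography(src_pts: np.ndarray, dst_pts: np.ndarray) -> Homography:
    """Hartley-normalized direct linear transform, exact for 4 correspondences.

    ``src_pts`` map to ``dst_pts``; both are (N >= 4, 2) arrays.  Raises on
    degenerate configurations (three collinear source or target points make
    the design matrix rank-deficient).
    """
    src = np.asarray(src_pts, dtype=float)
    dst = np.asarray(dst_pts, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 4 or src.shape[1] != 2:
        raise ValueError("need matching (N>=4, 2) point arrays")
    if src.shape[0] == 4:  # minimal case: no 3 points may be collinear
        from itertools import combinations

        for pts in (src, dst):
            scale = max(np.ptp(pts, axis=0).max(), 1e-12)
            for i, j, k in combinations(range(4), 3):
                u, v = pts[j] - pts[i], pts[k] - pts[i]
                if abs(u[0] * v[1] - u[1] * v[0]) < 1e-9 * scale * scale:
                    raise ValueError("degenerate homography: collinear points")
    sh, Ts = _hartley_normalize(src)
    dh, Td = _hartley_normalize(dst)
    rows = []
    for (x, y, w), (u, v, q) in zip(sh, dh):
        rows.append([0, 0, 0, -q * x, -q * y, -q * w, v * x, v * y, v * w])
        rows.append([q * x, q * y, q * w, 0, 0, 0, -u * x, -u * y, -u * w])
    A = np.array(rows)
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-9 * sv[0]:
        raise ValueError("degenerate homography: collinear correspondences")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return Homography(H)


def map_point(H: Homography, p: np.ndarray) -> np.ndarray:
    """Apply the projective map to one (u, v) point (or an (N,2) batch)."""
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ H.H.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("point maps to infinity under the homography")
    out = hom[:, :2] / w[:, None]
    return out[0] if single else out


# --------------------------------------------------------------------------
# table -> robot frame
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameTransform:
    """Planar isometry from table coordinates to robot coordinates.

    The composition (translate by (-200, -400), rotate by pi, flip x)
    collapses to (x, y) -> (x - 200, 400 - y): the robot sits at table
    point (200, 400), its +y axis pointing across the table.
    """

    translation: tuple[float, float] = (-200.0, -400.0)
    rotation: np.ndarray = field(
        default_factory=lambda: np.array([[np.cos(np.pi), -np.sin(np.pi)],
                                          [np.sin(np.pi), np.cos(np.pi)]]))
    axis_flip: tuple[float, float] = (-1.0, 1.0)

    def apply(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        q = (p + np.asarray(self.translation)) @ self.rotation.T
        return q * np.asarray(self.axis_flip)

    def invert(self, p: np.ndarray) -> np.ndarray:
        q = np.asarray(p, dtype=float) * np.asarray(self.axis_flip)
        return q @ np.linalg.inv(self.rotation).T - np.asarray(self.translation)


def table_to_robot(p_table: np.ndarray, t: FrameTransform | None = None) -> np.ndarray:
    """Table mm -> robot mm; an exact isometry of the plane."""
    return (t or FrameTransform()).apply(p_table)


def robot_to_table(p_robot: np.ndarray, t: FrameTransform | None = None) -> np.ndarray:
    return (t or FrameTransform()).invert(p_robot)


# --------------------------------------------------------------------------
# scene
# --------------------------------------------------------------------------

@dataclass
class TableScene:
    """Localized scene: marker/item centroids in image, table and robot frames."""

    marker_centroids_img: dict[str, np.ndarray]
    marker_centroids_world: dict[str, tuple[float, float]]
    homography: Homography
    disk_table: np.ndarray | None = None
    targets_table: dict[str, np.ndarray] = field(default_factory=dict)
    disk_robot: np.ndarray | None = None
    targets_robot: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def disk_absent(self) -> bool:
        return self.disk_table is None

    def to_json_dict(self) -> dict:
        def pair(v):
            return None if v is None else [float(v[0]), float(v[1])]

        return {
            "markers": {
                c: {
                    "img_px": pair(self.marker_centroids_img[c]),
                    "table_mm": list(self.marker_centroids_world[c]),
                    "robot_mm": pair(table_to_robot(np.array(self.marker_centroids_world[c]))),
                }
                for c in self.marker_centroids_img
            },
            "disk": {"table_mm": pair(self.disk_table), "robot_mm": pair(self.disk_robot)},
            "targets": {
                c: {"table_mm": pair(self.targets_table[c]),
                    "robot_mm": pair(self.targets_robot.get(c))}
                for c in self.targets_table
            },
            "homography": self.homography.H.tolist(),
        }


def locate_scene(image: np.ndarray,
                 color_specs: dict[str, ColorSpec] | None = None,
                 transform: FrameTransform | None = None,
                 target_colors: tuple[str, str] = ("green", "red")) -> TableScene:
    """Full localization: markers -> homography -> items in robot frame.

    All four markers must be visible; the disk and targets are optional and
    simply flagged absent when not found.
    """
    specs = dict(DEFAULT_COLOR_SPECS)
    if color_specs:
        specs.update(color_specs)
    transform = transform or FrameTransform()

    img_pts, world_pts, found = [], [], {}
    missing = []
    for name, world in MARKER_WORLD_MM.items():
        try:
            _, centroid, _ = detect_blobs(image, specs[name])
        except ColorNotFoundError:
            missing.append(name)
            continue
        found[name] = centroid
        img_pts.append(centroid)
        world_pts.append(world)
    if missing:
        raise MarkerSetIncompleteError(f"marker set incomplete: missing {missing}")

    H = estimate_homography(np.array(img_pts), np.array(world_pts))
    scene = TableScene(marker_centroids_img=found,
                       marker_centroids_world=dict(MARKER_WORLD_MM),
                       homography=H)

    try:
        _, c, _ = detect_blobs(image, specs["blue"])
        scene.disk_table = map_point(H, c)
        scene.disk_robot = table_to_robot(scene.disk_table, transform)
    except ColorNotFoundError:
        pass
    for name in target_colors:
        try:
            _, c, _ = detect_blobs(image, specs[name])
            scene.targets_table[name] = map_point(H, c)
            scene.targets_robot[name] = table_to_robot(scene.targets_table[name], transform)
        except ColorNotFoundError:
            pass
    return scene
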
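"""LC boundary fitting and regional partition of the strain grid.

The lamina cribrosa opening is an ellipse fitted to manually picked
boundary points separating the LC from the bright peripapillary sclera.
The analysis partition, centered on the central retinal artery and vein
(CRAV), comprises:

* a CRAV exclusion disk (radius 200 um by default),
* a central and a peripheral band, split at the mid-radial distance
  between the CRAV circle and the LC opening along each ray, and
* four quadrants — superior (S), inferior (I), temporal (T), nasal (N) —
  bounded by the 45 and 135 degree bisectors about the CRAV center,

for eight analysis regions (central and peripheral x four quadrants).
CRAV and background are mask labels only and never enter the regional
strain summaries. Which 90-degree sector is nasal depends on eye
laterality; nasal is +X for right eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

__all__ = [
    "EllipseParams",
    "LcGeometry",
    "REGION_NAMES",
    "fit_ellipse",
    "segment_regions",
    "regional_average_magnitude",
    "mask_field_to_ellipse",
]

QUADRANTS = ("S", "I", "T", "N")
REGION_NAMES = tuple(f"{loc}_{q}" for loc in ("central", "peripheral") for q in QUADRANTS)
LABELS = {"background": 0, "CRAV": 1}
LABELS.update({name: i + 2 for i, name in enumerate(REGION_NAMES)})


@dataclass
class EllipseParams:
    """Geometric ellipse: center (um), semi-axes a >= b (um), tilt (rad)."""

    center: tuple[float, float]
    a: float
    b: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.a >= self.b > 0:
            raise ValueError("require a >= b > 0")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ct, st = np.cos(self.angle), np.sin(self.angle)
        dx, dy = np.asarray(x) - self.center[0], np.asarray(y) - self.center[1]
        xr = dx * ct + dy * st
        yr = -dx * st + dy * ct
        return (xr / self.a) ** 2 + (yr / self.b) ** 2 <= 1.0

    def ray_distance(self, origin: tuple[float, float], theta: np.ndarray) -> np.ndarray:
        """Distance from ``origin`` to the ellipse boundary along angle theta.

        origin must be inside the ellipse (exactly one positive root).
        """
        theta = np.asarray(theta, dtype=np.float64)
        ct, st = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[ct, st], [-st, ct]])
        w = R @ (np.asarray(origin) - np.asarray(self.center))
        d = np.stack([np.cos(theta), np.sin(theta)], axis=0)
        e = R @ d.reshape(2, -1)
        ex, ey = e[0], e[1]
        A = (ex / self.a) ** 2 + (ey / self.b) ** 2
        B = 2.0 * (w[0] * ex / self.a**2 + w[1] * ey / self.b**2)
        C = (w[0] / self.a) ** 2 + (w[1] / self.b) ** 2 - 1.0
        if C >= 0:
            raise ValueError("ray origin lies outside the ellipse")
        rho = (-B + np.sqrt(B**2 - 4.0 * A * C)) / (2.0 * A)
        return rho.reshape(theta.shape)


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Direct least-squares conic fit to 2D boundary points.

    Requires at least 6 non-collinear points; returns geometric
    (center, semi-axes, angle) parameters with a >= b.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise ValueError("need at least 6 (x, y) boundary points")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed (degenerate or collinear points)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        raise ValueError("conic fit did not produce an ellipse")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    if b < 1e-6 * a:
        raise ValueError("conic fit degenerate (points nearly collinear)")
    return EllipseParams(center=(xc, yc), a=a, b=b, angle=theta % np.pi)


@dataclass
class LcGeometry:
    """Fitted LC geometry plus the region label map on a 2D node grid."""

    ellipse: EllipseParams
    crav_center: tuple[float, float]
    crav_radius: float
    axes: tuple[np.ndarray, np.ndarray]  # X, Y node positions (um)
    labels: np.ndarray  # int map, see LABELS
    laterality: str = "right"

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    def label_counts(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum()) for name, code in LABELS.items()}


def segment_regions(
    ellipse: EllipseParams,
    crav_center: tuple[float, float],
    axes: tuple[np.ndarray, np.ndarray],
    crav_radius: float = 200.0,
    laterality: str = "right",
) -> LcGeometry:
    """Partition a 2D node grid into the eight analysis regions.

    Every in-ellipse node receives exactly one label; the mid-radial
    boundary between central and peripheral bands is computed per ray:
    boundary(theta) = (crav_radius + rho_ellipse(theta)) / 2 with
    rho_ellipse the ray's ellipse-intersection distance from the CRAV
    center.
    """
    if laterality not in ("right", "left"):
        raise ValueError("laterality must be 'right' or 'left'")
    theta_check = np.linspace(0, 2 * np.pi, 721)
    if ellipse.ray_distance(crav_center, theta_check).min() <= crav_radius:
        raise ValueError("CRAV disk crosses the ellipse boundary")

    x, y = axes
    X, Y = np.meshgrid(x, y, indexing="ij")
    inside = ellipse.contains(X, Y)
    dx, dy = X - crav_center[0], Y - crav_center[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    rho = ellipse.ray_distance(crav_center, theta)
    mid = (crav_radius + rho) / 2.0

    labels = np.zeros(X.shape, dtype=np.int8)
    crav = inside & (r < crav_radius)
    central = inside & ~crav & (r < mid)
    peripheral = inside & ~crav & ~central

    # quadrants about the CRAV center, bisectors at +-45 and +-135 degrees
    deg = np.degrees(theta)
    if laterality == "right":
        nasal_sector = (deg > -45) & (deg <= 45)
        temporal_sector = (deg > 135) | (deg <= -135)
    else:
        nasal_sector = (deg > 135) | (deg <= -135)
        temporal_sector = (deg > -45) & (deg <= 45)
    superior_sector = (deg > 45) & (deg <= 135)
    inferior_sector = (deg > -135) & (deg <= -45)
    sectors = {"N": nasal_sector, "S": superior_sector, "T": temporal_sector, "I": inferior_sector}

    labels[crav] = LABELS["CRAV"]
    for q, sec in sectors.items():
        labels[central & sec] = LABELS[f"central_{q}"]
        labels[peripheral & sec] = LABELS[f"peripheral_{q}"]

    return LcGeometry(
        ellipse=ellipse,
        crav_center=tuple(crav_center),
        crav_radius=crav_radius,
        axes=axes,
        labels=labels,
        laterality=laterality,
    )


def regional_average_magnitude(strain_map: np.ndarray, geom: LcGeometry) -> dict[str, float]:
    """Average absolute strain per analysis region.

    The magnitude (not the signed value) is averaged so that regions with
    balanced positive and negative strain do not appear artificially
    unstrained. NaN nodes (failed correlation columns) are excluded;
    regions with no valid nodes are omitted from the result. CRAV and
    background never contribute.
    """
    if strain_map.shape != geom.labels.shape:
        raise ValueError("strain map and label map shapes differ")
    out: dict[str, float] = {}
    for name in REGION_NAMES:
        vals = strain_map[geom.region_mask(name)]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[name] = float(np.abs(vals).mean())
    if not out:
        raise RuntimeError("no region contains valid strain nodes")
    return out


def mask_field_to_ellipse(
    fld,
    ellipse: EllipseParams,
    margin: float = 0.0,
    crav_center: tuple[float, float] | None = None,
    crav_radius: float = 0.0,
    z_margin: float = 0.0,
):
    """Restrict a displacement field's validity to the LC interior.

    Separates the LC displacement field from the peripapillary sclera
    before strain fitting: nodes whose in-plane position falls outside
    the boundary ellipse (shrunk by a boundary margin, to keep subsets
    that straddle the bright ring out of the fit) are marked invalid, as
    are nodes within the same margin of the dark CRAV disk when its
    center is given. The requested ``margin`` (um, typically half the
    finest subset extent) is capped at a quarter of the annulus width so
    that small geometries retain an analysis band. ``z_margin`` (um)
    additionally drops node planes near the axial extremes of the node
    grid, whose subsets reach into the first and last image slices where
    interpolation quality degrades; it is likewise capped at a quarter of
    the axial node range. Returns a new field; the input is unchanged.
    """
    from dataclasses import replace as _replace

    band = ellipse.b - crav_radius if crav_radius > 0 else ellipse.b
    eff = min(margin, 0.25 * max(band, 0.0))
    inner = EllipseParams(
        center=ellipse.center,
        a=max(ellipse.a - eff, 1e-6),
        b=max(ellipse.b - eff, 1e-6),
        angle=ellipse.angle,
    )
    X, Y = np.meshgrid(fld.axes[0], fld.axes[1], indexing="ij")
    inside = inner.contains(X, Y)
    if crav_center is not None and crav_radius > 0:
        inside &= np.hypot(X - crav_center[0], Y - crav_center[1]) >= crav_radius + eff
    valid = fld.valid & inside[:, :, None]
    if z_margin > 0:
        z = fld.axes[2]
        zm = min(z_margin, 0.25 * (z[-1] - z[0]))
        keep_z = (z >= z[0] + zm) & (z <= z[-1] - zm)
        valid = valid & keep_z[None, None, :]
    return _replace(fld, valid=valid, u=np.where(valid[..., None], fld.u, np.nan))
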
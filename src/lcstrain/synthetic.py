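"""Synthetic SHG-like lamina cribrosa phantoms with known deformations.

The phantom emulates the appearance of a second-harmonic-generation z-stack
of the LC: a bright, oversaturated peripapillary scleral ring, an elliptical
LC interior filled with broadband collagen-beam texture, a dark central
retinal artery/vein (CRAV) region, and dark non-correlating patches. Warping
a phantom by an analytic deformation field gives every downstream stage —
displacement correlation, strain, segmentation, statistics — a known ground
truth.

The texture is a statistical stand-in for collagen beams (thresholded
smoothed noise), not a structural model of beam morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "GroundTruthDeformation",
    "generate_phantom",
    "evaluate_deformation",
    "warp_volume",
]

SATURATION = 65535.0  # 16-bit full scale, matching the oversaturated PPS ring


@dataclass
class PhantomSpec:
    """Parameters of a synthetic LC volume.

    Lengths are micrometers. Defaults give a 256x256x64-voxel stack at
    2.5 um in-plane / 3 um axial spacing (640 x 640 x 192 um), holding a
    560 x 500 um LC ellipse with a 200 um CRAV disk.
    """

    grid_shape: tuple[int, int, int] = (256, 256, 64)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 3.0)
    ellipse_center: tuple[float, float] | None = None  # defaults to grid center
    semi_axes: tuple[float, float] = (280.0, 250.0)
    tilt: float = 0.0  # radians, major axis from +X
    crav_center: tuple[float, float] | None = None  # defaults to ellipse center
    crav_radius: float = 200.0
    beam_density: float = 0.35
    pps_ring_width: float = 30.0
    dark_patch_count: int = 3
    dark_patch_radius: tuple[float, float] = (15.0, 30.0)
    background: float = 2000.0
    beam_amplitude: float = 25000.0
    noise_sigma: float = 300.0
    texture_scale: float = 1.5  # voxels, smoothing length of the beam field
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beam_density <= 1.0:
            raise ValueError("beam_density must lie in [0, 1]")
        if min(self.semi_axes) <= self.crav_radius:
            raise ValueError("ellipse semi-axes must exceed crav_radius")
        cx, cy = self.center_xy()
        ext_x = (self.grid_shape[0] - 1) * self.voxel_size[0]
        ext_y = (self.grid_shape[1] - 1) * self.voxel_size[1]
        a = max(self.semi_axes) + self.pps_ring_width
        if cx - a < 0 or cx + a > ext_x or cy - a < 0 or cy + a > ext_y:
            raise ValueError(
                "grid too small: ellipse plus PPS ring does not fit inside "
                f"the {ext_x:.0f} x {ext_y:.0f} um field of view"
            )

    def center_xy(self) -> tuple[float, float]:
        if self.ellipse_center is not None:
            return tuple(self.ellipse_center)
        return (
            (self.grid_shape[0] - 1) * self.voxel_size[0] / 2.0,
            (self.grid_shape[1] - 1) * self.voxel_size[1] / 2.0,
        )

    def crav_xy(self) -> tuple[float, float]:
        if self.crav_center is not None:
            return tuple(self.crav_center)
        return self.center_xy()

    def grid_center_um(self) -> tuple[float, float, float]:
        return tuple((n - 1) * d / 2.0 for n, d in zip(self.grid_shape, self.voxel_size))


@dataclass
class GroundTruthDeformation:
    """Analytic displacement field u(X) evaluable at any reference point.

    Kinds
    -----
    translation
        u = ``translation`` (um), constant.
    uniform_strain
        u_i = (lambda_i - 1) * (X_i - origin_i) for stretch ratios
        ``stretch`` about ``origin``.
    polynomial
        Per component, a sum of monomial terms ``coef * dx^i dy^j dz^k``
        in coordinates relative to ``origin`` (um).
    bowing
        Posterior out-of-plane bulge: u_Z = amplitude * exp(-(r/radius)^2)
        with r the in-plane distance from ``origin``.
    """

    kind: str
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stretch: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    poly_terms: dict = field(default_factory=dict)  # {"x"|"y"|"z": [(coef,i,j,k), ...]}
    bow_amplitude: float = 0.0
    bow_radius: float = 1.0

    KINDS = ("translation", "uniform_strain", "polynomial", "bowing")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown deformation kind {self.kind!r}; expected one of {self.KINDS}")

    def scaled(self, factor: float) -> "GroundTruthDeformation":
        """Deformation with all displacement amplitudes multiplied by ``factor``."""
        return GroundTruthDeformation(
            kind=self.kind,
            translation=tuple(factor * t for t in self.translation),
            stretch=tuple(1.0 + factor * (s - 1.0) for s in self.stretch),
            origin=self.origin,
            poly_terms={
                c: [(factor * coef, i, j, k) for coef, i, j, k in terms]
                for c, terms in self.poly_terms.items()
            },
            bow_amplitude=factor * self.bow_amplitude,
            bow_radius=self.bow_radius,
        )


def evaluate_deformation(d: GroundTruthDeformation, coords: np.ndarray) -> np.ndarray:
    """Evaluate the analytic displacement (um) at reference positions.

    Parameters
    ----------
    d
        Deformation description.
    coords
        Array of shape ``(..., 3)`` of reference positions in micrometers.

    Returns
    -------
    ndarray of the same shape: displacement vectors in micrometers.
    """
    coords = np.asarray(coords, dtype=np.float64)
    u = np.zeros_like(coords)
    if d.kind == "translation":
        u[...] = np.asarray(d.translation)
    elif d.kind == "uniform_strain":
        rel = coords - np.asarray(d.origin)
        u = rel * (np.asarray(d.stretch) - 1.0)
    elif d.kind == "polynomial":
        rel = coords - np.asarray(d.origin)
        comp_index = {"x": 0, "y": 1, "z": 2}
        for comp, terms in d.poly_terms.items():
            acc = np.zeros(coords.shape[:-1])
            for coef, i, j, k in terms:
                acc = acc + coef * rel[..., 0] ** i * rel[..., 1] ** j * rel[..., 2] ** k
            u[..., comp_index[comp]] = acc
    elif d.kind == "bowing":
        rel = coords - np.asarray(d.origin)
        r2 = rel[..., 0] ** 2 + rel[..., 1] ** 2
        u[..., 2] = d.bow_amplitude * np.exp(-r2 / d.bow_radius**2)
    return u


def generate_phantom(spec: PhantomSpec) -> ImageVolume:
    """Generate an SHG-like LC phantom volume.

    Deterministic for a fixed ``spec.seed``. The PPS ring saturates at the
    16-bit maximum, the CRAV disk and dark patches sit at background level,
    and the LC interior carries spatially broadband beam texture suitable
    for subset correlation.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size

    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")

    cx, cy = spec.center_xy()
    ct, st = np.cos(spec.tilt), np.sin(spec.tilt)
    xr = (X - cx) * ct + (Y - cy) * st
    yr = -(X - cx) * st + (Y - cy) * ct
    a, b = spec.semi_axes
    in_lc = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    in_ring = ((xr / (a + spec.pps_ring_width)) ** 2 + (yr / (b + spec.pps_ring_width)) ** 2 <= 1.0) & ~in_lc

    vx, vy = spec.crav_xy()
    in_crav = (X - vx) ** 2 + (Y - vy) ** 2 < spec.crav_radius**2

    vol = np.full((nx, ny, nz), spec.background, dtype=np.float64)

    # collagen-beam texture: thresholded smoothed white noise, lightly
    # re-smoothed so the intensity field is band limited (subvoxel peaks
    # in the correlation stay well behaved)
    noise = rng.standard_normal((nx, ny, nz))
    smooth = ndimage.gaussian_filter(noise, spec.texture_scale)
    if spec.beam_density > 0.0:
        thr = np.quantile(smooth, 1.0 - spec.beam_density)
        beams = ndimage.gaussian_filter((smooth > thr).astype(np.float64), 0.7)
        lc_mask3 = (in_lc & ~in_crav)[:, :, None] & np.ones(nz, dtype=bool)
        vol += spec.beam_amplitude * beams * lc_mask3

    # dark, non-correlating patches inside the LC (emulate failed regions)
    for _ in range(spec.dark_patch_count):
        while True:
            px = rng.uniform(cx - a, cx + a)
            py = rng.uniform(cy - b, cy + b)
            if ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 <= 0.8:
                break
        pr = rng.uniform(*spec.dark_patch_radius)
        pz = rng.uniform(0, (nz - 1) * dz)
        Z = np.arange(nz) * dz
        d2 = ((X - px) ** 2 + (Y - py) ** 2)[:, :, None] + (Z - pz)[None, None, :] ** 2
        vol[d2 < pr**2] = spec.background

    vol[in_crav[:, :, None] & np.ones(nz, dtype=bool)] = spec.background
    vol[in_ring[:, :, None] & np.ones(nz, dtype=bool)] = SATURATION

    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, vol.shape)
    vol = np.clip(vol, 0.0, SATURATION)

    return ImageVolume(
        intensities=vol,
        voxel_size=spec.voxel_size,
        meta={
            "background": spec.background,
            "phantom_seed": spec.seed,
            "lc_ellipse": {
                "center_um": [cx, cy],
                "semi_axes_um": list(spec.semi_axes),
                "tilt_rad": spec.tilt,
            },
            "crav_center_um": [vx, vy],
            "crav_radius_um": spec.crav_radius,
        },
    )


def _jacobian_positive(d: GroundTruthDeformation, spec_extent: tuple[float, float, float]) -> bool:
    """Check det(I + grad u) > 0 on a coarse sample of the grid."""
    axes = [np.linspace(0, e, 7) for e in spec_extent]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    h = 1e-3
    grads = np.zeros((len(pts), 3, 3))
    for j in range(3):
        step = np.zeros(3)
        step[j] = h
        grads[:, :, j] = (evaluate_deformation(d, pts + step) - evaluate_deformation(d, pts - step)) / (2 * h)
    dets = np.linalg.det(np.eye(3) + grads)
    return bool(np.all(dets > 0))


def warp_volume(
    vol: ImageVolume,
    d: GroundTruthDeformation,
    order: int = 3,
    return_mask: bool = False,
):
    """Resample a volume under the mapping ``x = X + u(X)``.

    Backward mapping: each deformed-grid voxel x is pulled back to its
    reference position X = phi^{-1}(x) (closed form for affine kinds,
    fixed-point iteration otherwise) and the reference volume is sampled
    there with a cubic spline. Voxels pulled back from outside the
    reference grid are filled with the background intensity and flagged
    in the out-of-domain mask.
    """
    extent = vol.physical_extent()
    if not _jacobian_positive(d, extent):
        raise ValueError("deformation mapping is not invertible on the grid (Jacobian <= 0)")

    nx, ny, nz = vol.shape
    spacing = np.asarray(vol.voxel_size)
    grids = [np.arange(n) * s for n, s in zip(vol.shape, spacing)]
    x_um = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1)

    if d.kind == "translation":
        ref = x_um - np.asarray(d.translation)
    elif d.kind == "uniform_strain":
        origin = np.asarray(d.origin)
        ref = origin + (x_um - origin) / np.asarray(d.stretch)
    else:
        ref = x_um.copy()
        for _ in range(40):
            new = x_um - evaluate_deformation(d, ref)
            delta = np.max(np.abs(new - ref))
            ref = new
            if delta < 1e-4:
                break

    idx = ref / spacing  # fractional voxel indices into the reference grid
    oob = np.zeros(vol.shape, dtype=bool)
    for ax, n in enumerate(vol.shape):
        oob |= (idx[..., ax] < 0) | (idx[..., ax] > n - 1)

    background = float(vol.meta.get("background", np.percentile(vol.intensities, 1)))
    warped = ndimage.map_coordinates(
        vol.intensities,
        [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=order,
        mode="constant",
        cval=background,
    )
    warped[oob] = background

    out_vol = vol.with_intensities(warped)
    out_vol.meta = dict(vol.meta)
    out_vol.meta["warped_out_of_domain_fraction"] = float(oob.mean())
    if return_mask:
        return out_vol, oob
    return out_vol
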
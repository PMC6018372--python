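"""Fast-Fourier iterative digital volume correlation (FIDVC).

Recovers the 3D displacement field between a reference and a deformed
volume by coarse-to-fine subset correlation. Each pass warps the deformed
volume back by the current displacement estimate, correlates subsets in the
frequency domain, localizes the peak to subvoxel precision with a 3-point
Gaussian fit, and accumulates the update. Nodes whose subsets lack texture
or whose normalized correlation falls below a quality threshold are masked
invalid — mirroring dark vessel shadows and non-correlating patches in SHG
stacks of the lamina cribrosa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .volume import ImageVolume

__all__ = [
    "DvcConfig",
    "DisplacementField",
    "CorrelationFailure",
    "correlate_subset",
    "run_fidvc",
    "apply_focal_offset",
    "output_axes_um",
]


class CorrelationFailure(RuntimeError):
    """Raised when too few subsets correlate to form a usable field."""


@dataclass
class DvcConfig:
    """Settings for the iterative correlation.

    subset_schedule lists subset edge lengths in voxels per pass, coarse to
    fine, as ``(sx, sy, sz)`` tuples. Node spacing per pass is
    ``subset * (1 - overlap)``. The final field is resampled onto a regular
    output grid of ``output_spacing`` voxels — default every 4 pixels
    in-plane (10 um at 2.5 um pixels) and every 2 slices axially (6 um at
    3 um slices).
    """

    subset_schedule: tuple = ((64, 64, 32), (32, 32, 16), (16, 16, 8))
    overlap: float = 0.5
    quality_threshold: float = 0.25
    max_iterations: int = 6
    convergence_tol: float = 0.02  # voxels, mean |update|
    output_spacing: tuple[int, int, int] = (4, 4, 2)
    min_valid_fraction: float = 0.25
    field_smoothing: float = 0.8  # node units, applied to the warp estimate each pass

    def __post_init__(self) -> None:
        sched = [tuple(np.broadcast_to(s, (3,)).astype(int)) for s in self.subset_schedule]
        self.subset_schedule = tuple(sched)
        edges = [max(s) for s in sched]
        if any(e2 >= e1 for e1, e2 in zip(edges[:-1], edges[1:])):
            raise ValueError("subset_size_schedule must be strictly decreasing")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if not 0.0 < self.quality_threshold < 1.0:
            raise ValueError("quality_threshold must lie in (0, 1)")


@dataclass
class DisplacementField:
    """Gridded displacement field in the reference frame.

    ``axes`` are the node positions (um) along X, Y, Z; ``u`` has shape
    ``(nx, ny, nz, 3)`` in micrometers; ``quality`` holds the normalized
    correlation coefficient per node; invalid nodes carry NaN displacement.
    """

    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    u: np.ndarray
    quality: np.ndarray
    valid: np.ndarray
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 3.0)

    def __post_init__(self) -> None:
        if self.u.shape[:3] != self.quality.shape or self.quality.shape != self.valid.shape:
            raise ValueError("field arrays must share the node-grid shape")
        self.u = np.where(self.valid[..., None], self.u, np.nan)

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return self.quality.shape

    def coords(self) -> np.ndarray:
        """Node positions, shape ``(nx, ny, nz, 3)``, micrometers."""
        return np.stack(np.meshgrid(*self.axes, indexing="ij"), axis=-1)

    def mean_displacement(self) -> np.ndarray:
        """Mean (U_X, U_Y, U_Z) over valid nodes, micrometers."""
        return np.nanmean(self.u.reshape(-1, 3), axis=0)

    def u_voxels(self) -> np.ndarray:
        """Displacements expressed in voxel units per axis."""
        return self.u / np.asarray(self.voxel_size)

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            for name, ax in zip("xyz", self.axes):
                f.create_dataset(f"axis_{name}", data=ax)
            f.create_dataset("u", data=self.u)
            f.create_dataset("quality", data=self.quality)
            f.create_dataset("valid", data=self.valid)
            f.attrs["voxel_size_um"] = self.voxel_size

    def to_csv(self, path: str | Path) -> None:
        """Node table: position (um), displacement (um), quality, validity."""
        import pandas as pd

        coords = self.coords().reshape(-1, 3)
        u = self.u.reshape(-1, 3)
        pd.DataFrame(
            {
                "x_um": coords[:, 0],
                "y_um": coords[:, 1],
                "z_um": coords[:, 2],
                "u_x_um": u[:, 0],
                "u_y_um": u[:, 1],
                "u_z_um": u[:, 2],
                "quality": self.quality.ravel(),
                "valid": self.valid.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "DisplacementField":
        with h5py.File(path, "r") as f:
            axes = tuple(f[f"axis_{n}"][...] for n in "xyz")
            return cls(
                axes=axes,
                u=f["u"][...],
                quality=f["quality"][...],
                valid=f["valid"][...].astype(bool),
                voxel_size=tuple(f.attrs["voxel_size_um"]),
            )


def _gaussian_subpixel(cm: np.ndarray, c0: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """3-point peak interpolation along one axis.

    Gaussian fit on the log of the correlation values where all three are
    positive, parabolic fit otherwise. Returns the fractional offset from
    the integer peak, clipped to [-1, 1].
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (cm > 0) & (c0 > 0) & (cp > 0)
        lm, l0, lp = np.log(np.where(ok, cm, 1.0)), np.log(np.where(ok, c0, 1.0)), np.log(np.where(ok, cp, 1.0))
        denom_g = 2.0 * (lm + lp - 2.0 * l0)
        gauss = np.where(np.abs(denom_g) > 1e-300, (lm - lp) / denom_g, 0.0)
        denom_p = 2.0 * (cm + cp - 2.0 * c0)
        para = np.where(np.abs(denom_p) > 1e-300, (cm - cp) / denom_p, 0.0)
    out = np.where(ok, gauss, para)
    return np.clip(np.nan_to_num(out), -1.0, 1.0)


def _correlate_batch(refs: np.ndarray, defs: np.ndarray, search: tuple[int, int, int]):
    """Correlate stacks of subsets, shape ``(n, sx, sy, sz)``.

    Returns integer+subvoxel offsets (n, 3) of the deformed subset relative
    to the reference, and the normalized correlation quality (n,).
    Offsets are sought within ``+-search`` voxels of zero lag.
    """
    shape = refs.shape[1:]
    n = refs.shape[0]
    r0 = refs - refs.mean(axis=(1, 2, 3), keepdims=True)
    d0 = defs - defs.mean(axis=(1, 2, 3), keepdims=True)
    nr = np.sqrt((r0**2).sum(axis=(1, 2, 3)))
    nd = np.sqrt((d0**2).sum(axis=(1, 2, 3)))
    dead = (nr < 1e-12) | (nd < 1e-12)
    # a subset that is (near-)invariant along an axis cannot constrain the
    # displacement along it (its correlation profile is flat there, e.g.
    # the cylindrical scleral-ring region has no axial structure): require
    # resolvable intensity gradients along every axis
    var_total = np.maximum(nr**2 / r0[0].size, 1e-30)
    for ax in (1, 2, 3):
        grad_var = np.mean(np.diff(r0, axis=ax) ** 2, axis=(1, 2, 3))
        dead |= grad_var < 0.02 * var_total
    nr = np.where(dead, 1.0, nr)
    nd = np.where(dead, 1.0, nd)

    F = np.fft.rfftn(r0, axes=(1, 2, 3))
    G = np.fft.rfftn(d0, axes=(1, 2, 3))
    cc = np.fft.irfftn(np.conj(F) * G, s=shape, axes=(1, 2, 3))
    cc = np.fft.fftshift(cc, axes=(1, 2, 3))
    centers = [s // 2 for s in shape]

    sl = tuple(
        slice(c - w, c + w + 1) for c, w in zip(centers, search)
    )
    window = cc[(slice(None),) + sl]
    # break exact ties (flat correlation ridges) toward zero lag
    lags = np.meshgrid(*[np.arange(-w, w + 1) for w in search], indexing="ij")
    lag_norm = sum(np.abs(l) for l in lags)
    scale = np.abs(window).max(axis=(1, 2, 3), keepdims=True) + 1e-30
    window = window - 1e-9 * scale * lag_norm
    flat = window.reshape(n, -1)
    peak = flat.argmax(axis=1)
    pk = np.stack(np.unravel_index(peak, window.shape[1:]), axis=-1)  # within window
    pk_full = pk + np.array([c - w for c, w in zip(centers, search)])  # index in cc

    offsets = np.empty((n, 3))
    idx_n = np.arange(n)
    c0 = cc[idx_n, pk_full[:, 0], pk_full[:, 1], pk_full[:, 2]]
    # overlap taper at the peak lag, for the quality normalization
    t_peak = np.ones(n)
    for ax in range(3):
        t_peak *= 1.0 - np.abs(pk_full[:, ax] - centers[ax]) / shape[ax]
    t_peak = np.maximum(t_peak, 0.25)
    for ax in range(3):
        lo = np.clip(pk_full[:, ax] - 1, 0, shape[ax] - 1)
        hi = np.clip(pk_full[:, ax] + 1, 0, shape[ax] - 1)
        ii = [pk_full[:, 0], pk_full[:, 1], pk_full[:, 2]]
        im = list(ii)
        ip = list(ii)
        im[ax] = lo
        ip[ax] = hi
        # undo the triangular overlap taper of the circular correlation,
        # (1 - |lag|/N) per axis, on the three samples entering the peak
        # fit; left uncorrected it pulls the fit toward the integer lag
        lag0 = pk_full[:, ax] - centers[ax]
        t0 = 1.0 - np.abs(lag0) / shape[ax]
        tm = 1.0 - np.abs(lo - centers[ax]) / shape[ax]
        tp = 1.0 - np.abs(hi - centers[ax]) / shape[ax]
        cm = cc[idx_n, im[0], im[1], im[2]] / tm
        cp = cc[idx_n, ip[0], ip[1], ip[2]] / tp
        frac = _gaussian_subpixel(cm, c0 / t0, cp)
        # no subvoxel refinement when the peak sits on the search edge
        edge = (pk_full[:, ax] - 1 < 0) | (pk_full[:, ax] + 1 > shape[ax] - 1)
        offsets[:, ax] = pk_full[:, ax] - centers[ax] + np.where(edge, 0.0, frac)

    quality = np.clip(c0 / (t_peak * nr * nd), -1.0, 1.0)
    quality[dead] = 0.0
    offsets[dead] = 0.0
    return offsets, quality, dead


def _flow_step(refs: np.ndarray, defs: np.ndarray) -> np.ndarray:
    """One linearized brightness-constancy update per subset pair.

    With the deformed subset content shifted by a small +delta relative to
    the reference, ``ref - def ~= grad(def) . delta``; solving the 3x3
    normal equations gives an unbiased subvoxel estimate of delta
    (voxels). Returns zeros for subsets with a singular gradient system.
    """
    r = refs - defs
    grads = np.stack(np.gradient(defs, axis=(1, 2, 3)), axis=-1)  # (n, sx, sy, sz, 3)
    g = grads.reshape(refs.shape[0], -1, 3)
    rv = r.reshape(refs.shape[0], -1)
    M = np.einsum("nki,nkj->nij", g, g)
    b = np.einsum("nki,nk->ni", g, rv)
    trace = np.einsum("nii->n", M)
    M = M + (1e-9 * trace[:, None, None] + 1e-30) * np.eye(3)
    try:
        delta = np.linalg.solve(M, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        delta = np.zeros((refs.shape[0], 3))
    return np.nan_to_num(delta)


def correlate_subset(ref_subset: np.ndarray, def_subset: np.ndarray):
    """Correlate a single subset pair.

    Returns ``(offset, quality)`` where offset (voxels) locates the
    deformed subset relative to the reference via the frequency-domain
    normalized cross-correlation peak with subvoxel Gaussian refinement.
    A zero-variance reference subset yields quality 0 (flagged, not an
    exception).
    """
    ref_subset = np.asarray(ref_subset, dtype=np.float64)
    def_subset = np.asarray(def_subset, dtype=np.float64)
    if ref_subset.shape != def_subset.shape:
        raise ValueError("subsets must share a shape")
    search = tuple(max(1, s // 4) for s in ref_subset.shape)
    off, q, dead = _correlate_batch(ref_subset[None], def_subset[None], search)
    return off[0], float(q[0])


def _node_grid(shape, subset, spacing):
    """Node center indices per axis for a given subset size and spacing."""
    axes = []
    for n, s, sp in zip(shape, subset, spacing):
        half = s // 2
        last = n - (s - half)
        if last < half:
            raise ValueError("volume smaller than one subset along an axis")
        axes.append(np.arange(half, last + 1, sp))
    return axes


def _extract_subsets(volume: np.ndarray, centers: np.ndarray, subset) -> np.ndarray:
    half = [s // 2 for s in subset]
    out = np.empty((len(centers),) + tuple(subset))
    for i, c in enumerate(centers):
        sl = tuple(slice(int(ci) - h, int(ci) - h + s) for ci, h, s in zip(c, half, subset))
        out[i] = volume[sl]
    return out


def output_axes_um(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    cfg: DvcConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Node positions (um) of the displacement field run_fidvc will output.

    Useful for building region label maps on the correlation grid before
    any correlation has run.
    """
    cfg = cfg or DvcConfig()
    subset = cfg.subset_schedule[min(cfg.max_iterations, len(cfg.subset_schedule)) - 1]
    spacing = [max(1, int(round(s * (1.0 - cfg.overlap)))) for s in subset]
    node_axes = _node_grid(shape, subset, spacing)
    return tuple(
        np.arange(ax[0], ax[-1] + 1e-9, sp) * v
        for ax, sp, v in zip(node_axes, cfg.output_spacing, voxel_size)
    )


def run_fidvc(ref: ImageVolume, deformed: ImageVolume, cfg: DvcConfig | None = None) -> DisplacementField:
    """Run the coarse-to-fine iterative DVC between two volumes.

    Each pass warps the deformed volume by the current displacement
    estimate, correlates subsets against the reference, and adds the
    residual offsets. The recorded focal-offset difference
    (deformed minus reference) is added to the anterior-posterior
    component of the output, restoring the absolute Z motion when the
    microscope was refocused between acquisitions.

    Raises
    ------
    CorrelationFailure
        If fewer than ``cfg.min_valid_fraction`` of output nodes are valid.
    """
    cfg = cfg or DvcConfig()
    if ref.shape != deformed.shape:
        raise ValueError("reference and deformed volumes must share a shape")
    if tuple(ref.voxel_size) != tuple(deformed.voxel_size):
        raise ValueError("reference and deformed volumes must share voxel spacing")

    f = np.asarray(ref.intensities, dtype=np.float64)
    g = np.asarray(deformed.intensities, dtype=np.float64)
    shape = f.shape

    # current displacement estimate, voxels, sampled on the previous node grid
    est_axes: list[np.ndarray] | None = None
    est_u: np.ndarray | None = None  # (nx, ny, nz, 3)
    node_axes: list[np.ndarray] = []
    node_u = node_quality = node_dead = None

    schedule = list(cfg.subset_schedule)
    n_pass = 0
    while n_pass < cfg.max_iterations:
        subset = schedule[min(n_pass, len(schedule) - 1)]
        if n_pass >= len(schedule) and node_u is None:
            break
        spacing = [max(1, int(round(s * (1.0 - cfg.overlap)))) for s in subset]
        node_axes = _node_grid(shape, subset, spacing)
        centers = np.stack(np.meshgrid(*node_axes, indexing="ij"), axis=-1)
        grid_shape = centers.shape[:3]
        centers_flat = centers.reshape(-1, 3)

        # displacement estimate at the new nodes (voxels)
        if est_u is None:
            u_here = np.zeros((len(centers_flat), 3))
        else:
            interp = RegularGridInterpolator(est_axes, est_u, bounds_error=False, fill_value=None)
            u_here = interp(centers_flat)

        g_warp = _warp_by_field(g, est_axes, est_u, shape) if est_u is not None else g

        search = tuple(max(1, s // 4) for s in subset)
        offsets = np.empty((len(centers_flat), 3))
        quality = np.empty(len(centers_flat))
        dead = np.empty(len(centers_flat), dtype=bool)
        chunk = max(1, int(2**24 // np.prod(subset)))
        for i0 in range(0, len(centers_flat), chunk):
            cs = centers_flat[i0 : i0 + chunk]
            refs = _extract_subsets(f, cs, subset)
            defs = _extract_subsets(g_warp, cs, subset)
            off, q, dd = _correlate_batch(refs, defs, search)
            offsets[i0 : i0 + chunk] = off
            quality[i0 : i0 + chunk] = q
            dead[i0 : i0 + chunk] = dd

        u_new = u_here + offsets
        update_mag = float(np.mean(np.abs(offsets[quality >= cfg.quality_threshold])) if np.any(quality >= cfg.quality_threshold) else np.mean(np.abs(offsets)))

        node_u = u_new.reshape(grid_shape + (3,))
        node_quality = quality.reshape(grid_shape)
        node_dead = dead.reshape(grid_shape)

        # local median consistency test: low-texture subsets straddling
        # high-contrast axial structures (vessel shadow wall, scleral-ring
        # edge) can lock confidently onto a wrong offset; a vector that
        # disagrees with its 3x3x3 neighborhood median by more than the
        # local deformation scale is treated as a failed correlation
        unreliable = node_dead | (node_quality < cfg.quality_threshold)
        u_for_med = node_u
        if unreliable.any() and (~unreliable).any():
            ind = ndimage.distance_transform_edt(unreliable, return_distances=False, return_indices=True)
            u_for_med = node_u[tuple(ind)]
        med = np.stack(
            [ndimage.median_filter(u_for_med[..., c], size=3, mode="nearest") for c in range(3)],
            axis=-1,
        )
        resid = np.abs(node_u - med)
        node_outlier = (resid > 1.0 + 0.1 * np.abs(med)).any(axis=-1) & ~unreliable
        node_u = np.where(node_outlier[..., None], med, node_u)
        node_textureless = node_dead.copy()
        node_dead = node_dead | node_outlier

        # field used for warping the next pass: nodes that failed to
        # correlate (dark regions, ring, outliers) take the value of the
        # nearest well-correlated node so the warp stays plausible there
        est_axes = [ax.astype(np.float64) for ax in node_axes]
        est_u = node_u.copy()
        bad = (node_quality < cfg.quality_threshold) | node_dead
        if bad.any() and (~bad).any():
            ind = ndimage.distance_transform_edt(bad, return_distances=False, return_indices=True)
            est_u = est_u[tuple(ind)]
        # regularize the estimate before it warps the next pass: node-level
        # correlation noise otherwise feeds back as spurious local strain
        # and accumulates over iterations
        for c in range(3):
            est_u[..., c] = ndimage.gaussian_filter(est_u[..., c], cfg.field_smoothing, mode="nearest")
        n_pass += 1
        if n_pass >= len(schedule) and update_mag < cfg.convergence_tol:
            break

    # differential subvoxel refinement: correlation peak fitting carries a
    # small systematic pull toward integer lags (peak locking); one
    # linearized brightness-constancy step on the residual removes it
    g_final = _warp_by_field(g, est_axes, est_u, shape)
    centers_flat = np.stack(np.meshgrid(*node_axes, indexing="ij"), axis=-1).reshape(-1, 3)
    subset = cfg.subset_schedule[min(n_pass - 1, len(cfg.subset_schedule) - 1)]
    delta = np.zeros((len(centers_flat), 3))
    chunk = max(1, int(2**24 // np.prod(subset)))
    for i0 in range(0, len(centers_flat), chunk):
        cs = centers_flat[i0 : i0 + chunk]
        fs = _extract_subsets(f, cs, subset)
        gs = _extract_subsets(g_final, cs, subset)
        delta[i0 : i0 + chunk] = _flow_step(fs, gs)
    node_u = node_u + np.clip(delta, -1.0, 1.0).reshape(node_u.shape)

    # resample onto the output grid; displacements are interpolated from
    # the filled field (bad nodes replaced by nearest good) and any output
    # node whose linear stencil touches a failed node is marked invalid —
    # interpolating across failures would blend garbage into the field
    out_axes_vox = [
        np.arange(ax[0], ax[-1] + 1e-9, sp)
        for ax, sp in zip(node_axes, cfg.output_spacing)
    ]
    out_grid = np.stack(np.meshgrid(*out_axes_vox, indexing="ij"), axis=-1)
    bad_final = (node_quality < cfg.quality_threshold) | node_dead
    node_u_filled = node_u
    if bad_final.any() and (~bad_final).any():
        ind = ndimage.distance_transform_edt(bad_final, return_distances=False, return_indices=True)
        node_u_filled = node_u[tuple(ind)]
    interp_u = RegularGridInterpolator(est_axes, node_u_filled, bounds_error=False, fill_value=None)
    interp_q = RegularGridInterpolator(est_axes, node_quality, bounds_error=False, fill_value=None)
    interp_bad = RegularGridInterpolator(
        est_axes, bad_final.astype(np.float64), bounds_error=False, fill_value=1.0
    )
    u_out = interp_u(out_grid.reshape(-1, 3)).reshape(out_grid.shape[:3] + (3,))
    q_out = interp_q(out_grid.reshape(-1, 3)).reshape(out_grid.shape[:3])
    bad_out = interp_bad(out_grid.reshape(-1, 3)).reshape(out_grid.shape[:3]) > 0.05
    valid = (q_out >= cfg.quality_threshold) & ~bad_out

    # failure is judged against nodes that had correlatable texture at
    # all: structurally blank regions (vessel shadow, saturated ring,
    # empty background) are excluded like dark regions in real acquisitions;
    # they are not counted as correlation failures
    interp_tex = RegularGridInterpolator(
        est_axes, node_textureless.astype(np.float64), bounds_error=False, fill_value=1.0
    )
    textureless_out = interp_tex(out_grid.reshape(-1, 3)).reshape(out_grid.shape[:3]) > 0.95
    n_correlatable = max(1, int((~textureless_out).sum()))
    if valid.sum() / n_correlatable < cfg.min_valid_fraction:
        raise CorrelationFailure(
            f"correlation failure: only {valid.sum() / n_correlatable:.1%} of "
            f"correlatable nodes valid (threshold {cfg.min_valid_fraction:.0%})"
        )

    vs = np.asarray(ref.voxel_size)
    u_um = u_out * vs  # per-axis voxels -> um
    dfocal = deformed.focal_offset - ref.focal_offset
    u_um[..., 2] += dfocal
    axes_um = tuple(ax * s for ax, s in zip(out_axes_vox, vs))
    return DisplacementField(
        axes=axes_um,
        u=u_um,
        quality=q_out,
        valid=valid,
        voxel_size=tuple(ref.voxel_size),
    )


def _warp_by_field(g: np.ndarray, axes, u_nodes: np.ndarray, shape) -> np.ndarray:
    """Sample the deformed volume at x + u_est(x) over the full grid."""
    interp = RegularGridInterpolator(axes, u_nodes, bounds_error=False, fill_value=None)
    grids = [np.arange(n, dtype=np.float64) for n in shape]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1)
    u_full = interp(pts.reshape(-1, 3)).reshape(shape + (3,))
    coords = pts + u_full
    return ndimage.map_coordinates(
        g, [coords[..., 0], coords[..., 1], coords[..., 2]], order=3, mode="nearest"
    )


def apply_focal_offset(fld: DisplacementField, dfocal: float) -> DisplacementField:
    """Add a recorded focal-depth adjustment (um) to U_Z uniformly."""
    u = fld.u.copy()
    u[..., 2] = u[..., 2] + dfocal
    return replace(fld, u=u)
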
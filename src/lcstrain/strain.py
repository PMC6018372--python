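"""Green-Lagrange strain fields from gridded displacement data.

The displacement field from volume correlation is smoothed by fitting one
trivariate polynomial of total degree 6 per displacement component (84
coefficients each) over the valid nodes, on a domain normalized to
[-1, 1]^3. The displacement gradient is then evaluated analytically and
the finite-deformation Green-Lagrange tensor formed:

    E = 1/2 (H + H^T + H^T H),    H = grad u,

which is objective under rigid rotation and retains the quadratic term
that the infinitesimal strain drops. In-plane principal and maximum-shear
measures follow the 2D Mohr construction:

    E_max   = (E_XX + E_YY)/2 + sqrt(((E_XX - E_YY)/2)^2 + E_XY^2)
    Gamma_max = sqrt(((E_XX - E_YY)/2)^2 + E_XY^2)

Gamma_max is the tensorial maximum shear (Mohr radius), not the
engineering shear (twice the tensorial value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvc import DisplacementField

__all__ = [
    "PolynomialFit",
    "StrainField",
    "PlanarStrainMaps",
    "fit_polynomial_field",
    "displacement_gradient",
    "green_lagrange",
    "principal_and_shear",
    "compute_strain_field",
    "average_through_z",
]


def _exponents(degree: int) -> np.ndarray:
    """All (i, j, k) with i + j + k <= degree."""
    exps = [
        (i, j, k)
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
        for k in range(degree + 1 - i - j)
    ]
    return np.array(exps, dtype=int)


@dataclass
class PolynomialFit:
    """Trivariate polynomial smoothing of a displacement field.

    Coefficients live on the normalized cube: physical coordinates are
    mapped by ``t = 2 (x - lo) / (hi - lo) - 1`` per axis before the
    monomials are evaluated. One coefficient vector per displacement
    component; residual RMS per component in micrometers.
    """

    degree: int
    exponents: np.ndarray  # (n_terms, 3)
    coeffs: np.ndarray  # (3, n_terms)
    lo: np.ndarray  # (3,)
    hi: np.ndarray  # (3,)
    residual_rms: np.ndarray  # (3,)

    def normalize(self, coords: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        return 2.0 * (coords - self.lo) / span - 1.0

    def in_domain(self, coords: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        """True where coords lie inside the fitted bounding box."""
        t = self.normalize(np.asarray(coords, dtype=np.float64))
        return np.all(np.abs(t) <= 1.0 + rtol, axis=-1)

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        """Evaluate the fitted displacement (um) at physical coords (..., 3)."""
        t = self.normalize(np.asarray(coords, dtype=np.float64))
        V = _design_matrix(t.reshape(-1, 3), self.exponents)
        vals = V @ self.coeffs.T
        return vals.reshape(coords.shape[:-1] + (3,))


def _design_matrix(t: np.ndarray, exps: np.ndarray) -> np.ndarray:
    """Monomial design matrix on normalized coordinates, (n_pts, n_terms)."""
    deg = int(exps.max())
    powers = [np.ones((t.shape[0], deg + 1)) for _ in range(3)]
    for ax in range(3):
        for p in range(1, deg + 1):
            powers[ax][:, p] = powers[ax][:, p - 1] * t[:, ax]
    return powers[0][:, exps[:, 0]] * powers[1][:, exps[:, 1]] * powers[2][:, exps[:, 2]]


def fit_polynomial_field(fld: DisplacementField, degree: int = 6) -> PolynomialFit:
    """Least-squares polynomial fit to each displacement component.

    Only valid nodes enter the fit. Raises if the valid nodes do not span
    all three axes or are too few for the coefficient count.
    """
    coords = fld.coords().reshape(-1, 3)
    u = fld.u.reshape(-1, 3)
    keep = fld.valid.reshape(-1) & np.all(np.isfinite(u), axis=-1)
    coords, u = coords[keep], u[keep]

    exps = _exponents(degree)
    if coords.shape[0] < exps.shape[0]:
        raise ValueError(
            f"{coords.shape[0]} valid nodes cannot determine {exps.shape[0]} coefficients"
        )
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    for ax, name in enumerate("XYZ"):
        if hi[ax] - lo[ax] <= 0:
            raise ValueError(f"valid nodes are degenerate along the {name} axis")

    fit = PolynomialFit(
        degree=degree,
        exponents=exps,
        coeffs=np.zeros((3, exps.shape[0])),
        lo=lo,
        hi=hi,
        residual_rms=np.zeros(3),
    )
    V = _design_matrix(fit.normalize(coords), exps)
    sol, *_ = np.linalg.lstsq(V, u, rcond=None)
    fit.coeffs = sol.T
    resid = V @ sol - u
    fit.residual_rms = np.sqrt(np.mean(resid**2, axis=0))
    return fit


def displacement_gradient(fit: PolynomialFit, coords: np.ndarray) -> np.ndarray:
    """Analytic displacement gradient H[i, j] = dU_i/dX_j at physical coords.

    Differentiates the polynomial on the normalized cube and chain-rules
    through the affine domain map. Shape ``coords.shape[:-1] + (3, 3)``.
    Use :meth:`PolynomialFit.in_domain` to flag extrapolated points.
    """
    coords = np.asarray(coords, dtype=np.float64)
    t = fit.normalize(coords).reshape(-1, 3)
    scale = 2.0 / (fit.hi - fit.lo)  # dt/dx per axis
    exps = fit.exponents
    H = np.zeros((t.shape[0], 3, 3))
    for j in range(3):
        dexp = exps.copy()
        fac = exps[:, j].astype(np.float64)
        dexp[:, j] = np.maximum(exps[:, j] - 1, 0)
        Vd = _design_matrix(t, dexp) * fac
        H[:, :, j] = (Vd @ fit.coeffs.T) * scale[j]
    return H.reshape(coords.shape[:-1] + (3, 3))


def green_lagrange(grad_u: np.ndarray) -> np.ndarray:
    """Green-Lagrange tensor E = 1/2 (H + H^T + H^T H) for H = grad u."""
    H = np.asarray(grad_u, dtype=np.float64)
    Ht = np.swapaxes(H, -1, -2)
    return 0.5 * (H + Ht + Ht @ H)


def principal_and_shear(e_xx, e_yy, e_xy):
    """In-plane maximum principal strain and maximum (tensorial) shear.

    Works elementwise on arrays or scalars; returns ``(E_max, Gamma_max)``.
    """
    e_xx = np.asarray(e_xx, dtype=np.float64)
    e_yy = np.asarray(e_yy, dtype=np.float64)
    e_xy = np.asarray(e_xy, dtype=np.float64)
    radius = np.sqrt(((e_xx - e_yy) / 2.0) ** 2 + e_xy**2)
    return (e_xx + e_yy) / 2.0 + radius, radius


@dataclass
class StrainField:
    """Full strain tensor on the displacement node grid.

    ``tensor`` has shape ``(nx, ny, nz, 3, 3)``; invalid nodes are NaN.
    """

    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    tensor: np.ndarray
    valid: np.ndarray

    @property
    def e_xx(self) -> np.ndarray:
        return self.tensor[..., 0, 0]

    @property
    def e_yy(self) -> np.ndarray:
        return self.tensor[..., 1, 1]

    @property
    def e_xy(self) -> np.ndarray:
        return self.tensor[..., 0, 1]

    def e_max(self) -> np.ndarray:
        return principal_and_shear(self.e_xx, self.e_yy, self.e_xy)[0]

    def gamma_max(self) -> np.ndarray:
        return principal_and_shear(self.e_xx, self.e_yy, self.e_xy)[1]

    def component_maps(self) -> dict[str, np.ndarray]:
        """The five analyzed in-plane strain fields, keyed by name."""
        return {
            "E_XX": self.e_xx,
            "E_YY": self.e_yy,
            "E_XY": self.e_xy,
            "E_max": self.e_max(),
            "Gamma_max": self.gamma_max(),
        }

    def to_hdf5(self, path) -> None:
        """Full tensor, derived in-plane fields and validity mask."""
        import h5py

        with h5py.File(path, "w") as f:
            for name, ax in zip("xyz", self.axes):
                f.create_dataset(f"axis_{name}", data=ax)
            f.create_dataset("tensor", data=self.tensor)
            f.create_dataset("valid", data=self.valid)
            derived = f.create_group("derived")
            for name, vol in self.component_maps().items():
                derived.create_dataset(name, data=vol)


@dataclass
class PlanarStrainMaps:
    """Z-averaged 2D strain maps on the in-plane node grid."""

    axes: tuple[np.ndarray, np.ndarray]  # X, Y node positions (um)
    maps: dict[str, np.ndarray] = field(default_factory=dict)
    valid: np.ndarray | None = None  # columns with >= 1 valid Z node

    def to_csv(self, path) -> None:
        import pandas as pd

        X, Y = np.meshgrid(*self.axes, indexing="ij")
        frame = {"x_um": X.ravel(), "y_um": Y.ravel()}
        frame.update({name: m.ravel() for name, m in self.maps.items()})
        pd.DataFrame(frame).to_csv(path, index=False)


def compute_strain_field(fit: PolynomialFit, fld: DisplacementField) -> StrainField:
    """Evaluate strains on the displacement node grid (valid nodes only)."""
    coords = fld.coords()
    H = displacement_gradient(fit, coords)
    E = green_lagrange(H)
    E = np.where(fld.valid[..., None, None], E, np.nan)
    return StrainField(axes=fld.axes, tensor=E, valid=fld.valid.copy())


def average_through_z(strain: StrainField) -> PlanarStrainMaps:
    """Signed mean over valid Z nodes at each (X, Y) column.

    E_max and Gamma_max are averaged as fields (per-node values averaged
    through Z), not recomputed from the averaged components. Columns with
    no valid node are flagged invalid and excluded downstream.
    """
    valid2d = strain.valid.any(axis=2)
    nvalid = strain.valid.sum(axis=2)
    out = PlanarStrainMaps(axes=(strain.axes[0], strain.axes[1]), valid=valid2d)
    for name, vol in strain.component_maps().items():
        col = np.where(strain.valid, vol, 0.0)
        mean = np.full(valid2d.shape, np.nan)
        mean[valid2d] = col.sum(axis=2)[valid2d] / nvalid[valid2d]
        out.maps[name] = mean
    return out
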
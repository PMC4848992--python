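"""CoMFA-style 3D-QSAR: lattice fields, column filtering and NIPALS PLS.

Aligned conformers are surrounded by a rectangular lattice extending a
margin (default 4 A) beyond every atom.  At each lattice point the
interaction energy with an sp3-carbon probe (vdW radius 1.52 A, charge +1)
is evaluated:

* steric: Lennard-Jones 6-12, E = sum_i eps_i [ (rmin_i/r)^12 - 2 (rmin_i/r)^6 ],
  with rmin_i = R_i + R_probe and eps_i = sqrt(eps_atom * eps_probe)
  (Lorentz-Berthelot-style combination); truncated at +cutoff (30 kcal/mol).
* electrostatic: Coulomb with distance-dependent dielectric eps(r) = r,
  E = sum_i 332.0636 q_i q_probe / r^2, truncated to [-cutoff, +cutoff];
  points buried inside the molecule's vdW envelope take the column mean of
  the unburied values (two-pass fill).

Columns whose across-molecule standard deviation falls below a minimum
sigma (default 6 kcal/mol) are dropped before PLS.  The PLS engine is a
NIPALS PLS1 implementation on mean-centred, optionally block-scaled data;
the component count is chosen by the highest leave-one-out Q^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chemio import AlignedConformer
from .validation import r_squared

__all__ = [
    "Lattice",
    "FieldBlock",
    "PLSFieldModel",
    "ContourGrid",
    "LJ_PARAMS",
    "PROBE_RADIUS",
    "PROBE_EPSILON",
    "COULOMB_CONSTANT",
    "build_lattice",
    "steric_field",
    "electrostatic_field",
    "compute_field_block",
    "column_filter",
    "nipals_pls",
    "fit_pls",
    "select_components",
    "contour_grid",
    "write_opendx",
]

#: Per-element Lennard-Jones well depths (kcal/mol); radii come from the
#: Bondi set carried on the conformer.  Values follow a standard
#: small-molecule force-field parameterisation.
LJ_PARAMS: dict[str, float] = {
    "H": 0.022, "C": 0.107, "N": 0.095, "O": 0.116, "F": 0.109,
    "P": 0.314, "S": 0.314, "Cl": 0.240, "Br": 0.320, "I": 0.424,
}
_DEFAULT_EPS = 0.107
PROBE_RADIUS = 1.52     # sp3 carbon probe, Angstrom
PROBE_EPSILON = 0.107   # kcal/mol
PROBE_CHARGE = 1.0
COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class Lattice:
    """Axis-aligned grid: point(ix,iy,iz) = origin + spacing*(ix,iy,iz)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, C-ordered (ix slowest, iz fastest), shape (P, 3)."""
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])
        return np.asarray(self.origin) + self.spacing * idx


def build_lattice(conformers, spacing: float = 2.0, margin: float = 4.0) -> Lattice:
    """Minimal lattice containing every atom with >= ``margin`` on all faces."""
    conformers = list(conformers)
    if not conformers:
        raise ValueError("need at least one conformer")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.vstack([c.xyz for c in conformers])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return Lattice(tuple(float(v) for v in lo), float(spacing), dims)


def _grid_points(lattice_or_points) -> np.ndarray:
    if isinstance(lattice_or_points, Lattice):
        return lattice_or_points.points()
    return np.asarray(lattice_or_points, dtype=float)


def steric_field(
    conf: AlignedConformer,
    lattice,
    probe_radius: float = PROBE_RADIUS,
    cutoff: float = 30.0,
) -> np.ndarray:
    """Lennard-Jones 6-12 probe energies (kcal/mol) at each lattice point."""
    if len(conf) == 0:
        raise ValueError("empty conformer")
    pts = _grid_points(lattice)
    rmin = conf.radii + probe_radius
    eps = np.sqrt(
        np.array([LJ_PARAMS.get(e, _DEFAULT_EPS) for e in conf.elements]) * PROBE_EPSILON
    )
    d = np.linalg.norm(pts[:, None, :] - conf.xyz[None, :, :], axis=-1)
    out = np.empty(len(pts))
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio = rmin[None, :] / d
        e = eps[None, :] * (ratio**12 - 2.0 * ratio**6)
        e = np.where(d == 0.0, np.inf, e)
        out = e.sum(axis=1)
    return np.minimum(np.nan_to_num(out, nan=np.inf, posinf=np.inf), cutoff)


def electrostatic_field(
    conf: AlignedConformer,
    lattice,
    probe_charge: float = PROBE_CHARGE,
    cutoff: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Coulomb probe energies with eps(r) = r, plus a buried-point mask.

    Returns ``(energies, buried)``: buried marks points inside any atom's
    vdW sphere, whose value should be replaced by the across-molecule column
    mean of unburied values (done by :func:`compute_field_block`).
    """
    pts = _grid_points(lattice)
    d = np.linalg.norm(pts[:, None, :] - conf.xyz[None, :, :], axis=-1)
    buried = (d < conf.radii[None, :]).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = COULOMB_CONSTANT * probe_charge * conf.charges[None, :] / d**2
        e = np.where(d == 0.0, 0.0, e)
    out = np.clip(e.sum(axis=1), -cutoff, cutoff)
    return out, buried


@dataclass(frozen=True)
class FieldBlock:
    """n_molecules x (2 * n_points) field matrix: steric block, then electrostatic."""

    matrix: np.ndarray
    lattice: Lattice
    retained_columns: np.ndarray  # indices into the full 2P columns

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1] // 2

    def field_of_column(self, j: int) -> str:
        return "steric" if j < self.n_points else "electrostatic"

    def point_of_column(self, j: int) -> int:
        return j if j < self.n_points else j - self.n_points

    @property
    def retained_matrix(self) -> np.ndarray:
        return self.matrix[:, self.retained_columns]


def compute_field_block(conformers, lattice: Lattice, cutoff: float = 30.0) -> FieldBlock:
    """Assemble the steric+electrostatic field matrix for aligned conformers."""
    conformers = list(conformers)
    if len(conformers) < 1:
        raise ValueError("need at least one conformer")
    ster, elec, buried = [], [], []
    for c in conformers:
        ster.append(steric_field(c, lattice, cutoff=cutoff))
        e, b = electrostatic_field(c, lattice, cutoff=cutoff)
        elec.append(e)
        buried.append(b)
    S = np.vstack(ster)
    E = np.vstack(elec)
    B = np.vstack(buried)
    # two-pass fill: buried entries take the column mean of unburied values
    with np.errstate(invalid="ignore"):
        col_sum = np.where(B, 0.0, E).sum(axis=0)
        col_n = (~B).sum(axis=0)
        col_mean = np.where(col_n > 0, col_sum / np.maximum(col_n, 1), 0.0)
    E = np.where(B, col_mean[None, :], E)
    M = np.hstack([S, E])
    return FieldBlock(M, lattice, np.arange(M.shape[1]))


def column_filter(block: FieldBlock, sigma_min: float = 6.0) -> FieldBlock:
    """Keep columns whose across-molecule standard deviation >= sigma_min."""
    if block.matrix.shape[0] < 2:
        raise ValueError("need at least two molecules to filter on variance")
    sd = block.matrix[:, block.retained_columns].std(axis=0)
    keep = block.retained_columns[sd >= sigma_min]
    if keep.size == 0:
        raise ValueError(
            f"all columns filtered at sigma_min={sigma_min}; lower the threshold"
        )
    return replace(block, retained_columns=keep)


# ---------------------------------------------------------------------------
# NIPALS PLS1

def nipals_pls(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1 on already centred data.

    Returns ``(B, W, P, Q, T)`` with regression vector B such that
    yhat = X @ B for centred X, y.
    """
    Xr = X.copy()
    yr = y.astype(float).copy()
    n, p = Xr.shape
    W = np.zeros((p, n_components))
    Pl = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual exhausted: truncate
            W, Pl, Q, T = W[:, :a], Pl[:, :a], Q[:a], T[:, :a]
            break
        w /= norm
        t = Xr @ w
        tt = t @ t
        if tt < 1e-14:
            W, Pl, Q, T = W[:, :a], Pl[:, :a], Q[:a], T[:, :a]
            break
        pl = Xr.T @ t / tt
        q = yr @ t / tt
        Xr -= np.outer(t, pl)
        yr -= q * t
        W[:, a], Pl[:, a], Q[a], T[:, a] = w, pl, q, t
    if W.shape[1] == 0:
        return np.zeros(p), W, Pl, Q, T
    B = W @ np.linalg.solve(Pl.T @ W, Q)
    return B, W, Pl, Q, T


@dataclass(frozen=True)
class PLSFieldModel:
    """A fitted field-PLS model in original (unscaled) column units."""

    n_components: int
    coefficients: np.ndarray         # per retained column
    intercept: float
    retained_columns: np.ndarray
    r2: float
    contributions: tuple[float, float]   # (steric, electrostatic), sum to 1
    q2_loo: float | None = None
    column_sd: np.ndarray | None = None

    def predict(self, block: FieldBlock) -> np.ndarray:
        if not np.array_equal(block.retained_columns, self.retained_columns):
            raise ValueError("block retained columns differ from the model's")
        return self.intercept + block.retained_matrix @ self.coefficients


def _block_weights(Xc: np.ndarray, cols: np.ndarray, n_points: int, scaling: str):
    w = np.ones(Xc.shape[1])
    if scaling == "none":
        return w
    if scaling not in ("block", "auto"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if scaling == "auto":
        sd = Xc.std(axis=0)
        return np.where(sd > 1e-12, 1.0 / np.where(sd > 1e-12, sd, 1.0), 1.0)
    steric = cols < n_points
    for mask in (steric, ~steric):
        if mask.any():
            s = Xc[:, mask].std()
            if s > 1e-12:
                w[mask] = 1.0 / s
    return w


def fit_pls(
    block: FieldBlock, y, n_components: int, scaling: str = "block"
) -> PLSFieldModel:
    """NIPALS PLS of activity on the retained field columns.

    Data are mean-centred; with ``scaling='block'`` each field block is
    weighted by the inverse of its overall standard deviation so neither
    field dominates.  Coefficients are returned in original column units.
    Field contributions are the normalized |coefficient * column sd| mass
    per block.
    """
    X = block.retained_matrix
    ya = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if ya.std() == 0:
        raise ValueError("zero-variance response")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    xbar = X.mean(axis=0)
    ybar = ya.mean()
    Xc = X - xbar
    w = _block_weights(Xc, block.retained_columns, block.n_points, scaling)
    B_scaled, *_ = nipals_pls(Xc * w, ya - ybar, n_components)
    B = B_scaled * w
    intercept = ybar - xbar @ B
    yhat = intercept + X @ B
    sd = X.std(axis=0)
    mass = np.abs(B) * sd
    steric = block.retained_columns < block.n_points
    tot = mass.sum()
    if tot <= 0:
        contrib = (0.5, 0.5)
    else:
        contrib = (float(mass[steric].sum() / tot), float(mass[~steric].sum() / tot))
    return PLSFieldModel(
        n_components=n_components,
        coefficients=B,
        intercept=float(intercept),
        retained_columns=block.retained_columns.copy(),
        r2=r_squared(ya, yhat) if np.std(yhat) > 0 else 0.0,
        contributions=contrib,
        column_sd=sd,
    )


def _loo_q2(block: FieldBlock, y: np.ndarray, n_components: int, scaling: str) -> float:
    X = block.retained_matrix
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        sub = FieldBlock(block.matrix[keep], block.lattice, block.retained_columns)
        m = fit_pls(sub, y[keep], min(n_components, n - 2), scaling)
        pred = m.intercept + X[i] @ m.coefficients
        press += (y[i] - pred) ** 2
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - press / sst


def select_components(
    block: FieldBlock, y, max_components: int = 10, scaling: str = "block"
) -> tuple[int, float]:
    """Pick the component count with the highest leave-one-out Q^2.

    Column filtering is fixed upfront (not recomputed per fold).  Ties break
    toward the smaller component count.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    ya = np.asarray(y, dtype=float).ravel()
    n, p = block.retained_matrix.shape
    upper = min(max_components, n - 2, p)
    best_a, best_q2 = 1, -np.inf
    for a in range(1, upper + 1):
        q2 = _loo_q2(block, ya, a, scaling)
        if q2 > best_q2 + 1e-12:
            best_a, best_q2 = a, q2
    return best_a, float(best_q2)


@dataclass(frozen=True)
class ContourGrid:
    """STDEV*COEFF grids per field with percentile iso-levels."""

    lattice: Lattice
    steric: np.ndarray          # (P,) stdev*coeff, zeros where filtered
    electrostatic: np.ndarray
    favored_level: float
    disfavored_level: float
    steric_thresholds: tuple[float, float]       # (disfavored, favored)
    electrostatic_thresholds: tuple[float, float]


def contour_grid(
    model: PLSFieldModel,
    block: FieldBlock,
    favored_level: float = 80.0,
    disfavored_level: float = 20.0,
) -> ContourGrid:
    """Per-point STDEV*COEFF values and favored/disfavored iso-levels.

    The favored threshold is the ``favored_level`` percentile of the
    positive values of a field; the disfavored threshold is the
    ``disfavored_level`` percentile of its negative values.
    """
    if not 0 < disfavored_level < favored_level < 100:
        raise ValueError("need 0 < disfavored_level < favored_level < 100")
    P = block.n_points
    full = np.zeros(2 * P)
    sd = model.column_sd if model.column_sd is not None else block.retained_matrix.std(axis=0)
    full[model.retained_columns] = model.coefficients * sd
    ster, elec = full[:P], full[P:]

    def levels(v: np.ndarray) -> tuple[float, float]:
        pos, neg = v[v > 0], v[v < 0]
        fav = float(np.percentile(pos, favored_level)) if pos.size else 0.0
        dis = float(np.percentile(neg, disfavored_level)) if neg.size else 0.0
        return dis, fav

    return ContourGrid(
        lattice=block.lattice,
        steric=ster,
        electrostatic=elec,
        favored_level=favored_level,
        disfavored_level=disfavored_level,
        steric_thresholds=levels(ster),
        electrostatic_thresholds=levels(elec),
    )


def write_opendx(values: np.ndarray, lattice: Lattice, path) -> None:
    """Export one volumetric grid in OpenDX scalar format (text)."""
    nx, ny, nz = lattice.dims
    if values.size != lattice.n_points:
        raise ValueError("values do not match lattice size")
    ox, oy, oz = lattice.origin
    s = lattice.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {s:.6f} 0 0\ndelta 0 {s:.6f} 0\ndelta 0 0 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        flat = values.ravel()
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
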
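"""Field-based 3D-QSAR: rigid alignment, Gaussian field grids, PLS.

Activities enter as pIC50 = -log10(IC50 in molar).  Conformers are
superposed onto a reference by least-squares rigid (Kabsch) alignment of
mapped scaffold atoms.  Four field channels are evaluated on a regular
grid around the aligned set, each as a sum of Gaussian kernels
exp(-alpha * r^2) over contributing centers:

* ``donor`` — hydrogens on H-bond donor heavy atoms;
* ``hydrophobic`` — hydrophobic carbons;
* ``electron_withdrawing`` — atoms with negative Gasteiger partial charge,
  weighted by |q| (Gasteiger is the iterative electronegativity-equalization
  charge scheme);
* ``negative_ionic`` — negative-ionizable group centroids.

The flattened per-point channel values are the descriptor matrix regressed
on pIC50 by NIPALS partial least squares (:class:`FieldPLS`), with training
r^2, F and RMSE, seeded repeated leave-k-out cross-validation (q^2 =
1 - PRESS / SS_tot), and signed coefficient maps marking favorable (> 0)
and disfavored (< 0) field regions per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression

from .chem_io import Compound
from .pharmacophore import DEFAULT_FEATURE_RULES, perceive_features

__all__ = [
    "CHANNELS",
    "pic50",
    "AlignedSet",
    "align_rigid",
    "kabsch",
    "GridSpec",
    "FieldGrid",
    "compute_fields",
    "descriptor_matrix",
    "FieldPLS",
    "fit_pls",
    "CVReport",
    "cross_validate",
    "field_maps",
]

CHANNELS = ("donor", "hydrophobic", "electron_withdrawing", "negative_ionic")


def pic50(ic50: float) -> float:
    """pIC50 = -log10(IC50 [M]); IC50 must be positive."""
    if not ic50 > 0:
        raise ValueError(f"ic50 must be > 0 M, got {ic50}")
    return -math.log10(ic50)


# ---------------------------------------------------------------------------
# Rigid alignment


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation R, translation t) such that mobile @ R.T + t best fits
    target; R is a proper rotation (det +1), so reflections are never used.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


@dataclass
class AlignedSet:
    """Compounds with conformers in the reference frame, plus fit RMSDs."""

    compounds: list[Compound]
    scaffold_map: list[list[tuple[int, int]]]
    rmsds: list[float] = field(default_factory=list)


def align_rigid(
    compounds: list[Compound],
    reference: Compound,
    scaffold_map: list[list[tuple[int, int]]],
) -> AlignedSet:
    """Rigidly superpose each compound onto the reference scaffold atoms.

    ``scaffold_map[i]`` lists (compound atom index, reference atom index)
    pairs over heavy atoms; at least 3 pairs are required per compound.
    Collinear mapped atoms still return the minimal-RMSD proper transform.
    """
    if reference.conformer is None:
        raise ValueError("reference has no conformer")
    ref_xyz = np.array([[x, y, z] for _e, x, y, z in reference.conformer])
    aligned: list[Compound] = []
    rmsds: list[float] = []
    for comp, mapping in zip(compounds, scaffold_map):
        if comp.conformer is None:
            raise ValueError(f"compound {comp.id!r} has no conformer")
        if len(mapping) < 3:
            raise ValueError(f"compound {comp.id!r}: need >= 3 mapped atoms, got {len(mapping)}")
        xyz = np.array([[x, y, z] for _e, x, y, z in comp.conformer])
        idx_m = [i for i, _j in mapping]
        idx_r = [j for _i, j in mapping]
        R, t = kabsch(xyz[idx_m], ref_xyz[idx_r])
        new_xyz = xyz @ R.T + t
        rmsd = float(np.sqrt(np.mean(np.sum((new_xyz[idx_m] - ref_xyz[idx_r]) ** 2, axis=1))))
        conformer = [
            (el, *map(float, p)) for (el, *_old), p in zip(comp.conformer, new_xyz)
        ]
        aligned.append(
            Compound(id=comp.id, smiles=comp.smiles, conformer=conformer, props=dict(comp.props))
        )
        rmsds.append(rmsd)
    return AlignedSet(compounds=aligned, scaffold_map=scaffold_map, rmsds=rmsds)


# ---------------------------------------------------------------------------
# Field grids


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin corner, isotropic spacing (A), dims (nx,ny,nz)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    @classmethod
    def enclosing(
        cls, compounds: list[Compound], spacing: float = 1.0, margin: float = 3.0
    ) -> "GridSpec":
        """Smallest grid enclosing all conformers with the given margin."""
        pts = np.vstack(
            [[[x, y, z] for _e, x, y, z in c.conformer] for c in compounds if c.conformer]
        )
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
        dims = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=tuple(map(float, lo)), spacing=float(spacing), dims=dims)

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points as an (n_points, 3) array (x fastest-varying last)."""
        nx, ny, nz = self.dims
        ax = [np.arange(n) * self.spacing + o for n, o in zip((nx, ny, nz), self.origin)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def contains(self, xyz: np.ndarray) -> bool:
        lo = np.array(self.origin)
        hi = lo + (np.array(self.dims) - 1) * self.spacing
        return bool(np.all(xyz >= lo - 1e-9) and np.all(xyz <= hi + 1e-9))


@dataclass
class FieldGrid:
    """Per-point non-negative values for the four field channels on a grid."""

    spec: GridSpec
    channels: dict[str, np.ndarray]


def _gauss_sum(points: np.ndarray, centers: np.ndarray, alpha: float,
               weights: np.ndarray | None = None) -> np.ndarray:
    if centers.size == 0:
        return np.zeros(len(points))
    g = np.exp(-alpha * cdist(points, centers) ** 2)
    if weights is not None:
        return g @ weights
    return g.sum(axis=1)


def _field_centers(compound: Compound) -> dict[str, tuple[np.ndarray, np.ndarray | None]]:
    """Per-channel (centers, weights) for one 3D compound."""
    mol = compound.to_mol(with_coords=True)
    molH = Chem.AddHs(mol, addCoords=True)
    coordsH = molH.GetConformer().GetPositions()

    donor_h: list[int] = []
    for smarts in DEFAULT_FEATURE_RULES["D"]:
        patt = Chem.MolFromSmarts(smarts)
        for (heavy_idx,) in molH.GetSubstructMatches(patt):
            for nb in molH.GetAtomWithIdx(int(heavy_idx)).GetNeighbors():
                if nb.GetSymbol() == "H":
                    donor_h.append(nb.GetIdx())
    donor_centers = coordsH[sorted(set(donor_h))] if donor_h else np.empty((0, 3))

    hydro: set[int] = set()
    for smarts in DEFAULT_FEATURE_RULES["H"]:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            hydro.update(match)
    coords = mol.GetConformer().GetPositions()
    hydro_centers = coords[sorted(hydro)] if hydro else np.empty((0, 3))

    Chem.rdPartialCharges.ComputeGasteigerCharges(molH)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in molH.GetAtoms()])
    q = np.nan_to_num(q, nan=0.0, posinf=0.0, neginf=0.0)
    neg = q < 0
    ew_centers = coordsH[neg] if neg.any() else np.empty((0, 3))
    ew_weights = np.abs(q[neg]) if neg.any() else None

    nfeats = [f for f in perceive_features(compound) if f.ftype == "N"]
    ni_centers = np.array([f.centroid for f in nfeats]) if nfeats else np.empty((0, 3))

    return {
        "donor": (donor_centers, None),
        "hydrophobic": (hydro_centers, None),
        "electron_withdrawing": (ew_centers, ew_weights),
        "negative_ionic": (ni_centers, None),
    }


def compute_fields(
    aligned: AlignedSet | list[Compound],
    grid: GridSpec | None = None,
    alpha: float = 0.5,
    spacing: float = 1.0,
    margin: float = 3.0,
) -> list[FieldGrid]:
    """Evaluate the four Gaussian field channels for each aligned compound.

    ``alpha`` is the kernel decay in A^-2.  If ``grid`` is None an enclosing
    grid with the given spacing and margin is constructed.  A conformer
    outside the grid raises ``ValueError``.
    """
    compounds = aligned.compounds if isinstance(aligned, AlignedSet) else aligned
    if grid is None:
        grid = GridSpec.enclosing(compounds, spacing=spacing, margin=margin)
    points = grid.points()
    out: list[FieldGrid] = []
    for comp in compounds:
        xyz = np.array([[x, y, z] for _e, x, y, z in comp.conformer])
        if not grid.contains(xyz):
            raise ValueError(f"conformer of {comp.id!r} lies outside the field grid")
        centers = _field_centers(comp)
        channels = {
            name: _gauss_sum(points, c, alpha, w) for name, (c, w) in centers.items()
        }
        out.append(FieldGrid(spec=grid, channels=channels))
    return out


def descriptor_matrix(fields: list[FieldGrid]) -> np.ndarray:
    """Stack field grids into an (n_compounds, 4 * n_points) matrix.

    Columns are the four channels concatenated in :data:`CHANNELS` order.
    """
    return np.array(
        [np.concatenate([fg.channels[ch] for ch in CHANNELS]) for fg in fields]
    )


# ---------------------------------------------------------------------------
# PLS model


class FieldPLS(BaseEstimator, RegressorMixin):
    """NIPALS partial least squares of pIC50 on field descriptors.

    Columns with variance below ``var_threshold`` (empty grid regions) are
    dropped, then descriptors and response are mean-centered.  Unit-variance
    autoscaling is available (``scale=True``) but off by default: grid-field
    channels share a common physical scale, and autoscaling inflates
    near-empty grid columns by orders of magnitude, which wrecks
    cross-validated prediction — field-QSAR models are conventionally fit
    unscaled.  Coefficients are reported in the original descriptor space
    with zeros at dropped columns.

    Attributes (after :meth:`fit`)
    ------------------------------
    coefficients_ : ndarray (n_descriptors,)
        Regression weights in the original descriptor space.
    intercept_ : float
    kept_columns_ : ndarray of int
        Descriptor indices surviving the variance filter.
    r2_, rmse_, f_ : float
        Training r^2, RMSE = sqrt(SS_res / n), and the regression
        F = (r^2 / k) / ((1 - r^2) / (n - k - 1)) with k latent factors.
    see_ : float
        Standard error of estimate, sqrt(SS_res / (n - k - 1)) — the
        alternative reading of a "pIC50 error".
    """

    def __init__(self, n_factors: int = 4, var_threshold: float = 1e-8, scale: bool = False):
        self.n_factors = n_factors
        self.var_threshold = var_threshold
        self.scale = scale

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FieldPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y sample counts differ")
        if n < self.n_factors + 2:
            raise ValueError(
                f"under-determined: {n} samples for {self.n_factors} factors "
                f"(need >= n_factors + 2)"
            )
        if np.var(y) < 1e-16:
            raise ValueError("degenerate response: y has zero variance")
        kept = np.flatnonzero(np.var(X, axis=0) >= self.var_threshold)
        if kept.size == 0:
            raise ValueError("all descriptor columns filtered out (zero variance)")
        k = min(self.n_factors, n - 1, kept.size)
        if k < 1:
            raise ValueError("cannot fit with < 1 latent factor")
        pls = PLSRegression(n_components=k, scale=self.scale)
        pls.fit(X[:, kept], y)
        # sklearn stores coef_ in unscaled-X units and predicts on centered X
        coef_kept = pls.coef_.ravel()
        self.coefficients_ = np.zeros(p)
        self.coefficients_[kept] = coef_kept
        self.intercept_ = float(np.ravel(pls.intercept_)[0] - pls._x_mean @ coef_kept)
        self.kept_columns_ = kept
        self.n_factors_used_ = k
        y_hat = X @ self.coefficients_ + self.intercept_
        ss_res = float(np.sum((y - y_hat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot
        self.rmse_ = math.sqrt(ss_res / n)
        dof = n - k - 1
        self.see_ = math.sqrt(ss_res / dof) if dof > 0 else float("nan")
        self.f_ = f_statistic(self.r2_, k, n)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coefficients_"):
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.coefficients_):
            raise ValueError(
                f"descriptor length {X.shape[1]} does not match model ({len(self.coefficients_)})"
            )
        return X @ self.coefficients_ + self.intercept_


def f_statistic(r2: float, k: int, n: int) -> float:
    """Regression F-test: (r^2 / k) / ((1 - r^2) / (n - k - 1)).

    A numerically perfect fit (r^2 == 1) yields +inf.
    """
    if n - k - 1 <= 0:
        raise ValueError("n - k - 1 must be positive")
    if r2 >= 1.0:
        return float("inf")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def fit_pls(X: np.ndarray, y: np.ndarray, n_factors: int = 4) -> FieldPLS:
    """Fit a :class:`FieldPLS` model (functional wrapper)."""
    return FieldPLS(n_factors=n_factors).fit(X, y)


@dataclass
class CVReport:
    """Repeated leave-k-out cross-validation summary."""

    scheme: str
    k: int
    n_repeats: int
    seed: int
    q2: float
    press: float
    q2_per_repeat: list[float]
    r2_per_repeat: list[float]
    residuals: list[np.ndarray]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    n_repeats: int = 5,
    n_factors: int = 4,
    seed: int = 20160325,
) -> CVReport:
    """Seeded repeated leave-k-out cross-validation of the PLS model.

    Each repeat randomly partitions the samples into folds of size ``k``
    (a final smaller fold absorbs any remainder); each fold is predicted
    from a model fit on the rest.  q^2 = 1 - PRESS / SS_tot, pooled over
    repeats.  Also reports the per-repeat full-data training r^2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if k >= n:
        raise ValueError(f"fold size k={k} must be < n_samples={n}")
    rng = np.random.default_rng(seed)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    press_total = 0.0
    q2_rep: list[float] = []
    r2_rep: list[float] = []
    residuals: list[np.ndarray] = []
    for _rep in range(n_repeats):
        perm = rng.permutation(n)
        folds = [perm[i : i + k] for i in range(0, n, k)]
        resid = np.empty(n)
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            model = FieldPLS(n_factors=n_factors).fit(X[train], y[train])
            resid[fold] = y[fold] - model.predict(X[fold])
        press = float(np.sum(resid**2))
        press_total += press
        q2_rep.append(1.0 - press / ss_tot)
        r2_rep.append(FieldPLS(n_factors=n_factors).fit(X, y).r2_)
        residuals.append(resid)
    q2 = 1.0 - press_total / (n_repeats * ss_tot)
    return CVReport(
        scheme="leave-k-out",
        k=k,
        n_repeats=n_repeats,
        seed=seed,
        q2=q2,
        press=press_total,
        q2_per_repeat=q2_rep,
        r2_per_repeat=r2_rep,
        residuals=residuals,
    )


def field_maps(model: FieldPLS, grid: GridSpec) -> pd.DataFrame:
    """Signed PLS coefficients on the grid, one row per (point, channel).

    Columns (x, y, z, channel, coefficient); favorable regions have
    coefficient > 0, disfavored < 0.  Row count is 4 * n_points.
    """
    if not hasattr(model, "coefficients_"):
        raise RuntimeError("model is not fitted")
    G = grid.n_points
    if len(model.coefficients_) != 4 * G:
        raise ValueError("model descriptor length does not match grid")
    pts = grid.points()
    frames = []
    for ci, ch in enumerate(CHANNELS):
        coef = model.coefficients_[ci * G : (ci + 1) * G]
        frames.append(
            pd.DataFrame(
                {"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "channel": ch,
                 "coefficient": coef}
            )
        )
    return pd.concat(frames, ignore_index=True)
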
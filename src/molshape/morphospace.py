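"""Morphospace construction and mean-shape comparison.

EFA coefficient sets are flattened into a shapes x coefficients matrix
(DC terms excluded — location is an alignment artifact), embedded by PCA on
the covariance (coefficients share units, so no column scaling), and group
separation along each component is tested with a two-sample location test.
Mean shapes of two groups are compared with an exact-interpolation 2-D
thin-plate spline (TPS); the displacement magnitude ``|f(x) - x|`` on a
regular lattice is the deformation heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, solve

from . import stats as _stats
from .efa import EFACoefficients, efa_inverse, mean_shape
from .errors import (BadGrouping, BadParameter, DegenerateMatrix,
                     SingularSystem)
from .outlines import Outline


@dataclass
class ShapeMatrix:
    """Shapes x flattened-EFA-coefficient matrix with group labels."""

    data: pd.DataFrame          # rows = shape labels, cols = a1..dN
    groups: pd.Series           # group label per row
    view: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise BadParameter("a shape matrix needs at least 2 rows")
        if self.data.isna().any().any():
            raise BadParameter("shape matrix has missing cells")
        self.groups = pd.Series(self.groups, index=self.data.index)


def build_shape_matrix(coeff_list: list[EFACoefficients], groups,
                       view: str = "") -> ShapeMatrix:
    """Flatten coefficient sets (harmonics only, DC excluded) row-wise."""
    n = coeff_list[0].n_harmonics
    cols = [f"{k}{i}" for k in "abcd" for i in range(1, n + 1)]
    rows = {c.label: c.flattened() for c in coeff_list}
    data = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return ShapeMatrix(data, pd.Series(list(groups), index=data.index),
                       view=view, normalized=coeff_list[0].normalized)


@dataclass
class PCAResult:
    scores: pd.DataFrame        # shapes x components
    loadings: pd.DataFrame      # columns x components
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    center: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        """Scores x loadings' + center; equals the input matrix."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(rec + self.center.to_numpy(),
                            index=self.scores.index,
                            columns=self.loadings.index)


def pca(matrix: ShapeMatrix) -> PCAResult:
    """Column-centered covariance PCA with a deterministic sign convention
    (the largest-magnitude loading of each component is positive)."""
    X = matrix.data.to_numpy(dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(Xc):
        raise DegenerateMatrix("shape matrix has zero total variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (len(X) - 1)
    # deterministic sign: flip so each component's extreme loading is positive
    for k in range(len(s)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    names = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=matrix.data.index, columns=names),
        loadings=pd.DataFrame(Vt.T, index=matrix.data.columns, columns=names),
        eigenvalues=eig,
        variance_fractions=eig / eig.sum(),
        center=pd.Series(center, index=matrix.data.columns))


def pc_group_test(scores, groups, variant: str = "welch") -> _stats.TestResult:
    """Two-sample location test of one PC's scores between two groups.

    A group with fewer than 2 members yields a low-power-flagged result
    (group means reported, statistic undefined) rather than an error.
    """
    scores = pd.Series(scores)
    groups = pd.Series(list(groups), index=scores.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise BadGrouping(f"need exactly 2 group levels, got {len(levels)}")
    x = scores[groups == levels[0]].to_numpy(dtype=float)
    y = scores[groups == levels[1]].to_numpy(dtype=float)
    means = (float(np.mean(x)), float(np.mean(y)))
    if min(len(x), len(y)) < 2:
        return _stats.TestResult(statistic=np.nan, p_value=np.nan, df=np.nan,
                                 n=(len(x), len(y)), variant=variant,
                                 group_means=means, low_power=True)
    res = _stats.two_sample_t(x, y, variant=variant)
    res.group_means = means
    return res


# ---------------------------------------------------------------------------
# Thin-plate spline deformation
# ---------------------------------------------------------------------------

def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r ** 2 * np.log(r)
    return np.where(r > 0, u, 0.0)


@dataclass
class DeformationField:
    """Exact-interpolation TPS from source to target landmarks, evaluated as
    a displacement-magnitude field on a regular lattice."""

    grid_x: np.ndarray            # (g, g)
    grid_y: np.ndarray
    magnitude: np.ndarray         # (g, g) |f(x) - x|
    weights: np.ndarray           # (n, 2) kernel weights per coordinate
    affine: np.ndarray            # (3, 2) rows: 1, x, y
    control_points: np.ndarray    # (n, 2) source landmarks
    targets: np.ndarray           # (n, 2)

    def transform(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        r = np.hypot(pts[:, None, 0] - self.control_points[None, :, 0],
                     pts[:, None, 1] - self.control_points[None, :, 1])
        P = np.column_stack([np.ones(len(pts)), pts])
        return _tps_kernel(r) @ self.weights + P @ self.affine

    def grid_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.grid_x.ravel(),
                             "y": self.grid_y.ravel(),
                             "magnitude": self.magnitude.ravel()})


def tps_deformation(source: Outline, target: Outline,
                    grid_size: int = 60) -> DeformationField:
    """Thin-plate-spline map taking the source outline's points onto the
    target's (corresponding indices), with the displacement magnitude
    evaluated on a ``grid_size`` x ``grid_size`` lattice covering the source
    bounding box padded by 10%."""
    src, dst = source.points, target.points
    if len(src) != len(dst):
        raise BadParameter("source and target must have equal point counts")
    n = len(src)
    r = np.hypot(src[:, None, 0] - src[None, :, 0],
                 src[:, None, 1] - src[None, :, 1])
    K = _tps_kernel(r)
    P = np.column_stack([np.ones(n), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    try:
        sol = solve(A, rhs)
    except LinAlgError as exc:
        raise SingularSystem("degenerate TPS control points") from exc
    if not np.all(np.isfinite(sol)):
        raise SingularSystem("degenerate TPS control points")
    weights, affine = sol[:n], sol[n:]

    lo, hi = src.min(axis=0), src.max(axis=0)
    pad = 0.1 * (hi - lo)
    gx, gy = np.meshgrid(np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size),
                         np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size))
    field = DeformationField(gx, gy, np.zeros_like(gx), weights, affine,
                             src.copy(), dst.copy())
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    disp = field.transform(pts) - pts
    field.magnitude = np.hypot(disp[:, 0], disp[:, 1]).reshape(gx.shape)
    return field


def mean_shape_pair(coeff_list: list[EFACoefficients], groups,
                    n_points: int = 300) -> tuple[Outline, Outline]:
    """Group-wise mean EFA coefficients of two groups, reconstructed as
    outlines at a common point count (point indices correspond)."""
    groups = pd.Series(list(groups))
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise BadGrouping(f"need exactly 2 group levels, got {len(levels)}")
    outs = []
    for lv in levels:
        members = [c for c, g in zip(coeff_list, groups) if g == lv]
        outs.append(efa_inverse(mean_shape(members, label=str(lv)), n_points))
    return outs[0], outs[1]


def plot_deformation_heatmap(field: DeformationField, path,
                             title: str = "") -> None:
    """Warm-colored displacement-magnitude heatmap with the source outline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.pcolormesh(field.grid_x, field.grid_y, field.magnitude,
                       cmap="hot_r", shading="auto")
    closed = np.vstack([field.control_points, field.control_points[:1]])
    ax.plot(closed[:, 0], closed[:, 1], "k-", lw=1)
    ax.set_aspect("equal")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="displacement")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
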
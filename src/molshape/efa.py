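"""Elliptic Fourier analysis (EFA) of closed outlines.

A closed outline traversed at constant speed defines periodic coordinate
functions x(t), y(t) with period T (the perimeter).  EFA expands both in a
truncated Fourier series; harmonic n contributes the coefficient quadruple
(a_n, b_n, c_n, d_n),

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T),

computed here with the classical closed-polygon (piecewise-linear) formulas,
which are exact for polygonal outlines.  The module also provides the inverse
transform, first-harmonic-ellipse normalization (size, rotation and
start-point standardization), the per-harmonic power criterion used to pick a
harmonic count, and arithmetic mean shapes for group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import BadParameter, DegenerateShape, MixedBasis
from .outlines import Outline

#: default harmonic count; for the toxin silhouettes this captures >=99% of
#: the harmonic power
DEFAULT_N_HARMONICS = 20


@dataclass
class EFACoefficients:
    """Per-harmonic Fourier descriptors of one closed outline.

    ``a, b, c, d`` are arrays of length ``n_harmonics``; ``dc = (A0, C0)``
    holds the centroid terms.  When ``normalized`` is set the coefficients are
    standardized against the first-harmonic ellipse: a_1 = 1, b_1 = c_1 = 0.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    dc: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if not (len(self.a) == len(self.b) == len(self.c) == len(self.d)):
            raise BadParameter("coefficient arrays must share one length")
        if len(self.a) < 1:
            raise BadParameter("at least one harmonic is required")

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def harmonic_matrix(self, n: int) -> np.ndarray:
        """2x2 matrix [[a_n, b_n], [c_n, d_n]] of harmonic ``n`` (1-based)."""
        i = n - 1
        return np.array([[self.a[i], self.b[i]], [self.c[i], self.d[i]]])

    def flattened(self, include_dc: bool = False) -> np.ndarray:
        vec = np.concatenate([self.a, self.b, self.c, self.d])
        if include_dc:
            vec = np.concatenate([np.asarray(self.dc, dtype=float), vec])
        return vec


@dataclass
class HarmonicPowerProfile:
    """Per-harmonic power P_n = (a_n^2+b_n^2+c_n^2+d_n^2)/2 and its
    cumulative fraction of the total."""

    power: np.ndarray
    cumulative_fraction: np.ndarray
    include_first: bool = field(default=True)


def efa_forward(outline: Outline, n_harmonics: int = DEFAULT_N_HARMONICS,
                ) -> EFACoefficients:
    """Forward EFA of a closed polygonal outline (unnormalized).

    Uses the exact piecewise-linear integrals over the polygon's chords.
    ``n_harmonics`` may not exceed the Nyquist bound floor(n_points / 2).
    """
    if n_harmonics < 1:
        raise BadParameter("n_harmonics must be positive")
    pts = outline.points
    if n_harmonics > len(pts) // 2:
        raise BadParameter(
            f"n_harmonics={n_harmonics} exceeds Nyquist bound "
            f"{len(pts) // 2} for {len(pts)} points")

    closed = np.vstack([pts, pts[:1]])
    deltas = np.diff(closed, axis=0)          # (K, 2) chords
    dt = np.hypot(deltas[:, 0], deltas[:, 1])  # chord lengths Delta t_p
    if np.any(dt == 0):
        raise BadParameter("outline has zero-length segments")
    t = np.concatenate([[0.0], np.cumsum(dt)])  # cumulative arc length t_p
    T = t[-1]

    n = np.arange(1, n_harmonics + 1)[:, None]       # (N, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T            # (N, K+1)
    dcos = np.diff(np.cos(phi), axis=1)               # (N, K)
    dsin = np.diff(np.sin(phi), axis=1)
    scale = T / (2.0 * n.ravel() ** 2 * np.pi ** 2)
    vx = deltas[:, 0] / dt
    vy = deltas[:, 1] / dt
    a = scale * (dcos @ vx)
    b = scale * (dsin @ vx)
    c = scale * (dcos @ vy)
    d = scale * (dsin @ vy)

    # DC terms: mean of the piecewise-linear parameterized curve
    mid = 0.5 * (closed[:-1] + closed[1:])
    a0, c0 = (mid * dt[:, None]).sum(axis=0) / T
    return EFACoefficients(a, b, c, d, dc=(float(a0), float(c0)),
                           normalized=False, label=outline.label)


def efa_inverse(coeffs: EFACoefficients, n_points: int = 300) -> Outline:
    """Reconstruct an outline by sampling the Fourier series at ``n_points``
    uniform parameter values.  All-zero harmonics give a degenerate outline
    collapsed at the DC point (flagged, not an error)."""
    if n_points < 3:
        raise BadParameter("n_points must be at least 3")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos = np.cos(2.0 * np.pi * n * t[None, :])
    sin = np.sin(2.0 * np.pi * n * t[None, :])
    x = coeffs.dc[0] + coeffs.a @ cos + coeffs.b @ sin
    y = coeffs.dc[1] + coeffs.c @ cos + coeffs.d @ sin
    pts = np.column_stack([x, y])
    degenerate = bool(np.allclose(pts, pts[0], atol=1e-12))
    return Outline(pts, label=coeffs.label, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Coefficient-space transforms (used by normalization and by tests)
# ---------------------------------------------------------------------------

def rotate_coefficients(coeffs: EFACoefficients, angle: float) -> EFACoefficients:
    """Rotate the underlying shape by ``angle`` (radians, CCW, about origin)."""
    cs, sn = np.cos(angle), np.sin(angle)
    a = cs * coeffs.a - sn * coeffs.c
    b = cs * coeffs.b - sn * coeffs.d
    c = sn * coeffs.a + cs * coeffs.c
    d = sn * coeffs.b + cs * coeffs.d
    a0 = cs * coeffs.dc[0] - sn * coeffs.dc[1]
    c0 = sn * coeffs.dc[0] + cs * coeffs.dc[1]
    return replace(coeffs, a=a, b=b, c=c, d=d, dc=(float(a0), float(c0)))


def scale_coefficients(coeffs: EFACoefficients, s: float) -> EFACoefficients:
    return replace(coeffs, a=s * coeffs.a, b=s * coeffs.b, c=s * coeffs.c,
                   d=s * coeffs.d, dc=(s * coeffs.dc[0], s * coeffs.dc[1]))


def shift_start(coeffs: EFACoefficients, phase: float) -> EFACoefficients:
    """Move the outline's start point along the curve by parameter ``phase``
    (radians of the fundamental period)."""
    n = np.arange(1, coeffs.n_harmonics + 1)
    cs, sn = np.cos(n * phase), np.sin(n * phase)
    a = coeffs.a * cs + coeffs.b * sn
    b = -coeffs.a * sn + coeffs.b * cs
    c = coeffs.c * cs + coeffs.d * sn
    d = -coeffs.c * sn + coeffs.d * cs
    return replace(coeffs, a=a, b=b, c=c, d=d)


def _first_harmonic_phase(coeffs: EFACoefficients) -> float:
    a1, b1, c1, d1 = coeffs.a[0], coeffs.b[0], coeffs.c[0], coeffs.d[0]
    return 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                            a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2)


def _normalize_candidate(coeffs: EFACoefficients, theta: float) -> EFACoefficients:
    shifted = shift_start(coeffs, theta)
    psi = np.arctan2(shifted.c[0], shifted.a[0])
    rotated = rotate_coefficients(shifted, -psi)
    size = rotated.a[0]
    if size <= 0:
        raise DegenerateShape("null first-harmonic ellipse")
    out = scale_coefficients(rotated, 1.0 / size)
    # b1 and c1 vanish analytically; snap away roundoff
    out.a[0], out.b[0], out.c[0] = 1.0, 0.0, 0.0
    return replace(out, normalized=True)


def efa_normalize(coeffs: EFACoefficients) -> EFACoefficients:
    """Standardize rotation, size, and start point against the first-harmonic
    ellipse, giving a_1 = 1, b_1 = c_1 = 0.

    The start-point phase has a residual 180-degree ambiguity (both ends of
    the major axis standardize the first harmonic identically but differ in
    higher harmonics); it is resolved deterministically by picking the
    candidate with the lexicographically larger flattened coefficient vector,
    which is invariant to the input's rotation, scale and start point.
    """
    first_power = float(coeffs.harmonic_matrix(1).ravel() @
                        coeffs.harmonic_matrix(1).ravel())
    if first_power <= 0:
        raise DegenerateShape("first harmonic is null")
    theta = _first_harmonic_phase(coeffs)
    cand1 = _normalize_candidate(coeffs, theta)
    cand2 = _normalize_candidate(coeffs, theta + np.pi)
    k1 = tuple(np.round(cand1.flattened(), 9))
    k2 = tuple(np.round(cand2.flattened(), 9))
    return cand1 if k1 >= k2 else cand2


def harmonic_power(coeffs: EFACoefficients,
                   include_first: bool = True) -> HarmonicPowerProfile:
    """Per-harmonic power and cumulative fraction of total power.

    ``include_first=False`` drops harmonic 1 from the total (a convention
    some outline-morphometric traditions use); the default includes it.
    """
    p = 0.5 * (coeffs.a ** 2 + coeffs.b ** 2 + coeffs.c ** 2 + coeffs.d ** 2)
    contrib = p.copy()
    if not include_first:
        contrib[0] = 0.0
    total = contrib.sum()
    if total <= 0:
        raise DegenerateShape("outline has zero harmonic power")
    return HarmonicPowerProfile(p, np.cumsum(contrib) / total,
                                include_first=include_first)


def min_harmonics_for_power(coeffs: EFACoefficients, threshold: float,
                            include_first: bool = True) -> int:
    """Smallest harmonic count whose cumulative power fraction reaches
    ``threshold`` (a fraction in (0, 1])."""
    if not 0.0 < threshold <= 1.0:
        raise BadParameter("threshold must be in (0, 1]")
    frac = harmonic_power(coeffs, include_first=include_first).cumulative_fraction
    idx = np.nonzero(frac >= threshold - 1e-12)[0]
    return int(idx[0]) + 1


def mean_shape(coeff_list: list[EFACoefficients], label: str = "mean",
               ) -> EFACoefficients:
    """Per-coefficient arithmetic mean (including DC terms) of a family of
    coefficient sets sharing one harmonic count and normalization state."""
    if not coeff_list:
        raise BadParameter("mean_shape needs at least one member")
    n = coeff_list[0].n_harmonics
    norm = coeff_list[0].normalized
    for c in coeff_list[1:]:
        if c.n_harmonics != n or c.normalized != norm:
            raise MixedBasis("mean_shape requires a common harmonic count "
                             "and normalization state")
    return EFACoefficients(
        a=np.mean([c.a for c in coeff_list], axis=0),
        b=np.mean([c.b for c in coeff_list], axis=0),
        c=np.mean([c.c for c in coeff_list], axis=0),
        d=np.mean([c.d for c in coeff_list], axis=0),
        dc=tuple(np.mean([c.dc for c in coeff_list], axis=0)),
        normalized=norm, label=label)


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def coeffs_to_frame(coeff_list: list[EFACoefficients]) -> pd.DataFrame:
    n = coeff_list[0].n_harmonics
    cols = (["label", "normalized", "A0", "C0"]
            + [f"{k}{i}" for k in "abcd" for i in range(1, n + 1)])
    rows = []
    for c in coeff_list:
        if c.n_harmonics != n:
            raise MixedBasis("all coefficient sets must share one harmonic count")
        rows.append([c.label, c.normalized, c.dc[0], c.dc[1],
                     *c.a, *c.b, *c.c, *c.d])
    return pd.DataFrame(rows, columns=cols)


def write_coeffs_csv(coeff_list: list[EFACoefficients], path) -> None:
    coeffs_to_frame(coeff_list).to_csv(path, index=False)


def read_coeffs_csv(path) -> list[EFACoefficients]:
    df = pd.read_csv(path)
    n = sum(col.startswith("a") and col[1:].isdigit() for col in df.columns)
    out = []
    for _, row in df.iterrows():
        out.append(EFACoefficients(
            a=row[[f"a{i}" for i in range(1, n + 1)]].to_numpy(float),
            b=row[[f"b{i}" for i in range(1, n + 1)]].to_numpy(float),
            c=row[[f"c{i}" for i in range(1, n + 1)]].to_numpy(float),
            d=row[[f"d{i}" for i in range(1, n + 1)]].to_numpy(float),
            dc=(float(row["A0"]), float(row["C0"])),
            normalized=bool(row["normalized"]), label=str(row["label"])))
    return out
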
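"""Deterministic spline bases: natural cubic (1-d) and low-rank thin plate (2-d).

Natural cubic bases carry interior knots at quantiles and boundary knots at
the data range; the thin-plate basis uses the r^2 log r radial kernel on
space-filling knots, reduced to the requested degrees of freedom by an
eigendecomposition of the knot kernel matrix.  Both bases contain the linear
trend exactly (the natural basis includes x itself; the thin-plate basis
includes centred coordinates), and the thin-plate construction depends on
coordinates only through pairwise distances plus centred linear terms, so
fitted values are invariant under translation of the coordinate system.
"""

from __future__ import annotations

import numpy as np


def natural_cubic_basis(
    x: np.ndarray, df: int, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Interior knots sit at quantiles of ``x``; boundary knots at its range.
    The function is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if np.unique(x).size <= df:
        raise ValueError(f"df={df} needs more than {df} distinct values")
    if df == 1:
        return x[:, None].copy()
    if knots is None:
        probs = np.linspace(0, 100, df + 1)  # 2 boundary + (df-1) interior
        knots = np.percentile(x, probs)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValueError("knots must be distinct; too many df for the data?")
    K = len(knots)  # == df + 1

    def d(j: int) -> np.ndarray:
        num = np.maximum(x - knots[j], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x]
    dKm1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dKm1)
    raw = np.column_stack(cols)
    # centre then orthonormalise (span-preserving modulo the intercept): raw
    # truncated-power columns are badly scaled, nearly collinear with each
    # other and — for variables like calendar year — with the constant, which
    # wrecks downstream Newton solvers.  Models pair this basis with an
    # explicit intercept, so removing the constant component is harmless.
    raw = raw - raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    return q * np.sqrt(len(x))


def _farthest_point_knots(pts: np.ndarray, k: int) -> np.ndarray:
    """Deterministic space-filling subset: start nearest the centroid, then
    repeatedly add the point farthest from the chosen set."""
    centroid = pts.mean(axis=0)
    chosen = [int(np.argmin(((pts - centroid) ** 2).sum(axis=1)))]
    d2 = ((pts - pts[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, ((pts - pts[nxt]) ** 2).sum(axis=1))
    return pts[chosen]


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # r^2 log r = 0.5 * r^2 log r^2; define 0 at r = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def thin_plate_basis(coords: np.ndarray, df: int, max_knots: int = 40) -> np.ndarray:
    """Low-rank 2-d thin plate regression spline basis with ``df`` columns.

    Columns: the two centred coordinates plus ``df - 2`` leading eigenvectors
    of the radial-kernel matrix evaluated on space-filling knots, mapped to
    the data through the kernel.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("thin plate basis needs (n, 2) coordinates")
    if df < 3:
        raise ValueError("2-d thin plate basis needs df >= 3")
    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] <= df:
        raise ValueError(f"df={df} needs more than {df} distinct coordinate pairs")
    centred = coords - coords.mean(axis=0)

    k = min(max(3 * df, 20), uniq.shape[0], max_knots)
    knots = _farthest_point_knots(uniq, k)
    d2_kk = ((knots[:, None, :] - knots[None, :, :]) ** 2).sum(-1)
    K_kk = _tps_kernel(d2_kk)
    eigval, eigvec = np.linalg.eigh(K_kk)
    order = np.argsort(np.abs(eigval))[::-1]
    U = eigvec[:, order[: df - 2]]
    scale = np.sqrt(np.abs(eigval[order[: df - 2]]))
    scale[scale == 0] = 1.0

    d2_nk = ((coords[:, None, :] - knots[None, :, :]) ** 2).sum(-1)
    E = _tps_kernel(d2_nk)
    smooth = (E @ U) / scale
    # unit-scale the smooth columns: the eigen-scaling leaves arbitrary and
    # wildly different magnitudes, which hurts downstream conditioning
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    smooth = smooth / sd
    return np.column_stack([centred, smooth])


def spline_basis(values: np.ndarray, df: int, kind: str = "natural_cubic") -> np.ndarray:
    """Dispatch: ``natural_cubic`` for 1-d values, ``thin_plate_2d`` for (n, 2)
    coordinates.  Returns a basis matrix with exactly ``df`` columns."""
    if kind == "natural_cubic":
        return natural_cubic_basis(np.asarray(values, float).ravel(), df)
    if kind == "thin_plate_2d":
        return thin_plate_basis(values, df)
    raise ValueError(f"unknown spline kind {kind!r}")
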
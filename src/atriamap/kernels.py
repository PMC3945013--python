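"""Analytic triangle integrals used by the boundary-element operators.

Two kernels per (point, triangle) pair:

* the solid angle subtended by the triangle (van Oosterom & Strackee
  arctangent formula), the building block of the double-layer operator;
* the single-layer potential integral ``\\int_T 1/r dS`` (Wilton/Rao
  line-integral formula), finite even when the observation point lies in
  the triangle, including at the singular point r = 0.

Both are exact for flat triangles.  Numba-compiled; inputs are float64.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "triangle_solid_angles",
    "triangle_single_layer",
    "winding_number",
]

_EPS = 1e-12


@njit(cache=True)
def _solid_angle_one(ax, ay, az, bx, by, bz, cx, cy, cz):
    """Signed solid angle of triangle (a, b, c) at the origin.

    Positive when the triangle winding appears counterclockwise from the
    origin, i.e. for an outward-oriented closed surface enclosing it.
    """
    ra = np.sqrt(ax * ax + ay * ay + az * az)
    rb = np.sqrt(bx * bx + by * by + bz * bz)
    rc = np.sqrt(cx * cx + cy * cy + cz * cz)
    if ra < _EPS or rb < _EPS or rc < _EPS:
        return 0.0  # observation at a vertex: adjacent triangle subtends 0
    num = (
        ax * (by * cz - bz * cy)
        + ay * (bz * cx - bx * cz)
        + az * (bx * cy - by * cx)
    )
    den = (
        ra * rb * rc
        + (ax * bx + ay * by + az * bz) * rc
        + (ax * cx + ay * cy + az * cz) * rb
        + (bx * cx + by * cy + bz * cz) * ra
    )
    return 2.0 * np.arctan2(num, den)


@njit(cache=True)
def _single_layer_one(x, v0, v1, v2):
    """``\\int_T 1/|y - x| dS(y)`` over the flat triangle (v0, v1, v2)."""
    e1x = v1[0] - v0[0]; e1y = v1[1] - v0[1]; e1z = v1[2] - v0[2]
    e2x = v2[0] - v0[0]; e2y = v2[1] - v0[1]; e2z = v2[2] - v0[2]
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < _EPS:
        raise ValueError("degenerate triangle in single-layer integral")
    nx /= nn; ny /= nn; nz /= nn
    # signed height of x above the triangle plane
    d = (x[0] - v0[0]) * nx + (x[1] - v0[1]) * ny + (x[2] - v0[2]) * nz
    px = x[0] - d * nx; py = x[1] - d * ny; pz = x[2] - d * nz
    total = 0.0
    for k in range(3):
        if k == 0:
            a0, a1 = v0, v1
        elif k == 1:
            a0, a1 = v1, v2
        else:
            a0, a1 = v2, v0
        sx = a1[0] - a0[0]; sy = a1[1] - a0[1]; sz = a1[2] - a0[2]
        sl = np.sqrt(sx * sx + sy * sy + sz * sz)
        sx /= sl; sy /= sl; sz /= sl
        # outward in-plane edge normal for CCW winding: s x n
        ux = sy * nz - sz * ny
        uy = sz * nx - sx * nz
        uz = sx * ny - sy * nx
        t0 = (a0[0] - px) * ux + (a0[1] - py) * uy + (a0[2] - pz) * uz
        sm = (a0[0] - px) * sx + (a0[1] - py) * sy + (a0[2] - pz) * sz
        sp = (a1[0] - px) * sx + (a1[1] - py) * sy + (a1[2] - pz) * sz
        rm = np.sqrt(
            (a0[0] - x[0]) ** 2 + (a0[1] - x[1]) ** 2 + (a0[2] - x[2]) ** 2
        )
        rp = np.sqrt(
            (a1[0] - x[0]) ** 2 + (a1[1] - x[1]) ** 2 + (a1[2] - x[2]) ** 2
        )
        ad = abs(d)
        r02 = t0 * t0 + d * d
        if abs(t0) < 1e-10 and ad < 1e-10:
            continue  # observation point on the edge line: term vanishes
        num = rp + sp
        den = rm + sm
        if num < 1e-14 or den < 1e-14:
            continue
        term = t0 * np.log(num / den)
        if ad > 1e-14:
            term -= ad * (
                np.arctan(t0 * sp / (r02 + ad * rp))
                - np.arctan(t0 * sm / (r02 + ad * rm))
            )
        total += term
    return total


@njit(cache=True)
def triangle_solid_angles(nodes, triangles, x):
    """Solid angle of every triangle at point ``x`` -> (M,) array."""
    m = triangles.shape[0]
    out = np.empty(m)
    for t in range(m):
        i, j, k = triangles[t, 0], triangles[t, 1], triangles[t, 2]
        out[t] = _solid_angle_one(
            nodes[i, 0] - x[0], nodes[i, 1] - x[1], nodes[i, 2] - x[2],
            nodes[j, 0] - x[0], nodes[j, 1] - x[1], nodes[j, 2] - x[2],
            nodes[k, 0] - x[0], nodes[k, 1] - x[1], nodes[k, 2] - x[2],
        )
    return out


@njit(cache=True)
def triangle_single_layer(nodes, triangles, x):
    """``\\int_T 1/r dS`` for every triangle at point ``x`` -> (M,) array."""
    m = triangles.shape[0]
    out = np.empty(m)
    for t in range(m):
        out[t] = _single_layer_one(
            x, nodes[triangles[t, 0]], nodes[triangles[t, 1]],
            nodes[triangles[t, 2]],
        )
    return out


def winding_number(nodes: np.ndarray, triangles: np.ndarray,
                   points: np.ndarray) -> np.ndarray:
    """Generalized winding number (total solid angle / 4 pi) at each point.

    ~1 for points inside a closed outward-oriented surface, ~0 outside.
    """
    nodes = np.ascontiguousarray(nodes, dtype=np.float64)
    triangles = np.ascontiguousarray(triangles, dtype=np.int64)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        out[i] = triangle_solid_angles(nodes, triangles, p).sum() / (4 * np.pi)
    return out
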
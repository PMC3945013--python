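"""Boundary-element forward model and Tikhonov inverse for noncontact mapping.

The blood pool V inside the closed endocardial surface S is source-free, so
the potential is harmonic and Green's second identity links the potential at
an interior point x (a balloon electrode) to the surface potential and its
outward normal derivative E = d(phi)/dn:

    phi(x) = 1/(4 pi) [ integral_S E / r dS + integral_S phi dOmega ].

Collocating at the N surface nodes (piecewise-linear surface potential,
per-triangle analytic integrals distributed to vertices) gives

    (I - S_ee) phi_e = O_ee E_e          (boundary relation)
    phi_c = S_ec phi_e + O_ec E_e        (interior relation)

where S_* are solid-angle (double-layer) matrices scaled by 1/4pi and O_* are
single-layer matrices.  The diagonal of S_ee (the auto-solid-angle, i.e. the
interior solid angle at a node) is completed so that every row sums to 1.
Eliminating E_e yields the 64-by-N forward transfer matrix

    T_ec = S_ec + O_ec O_ee^{-1} (I - S_ee),

which reproduces constant fields exactly (T_ec 1 = 1).  The catheter-to-
endocardium inverse is the Tikhonov-regularized pseudo-inverse

    T_ce = T_ec^T (T_ec T_ec^T + lambda I)^{-1},

using the 64-dimensional normal-equations form of the underdetermined
system.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .electrogram import EgmSet
from .geometry import BalloonArray, TriSurface
from .kernels import triangle_single_layer, triangle_solid_angles

__all__ = [
    "TransferMatrices",
    "solid_angle_row",
    "single_layer_row",
    "assemble_forward",
    "tikhonov_inverse",
    "reconstruct",
    "calibrate_lambda",
    "LAMBDA_REFERENCE",
]

# reference value reported for the clinical-scale discretization; the
# effective optimum depends on mesh, units and electrode layout, so the
# default policy is to calibrate on simulated data instead
LAMBDA_REFERENCE = 1.4e-5


def _node_weights(surface: TriSurface, values: np.ndarray) -> np.ndarray:
    """Distribute per-triangle integral values to vertices in equal thirds."""
    out = np.zeros(surface.n_nodes)
    np.add.at(out, surface.triangles[:, 0], values / 3.0)
    np.add.at(out, surface.triangles[:, 1], values / 3.0)
    np.add.at(out, surface.triangles[:, 2], values / 3.0)
    return out


def solid_angle_row(surface: TriSurface, x) -> np.ndarray:
    """Per-node solid-angle weights at ``x`` (raw, sums to 4 pi inside).

    Uses the van Oosterom-Strackee analytic per-triangle solid angle.
    Triangles containing ``x`` as a vertex subtend zero; points exactly on a
    surface node are handled by the auto-solid-angle completion during
    assembly instead.
    """
    x = np.asarray(x, dtype=np.float64)
    omega = triangle_solid_angles(
        np.ascontiguousarray(surface.nodes),
        np.ascontiguousarray(surface.triangles), x,
    )
    return _node_weights(surface, omega)


def single_layer_row(surface: TriSurface, x) -> np.ndarray:
    """Per-node weights for ``integral psi_j / r dS`` at ``x`` (raw).

    The per-triangle analytic (line-integral) formula is finite for any
    observation point, including the singular case of ``x`` on the triangle.
    """
    x = np.asarray(x, dtype=np.float64)
    g = triangle_single_layer(
        np.ascontiguousarray(surface.nodes),
        np.ascontiguousarray(surface.triangles), x,
    )
    return _node_weights(surface, g)


@dataclass
class TransferMatrices:
    """Assembled BEM operators for one surface/balloon geometry."""

    o_ec: np.ndarray        # (64, N) single layer, catheter rows
    s_ec: np.ndarray        # (64, N) solid angle / 4 pi, catheter rows
    o_ee: np.ndarray        # (N, N) single layer, boundary collocation
    s_ee: np.ndarray        # (N, N) solid angle / 4 pi, row sums 1
    t_ec: np.ndarray        # (64, N) forward transfer matrix
    surface: TriSurface
    lam: float | None = None
    t_ce: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.t_ec.shape[1]

    def with_inverse(self, lam: float) -> "TransferMatrices":
        self.t_ce = tikhonov_inverse(self.t_ec, lam)
        self.lam = lam
        return self

    def surface_checksum(self) -> str:
        hd = hashlib.sha256()
        hd.update(np.ascontiguousarray(self.surface.nodes).tobytes())
        hd.update(np.ascontiguousarray(self.surface.triangles).tobytes())
        return hd.hexdigest()[:16]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("o_ec", "s_ec", "o_ee", "s_ee", "t_ec"):
                f.create_dataset(name, data=getattr(self, name))
            if self.t_ce is not None:
                f.create_dataset("t_ce", data=self.t_ce)
                f.attrs["lam"] = self.lam
            f.attrs["surface_checksum"] = self.surface_checksum()
            f.create_dataset("nodes", data=self.surface.nodes)
            f.create_dataset("triangles", data=self.surface.triangles)

    @classmethod
    def load(cls, path) -> "TransferMatrices":
        import h5py

        with h5py.File(path, "r") as f:
            surface = TriSurface(f["nodes"][:], f["triangles"][:])
            obj = cls(
                o_ec=f["o_ec"][:], s_ec=f["s_ec"][:], o_ee=f["o_ee"][:],
                s_ee=f["s_ee"][:], t_ec=f["t_ec"][:], surface=surface,
            )
            if "t_ce" in f:
                obj.t_ce = f["t_ce"][:]
                obj.lam = float(f.attrs["lam"])
            return obj


def _collocation_rows(surface: TriSurface, points: np.ndarray):
    nodes = np.ascontiguousarray(surface.nodes, dtype=np.float64)
    tris = np.ascontiguousarray(surface.triangles, dtype=np.int64)
    n_pts = len(points)
    omega = np.empty((n_pts, surface.n_nodes))
    single = np.empty((n_pts, surface.n_nodes))
    for i, x in enumerate(np.asarray(points, dtype=np.float64)):
        omega[i] = _node_weights(surface,
                                 triangle_solid_angles(nodes, tris, x))
        single[i] = _node_weights(surface,
                                  triangle_single_layer(nodes, tris, x))
    return omega / (4.0 * np.pi), single / (4.0 * np.pi)


def assemble_forward(surface: TriSurface, balloon: BalloonArray,
                     cond_limit: float = 1e12) -> TransferMatrices:
    """Assemble the 64-by-N forward transfer matrix and its constituents."""
    if not surface.closed:
        raise ValueError("the inverse-problem surface must be closed")
    s_ec, o_ec = _collocation_rows(surface, balloon.positions)
    s_ee, o_ee = _collocation_rows(surface, surface.nodes)
    # auto-solid-angle completion: each row of the double-layer matrix sums
    # to 1, the diagonal being the interior solid angle at the node / 4 pi
    np.fill_diagonal(s_ee, 0.0)
    np.fill_diagonal(s_ee, 1.0 - s_ee.sum(axis=1))

    cond = np.linalg.cond(o_ee)
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"singular single-layer matrix (condition number {cond:.3g})"
        )
    x = linalg.solve(o_ee, np.eye(len(o_ee)) - s_ee)
    t_ec = s_ec + o_ec @ x
    if not np.all(np.isfinite(t_ec)):
        raise FloatingPointError("non-finite entries in forward matrix")
    return TransferMatrices(o_ec=o_ec, s_ec=s_ec, o_ee=o_ee, s_ee=s_ee,
                            t_ec=t_ec, surface=surface)


def tikhonov_inverse(t_ec: np.ndarray, lam: float,
                     cond_limit: float = 1e8) -> np.ndarray:
    """N-by-64 Tikhonov-regularized inverse of the forward matrix."""
    if lam < 0:
        raise ValueError("regularization parameter must be non-negative")
    gram = t_ec @ t_ec.T
    if lam == 0.0 and np.linalg.cond(gram) > cond_limit:
        raise np.linalg.LinAlgError(
            "lambda = 0 requires a well-conditioned system"
        )
    return linalg.solve(gram + lam * np.eye(len(gram)), t_ec,
                        assume_a="pos" if lam > 0 else "gen").T


def reconstruct(catheter: EgmSet, t_ce: np.ndarray,
                positions: np.ndarray | None = None) -> EgmSet:
    """Virtual endocardial electrograms: per-sample product with T_ce."""
    if catheter.n_channels != t_ce.shape[1]:
        raise ValueError(
            f"catheter has {catheter.n_channels} channels, inverse expects "
            f"{t_ce.shape[1]}"
        )
    virtual = t_ce @ catheter.waveforms
    if positions is None:
        positions = np.zeros((t_ce.shape[0], 3))
    return EgmSet(positions=positions, waveforms=virtual, fs=catheter.fs,
                  reconstructed=True)


def calibrate_lambda(
    direct: EgmSet,
    catheter: EgmSet,
    t_ec: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Pick lambda minimizing the mean RMS error between electrograms
    reconstructed from the catheter signals and those computed directly at
    the surface nodes.

    Returns ``(lambda_star, errors)`` with one error per grid value.
    """
    if grid is None:
        grid = np.logspace(-10, -1, 19)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    errors = np.empty(len(grid))
    for i, lam in enumerate(grid):
        t_ce = tikhonov_inverse(t_ec, lam)
        recon = t_ce @ catheter.waveforms
        errors[i] = float(np.sqrt(np.mean(
            (recon - direct.waveforms) ** 2, axis=1)).mean())
    return float(grid[int(np.argmin(errors))]), errors
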
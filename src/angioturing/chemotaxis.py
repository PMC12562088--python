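"""Explicit probabilistic finite-difference scheme for endothelial chemotaxis.

The endothelial density equation

    dn/dt = Dn lap(n) - div( chi(c) n grad c ),   chi(c) = chi0/(1 + alpha c)

is advanced with a conservative flux-form forward-Euler update: diffusive and
chemotactic fluxes are evaluated on cell faces (half indices, arithmetic-mean
interpolation of chi and n) and differenced, with zero normal flux on Neumann
boundaries.  Because every interior face flux appears in exactly two node
updates with opposite sign, the node sum of n is conserved to rounding error.

The same update has a probabilistic reading: the coefficients multiplying the
five von-Neumann-stencil values of n act as stay/left/right/down/up motility
weights.  :func:`motility_probabilities` evaluates those weights at a single
node (the form used by lattice-bound tip agents), clips them at zero and
normalizes them to a probability vector; under the CFL bounds the clipping is
vacuous.  :func:`sample_direction` turns a uniform draw into a move via the
cumulative partition of [0, 1).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .pde_core import CFLViolationError, Grid2D, cfl_dt

__all__ = [
    "MotilityProbs",
    "DIRECTIONS",
    "motility_probabilities",
    "endothelial_step",
    "sample_direction",
]

#: direction labels in cumulative-interval order, with lattice index offsets
#: (axis 0 = x, axis 1 = y): left/right step -x/+x, down/up step -y/+y.
DIRECTIONS = {
    "stay": (0, 0),
    "left": (-1, 0),
    "right": (1, 0),
    "down": (0, -1),
    "up": (0, 1),
}


class MotilityProbs(NamedTuple):
    stay: float
    left: float
    right: float
    down: float
    up: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def motility_probabilities(c_patch, p, dt: float, dx: float) -> MotilityProbs:
    """Stay/move probabilities from a 5-point TAF stencil.

    ``c_patch`` is ``(c_center, c_left, c_right, c_down, c_up)`` where
    left/right are the -x/+x neighbors and down/up the -y/+y neighbors.
    Raw weights follow the probabilistic finite-difference scheme with
    chi(c) = chi0/(1+alpha*c); they are clipped at zero and normalized to
    sum to one (a no-op when dt satisfies the CFL bounds).
    """
    cc, cl, cr, cd, cu = (float(v) for v in c_patch)
    r = p.Dn * dt / dx ** 2
    k = dt * p.chi0 / (4.0 * dx ** 2)

    def s(c):  # chi(c)/chi0
        return 1.0 / (1.0 + p.alpha * c)

    t_xp = k * (s(cr) + s(cc)) * (cr - cc)   # +x face chemotactic weight
    t_xm = k * (s(cl) + s(cc)) * (cc - cl)   # -x face
    t_yp = k * (s(cu) + s(cc)) * (cu - cc)   # +y face
    t_ym = k * (s(cd) + s(cc)) * (cc - cd)   # -y face

    p0 = 1.0 - 4.0 * r - t_xp + t_xm - t_yp + t_ym
    p1 = r - t_xp   # left
    p2 = r + t_xm   # right
    p3 = r - t_yp   # down
    p4 = r + t_ym   # up

    raw = np.maximum([p0, p1, p2, p3, p4], 0.0)
    total = raw.sum()
    if total <= 0.0:
        return MotilityProbs(1.0, 0.0, 0.0, 0.0, 0.0)
    return MotilityProbs(*(raw / total))


def _donor_weights(c: np.ndarray, p, dt: float, grid: Grid2D):
    """Per-node stay/left/right/down/up redistribution weights.

    These are the scheme's coefficients read donor-wise: a node keeps the
    stay weight of its mass and sends the four movement weights to its von
    Neumann neighbors.  Boundary-crossing weights vanish on Neumann grids
    (zero normal flux); periodic grids wrap.  Before clipping the five
    weights sum to one exactly, so the update coincides with the
    conservative flux-form finite-difference step.
    """
    dx, dy = grid.dx, grid.dy
    rx = p.Dn * dt / dx ** 2
    ry = p.Dn * dt / dy ** 2
    kx = dt * p.chi0 / (4.0 * dx ** 2)
    ky = dt * p.chi0 / (4.0 * dy ** 2)
    s = 1.0 / (1.0 + p.alpha * c)

    def face_terms(cv, sv, k):
        """k*(s_i + s_{i+1})*(c_{i+1} - c_i) on faces along axis 0."""
        return k * (sv[1:] + sv[:-1]) * (cv[1:] - cv[:-1])

    shape = grid.shape
    w_left = np.zeros(shape)
    w_right = np.zeros(shape)
    w_down = np.zeros(shape)
    w_up = np.zeros(shape)
    if grid.bc == "periodic":
        cx, sx = np.vstack([c, c[:1]]), np.vstack([s, s[:1]])
        tx = face_terms(cx, sx, kx)               # Nx faces (wraps)
        w_right += rx + tx
        w_left += rx - np.roll(tx, 1, axis=0)
        cy, sy = np.hstack([c, c[:, :1]]), np.hstack([s, s[:, :1]])
        ty = face_terms(cy.T, sy.T, ky).T
        w_up += ry + ty
        w_down += ry - np.roll(ty, 1, axis=1)
    else:
        tx = face_terms(c, s, kx)                 # Nx-1 interior faces
        w_right[:-1] = rx + tx
        w_left[1:] = rx - tx
        ty = face_terms(c.T, s.T, ky).T
        w_up[:, :-1] = ry + ty
        w_down[:, 1:] = ry - ty
    w_stay = 1.0 - (w_left + w_right + w_down + w_up)
    return w_stay, w_left, w_right, w_down, w_up


def endothelial_step(n: np.ndarray, c: np.ndarray, p, dt: float,
                     grid: Grid2D) -> np.ndarray:
    """One conservative explicit step of the endothelial density equation.

    Refuses to step if ``dt`` exceeds the CFL bound for the current TAF
    field (the admissible step is recomputed here; callers normally obtain
    it from :func:`angioturing.pde_core.cfl_dt`).  Each node redistributes
    its mass over its von Neumann stencil with clip-then-normalized
    weights; when the mesh constraint holds no clipping occurs and the
    update is exactly the flux-form finite-difference scheme, while in
    steep-gradient regimes the clipping limits the chemotactic flux so the
    update stays nonnegative and mass-conserving.
    """
    report = cfl_dt(p, c, grid)
    if dt > report.dt * (1.0 + 1e-12):
        raise CFLViolationError(
            f"dt={dt:.3e} exceeds CFL bound {report.dt:.3e}")
    if np.any(n < 0):
        raise ValueError("endothelial density must be nonnegative")
    ws, wl, wr, wd, wu = _donor_weights(c, p, dt, grid)
    stacked = np.stack([ws, wl, wr, wd, wu])
    if stacked.min() < 0.0:
        np.maximum(stacked, 0.0, out=stacked)
        stacked /= stacked.sum(axis=0)
        ws, wl, wr, wd, wu = stacked
    out = n * ws
    if grid.bc == "periodic":
        out += np.roll(n * wr, 1, axis=0) + np.roll(n * wl, -1, axis=0)
        out += np.roll(n * wu, 1, axis=1) + np.roll(n * wd, -1, axis=1)
    else:
        out[1:] += (n * wr)[:-1]
        out[:-1] += (n * wl)[1:]
        out[:, 1:] += (n * wu)[:, :-1]
        out[:, :-1] += (n * wd)[:, 1:]
    return out


def sample_direction(pr: MotilityProbs, u: float) -> str:
    """Direction whose cumulative interval contains the uniform draw ``u``.

    Intervals are half-open [lo, hi); a draw of exactly 1 maps to the last
    direction with nonzero probability (ties are measure zero).
    """
    labels = ("stay", "left", "right", "down", "up")
    cum = np.cumsum(pr.as_array())
    idx = int(np.searchsorted(cum, u, side="right"))
    if idx >= len(labels):
        nz = np.nonzero(pr.as_array())[0]
        idx = int(nz[-1]) if len(nz) else 0
    return labels[idx]
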
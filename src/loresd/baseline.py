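"""Fixed-response multi-shell multi-tissue CSD baseline.

Given externally supplied response functions (for simulations, the ground
truth), solves the convex problem: represent the per-shell signal
coefficients as the convolution of the anisotropic WM response with a WM ODF
plus nonnegative isotropic tissue contributions, subject to ODF amplitude
nonnegativity on the fixed direction set.  Unlike the joint estimator, the
WM ODF here is not unit-normalised; its l = 0 coefficient is a variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import harmonics as shm
from .response import ResponseFunction
from .scheme import ShellSignal

__all__ = ["TissueResponseSet", "msmt_fit_voxel", "response_from_text",
           "response_to_text"]


@dataclass
class TissueResponseSet:
    """WM response plus named isotropic (l = 0 only) responses, shared shells."""

    wm: ResponseFunction
    iso: list[tuple[str, np.ndarray]] = field(default_factory=list)
    # each iso entry: (name, per-shell l=0 zonal coefficients)

    def __post_init__(self):
        n_shells = self.wm.H.shape[0]
        for name, h in self.iso:
            if np.asarray(h).shape != (n_shells,):
                raise ValueError(
                    f"isotropic response {name!r} does not match the WM shell count")
        for i, (na, ha) in enumerate(self.iso):
            for nb, hb in self.iso[i + 1:]:
                if np.allclose(ha, hb, rtol=1e-10, atol=1e-12):
                    raise ValueError(
                        f"isotropic responses {na!r} and {nb!r} are collinear")


def msmt_fit_voxel(signal: ShellSignal, responses: TissueResponseSet,
                   n_constraint_dirs: int = 300,
                   x0: np.ndarray | None = None) -> tuple[np.ndarray, dict[str, float]]:
    """Convex least-squares multi-tissue fit of one voxel.

    Returns the WM ODF coefficient vector and a dict of per-tissue fractions.
    Deterministic: the problem is a convex QP solved to tight tolerance, so
    the solution does not depend on the starting point ``x0``.
    """
    lmax = signal.lmax
    nc = shm.n_coeffs(lmax)
    orders = shm.coeff_orders(lmax)
    shell_lmax = signal.scheme.shell_lmax(lmax)
    mask = orders[None, :] <= shell_lmax[:, None]
    S = np.where(mask, signal.coeffs, 0.0)
    if responses.wm.H.shape[0] != S.shape[0]:
        raise ValueError("response shell count does not match signal")
    N_i = shm.conv_normalisation(lmax)[orders // 2]
    A = (N_i * responses.wm.H[:, orders // 2]) * mask       # (B, nc): S ~ A*p + iso
    iso_cols = np.array([h for _, h in responses.iso]).T \
        if responses.iso else np.zeros((S.shape[0], 0))      # (B, n_iso) -> l=0 only
    n_iso = iso_cols.shape[1]
    Q = shm.constraint_directions(n_constraint_dirs)
    Y = shm.sh_basis_matrix(Q, lmax)

    def fun(x):
        p, c = x[:nc], x[nc:]
        M = A * p
        M[:, 0] += iso_cols @ c
        R = S - M
        gp = -2.0 * np.einsum("bi,bi->i", R, A)
        gc = -2.0 * (R[:, 0] @ iso_cols)
        return float(np.einsum("bi,bi->", R, R)), np.concatenate([gp, gc])

    # unconstrained solution first: the data term is separable in the ODF
    # coefficients (diagonal design) plus the iso block on the l=0 column;
    # if it already satisfies the constraints it is the exact optimum
    D = np.zeros((S.size, nc + n_iso))
    for i in range(nc):
        D[i::nc, i] = A[:, i]
    D[0::nc, nc:] = iso_cols
    x_ls, *_ = np.linalg.lstsq(D, S.ravel(), rcond=None)
    if (Y @ x_ls[:nc]).min() >= -1e-12 and (x_ls[nc:] >= -1e-12).all():
        p = x_ls[:nc]
        fractions = {name: float(max(v, 0.0))
                     for (name, _), v in zip(responses.iso, x_ls[nc:])}
        return p, fractions

    if x0 is None:
        x0 = np.zeros(nc + n_iso)
        x0[0] = max(S[:, 0].mean(), 0.0) / max(A[:, 0].mean(), 1e-12) * 0.5
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.size != nc + n_iso:
            raise ValueError("x0 has wrong length")
    bounds = [(None, None)] * nc + [(0.0, None)] * n_iso
    cons = [{"type": "ineq", "fun": lambda x: Y @ x[:nc],
             "jac": lambda x: np.hstack([Y, np.zeros((Y.shape[0], n_iso))])}]
    res = minimize(fun, x0, jac=True, method="SLSQP", bounds=bounds,
                   constraints=cons, options={"maxiter": 500, "ftol": 1e-12})
    p = res.x[:nc]
    fractions = {name: float(v) for (name, _), v in zip(responses.iso, res.x[nc:])}
    return p, fractions


def response_from_text(path) -> ResponseFunction:
    """Read the standard multi-shell response text format.

    One row per shell, columns = zonal coefficients of even orders
    0, 2, ..., lmax; a single column denotes an isotropic response.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            vals = [float(v) for v in line.split()]
            if rows and len(vals) != len(rows[-1]):
                raise ValueError(f"{path}: ragged row at line {ln}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty response file")
    H = np.array(rows)
    lmax = 2 * (H.shape[1] - 1)
    return ResponseFunction(H=H, lmax=lmax, shell_bvals=np.full(H.shape[0], np.nan))


def response_to_text(path, response: ResponseFunction) -> None:
    np.savetxt(path, response.H, fmt="%.17g")
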
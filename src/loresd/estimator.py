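"""Joint voxel-wise estimation of the local response function and fibre ODF.

In every voxel the signal's per-shell SH coefficients S_l are modelled as the
spherical convolution of a mixture response H(f) = S0 * sum_k f_k G_k and a
unit-normalised ODF p.  The fit minimises

    sum_l || S_l - N_l H_l p_l^T ||_F^2  +  lambda * sum_{l>0} || N_l H_l ||_2^2

over the mixture fractions f (bounds [0, 1], sum to one) and the l >= 2 ODF
coefficients (amplitudes nonnegative on a fixed 300-direction set; the l = 0
coefficient is pinned at 1/sqrt(4*pi)).  The regulariser penalises the
anisotropic energy of the response on the scale on which it enters the
forward model (the convolution coefficients N_l h_l), which indirectly
promotes sparse ODFs.  Solved per voxel by
SQP with the analytic gradient, from a uniform mixture and a single
constrained CSD iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import minimize

from . import harmonics as shm
from .response import (
    DiffusivityGrid,
    GaussianDictionary,
    ResponseFunction,
    assemble_response,
    build_dictionary,
    contrast_matrix,
    contrast_value,
)
from .scheme import AcquisitionScheme, ShellSignal

log = logging.getLogger(__name__)

P00 = 1.0 / np.sqrt(4 * np.pi)

__all__ = [
    "FitConfig",
    "VoxelFit",
    "objective",
    "gradient",
    "initialize",
    "fit_voxel",
    "fit_volume",
    "rmse",
    "parameter_count",
    "aic",
]


@dataclass(frozen=True)
class FitConfig:
    lmax: int = 8
    grid: DiffusivityGrid = field(default_factory=DiffusivityGrid)
    reg_lambda: float = 1e-3
    n_constraint_dirs: int = 300
    rel_ftol: float = 1e-4
    max_iter: int = 200
    n_threads: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.rel_ftol <= 0:
            raise ValueError("rel_ftol must be > 0")


@dataclass
class VoxelFit:
    f: np.ndarray
    p: np.ndarray
    H: ResponseFunction
    rmse: float
    objective_value: float
    n_iterations: int
    converged: bool
    aic: float
    k_params: int


class _Problem:
    """Precomputed tensors for one (signal, dictionary, config) triple."""

    def __init__(self, signal: ShellSignal, dictionary: GaussianDictionary,
                 config: FitConfig):
        lmax = config.lmax
        nc = shm.n_coeffs(lmax)
        orders = shm.coeff_orders(lmax)
        self.j_of_i = orders // 2
        scheme = signal.scheme
        shell_lmax = scheme.shell_lmax(lmax)
        # mask of measurable (shell, coefficient) entries
        self.mask = orders[None, :] <= shell_lmax[:, None]
        self.S = np.where(self.mask, signal.coeffs, 0.0)
        self.N_i = shm.conv_normalisation(lmax)[self.j_of_i]
        self.G = dictionary.G                       # (K, B, J)
        self.Gc = dictionary.G[:, :, self.j_of_i] * self.mask[None]  # (K, B, nc)
        self.K = dictionary.n_nodes
        self.nc = nc
        self.n_q = nc - 1
        self.lam = config.reg_lambda
        # the penalty acts on the convolution coefficients N_l * h_{l,b}
        self.reg_w = shm.conv_normalisation(lmax)[1:] ** 2
        Q = shm.constraint_directions(config.n_constraint_dirs)
        Y = shm.sh_basis_matrix(Q, lmax)
        self.Y0 = Y[:, 0] * P00       # fixed contribution of the pinned l=0 term
        self.Yq = Y[:, 1:]

    def split(self, x):
        return x[: self.K], x[self.K:]

    def value_and_grad(self, x):
        f, q = self.split(x)
        p = np.concatenate(([P00], q))
        Hn = np.tensordot(f, self.G, axes=1)          # (B, J)
        He = Hn[:, self.j_of_i]                       # expanded to coeffs
        M = self.N_i * p * He * self.mask
        R = self.S - M
        data = float(np.einsum("bi,bi->", R, R))
        reg = self.lam * float(
            np.einsum("j,bj,bj->", self.reg_w, Hn[:, 1:], Hn[:, 1:]))
        W = R * (self.N_i * p)                        # (B, nc)
        grad_f = -2.0 * np.einsum("bi,kbi->k", W, self.Gc) \
            + 2.0 * self.lam * np.einsum(
                "j,bj,kbj->k", self.reg_w, Hn[:, 1:], self.G[:, :, 1:])
        # p enters M linearly: d/dp_i = -2 sum_b R_bi * N_i * He_bi
        grad_p = -2.0 * np.einsum("bi,bi->i", R, self.N_i * He * self.mask)
        return data + reg, np.concatenate([grad_f, grad_p[1:]])


def objective(f, q, signal: ShellSignal, dictionary: GaussianDictionary,
              reg_lambda: float = 1e-3, lmax: int | None = None) -> float:
    """Objective value at mixture fractions f and l>=2 ODF coefficients q."""
    cfg = FitConfig(lmax=lmax or dictionary.lmax, grid=dictionary.grid,
                    reg_lambda=reg_lambda)
    prob = _Problem(signal, dictionary, cfg)
    val, _ = prob.value_and_grad(np.concatenate([f, q]))
    return val


def gradient(f, q, signal: ShellSignal, dictionary: GaussianDictionary,
             reg_lambda: float = 1e-3, lmax: int | None = None) -> np.ndarray:
    """Analytic gradient over (f, q); the l=0 ODF coefficient is not a variable."""
    cfg = FitConfig(lmax=lmax or dictionary.lmax, grid=dictionary.grid,
                    reg_lambda=reg_lambda)
    prob = _Problem(signal, dictionary, cfg)
    _, g = prob.value_and_grad(np.concatenate([f, q]))
    return g


def initialize(signal: ShellSignal, dictionary: GaussianDictionary,
               config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Uniform mixture plus one constrained CSD iteration for the ODF.

    With the mixture fixed, the data term is diagonal in the ODF
    coefficients, so the unconstrained optimum is closed-form; a small convex
    QP then restores nonnegativity on the constraint directions.
    Deterministic.  A degenerate (all-zero) signal returns the isotropic ODF.
    """
    prob = _Problem(signal, dictionary, config)
    f0 = np.full(prob.K, 1.0 / prob.K)
    if not np.any(np.abs(prob.S) > 1e-14):
        return f0, np.zeros(prob.n_q)
    Hn = np.tensordot(f0, prob.G, axes=1)
    A = (prob.N_i * Hn[:, prob.j_of_i]) * prob.mask   # (B, nc): S ~ A * p
    den = np.einsum("bi,bi->i", A, A)
    num = np.einsum("bi,bi->i", A, prob.S)
    p_ls = np.where(den > 1e-30, num / np.where(den > 1e-30, den, 1.0), 0.0)
    q0 = p_ls[1:]
    amp = prob.Y0 + prob.Yq @ q0
    if amp.min() >= 0:
        return f0, q0

    def fun(q):
        d = q - q0
        return float(den[1:] @ d**2), 2.0 * den[1:] * d

    cons = [{"type": "ineq",
             "fun": lambda q: prob.Y0 + prob.Yq @ q,
             "jac": lambda q: prob.Yq}]
    res = minimize(fun, np.where(amp.min() < 0, 0.5 * q0, q0), jac=True,
                   method="SLSQP", constraints=cons,
                   options={"maxiter": 100, "ftol": 1e-10})
    return f0, res.x


def _feasibility_polish(prob: _Problem, f: np.ndarray, q: np.ndarray):
    f = np.clip(f, 0.0, 1.0)
    s = f.sum()
    f = f / s if s > 0 else np.full_like(f, 1.0 / f.size)
    amp = prob.Y0 + prob.Yq @ q
    worst = amp.min()
    if worst < -1e-7:
        # shrink the anisotropic part toward the (feasible) isotropic ODF
        t = min(1.0, (prob.Y0.min() - 1e-9) / (prob.Y0.min() - worst))
        q = t * q
    return f, q


def fit_voxel(signal: ShellSignal, dictionary: GaussianDictionary,
              config: FitConfig | None = None) -> VoxelFit:
    """Fit the local response mixture and ODF of a single voxel.

    The signal is normalised by S0 internally so the solver tolerance and the
    regularisation weight are independent of scanner units; the returned
    response carries the S0 scale (the ODF is unit-normalised by
    construction).  Solver failure is reported through ``converged``; the
    best iterate is always returned.
    """
    config = config or FitConfig()
    s0 = signal.s0 if signal.s0 > 0 else 1.0
    norm = ShellSignal(coeffs=signal.coeffs / s0, s0=1.0, lmax=signal.lmax,
                       scheme=signal.scheme,
                       amplitudes=None if signal.amplitudes is None
                       else signal.amplitudes / s0)
    prob = _Problem(norm, dictionary, config)
    f0, q0 = initialize(norm, dictionary, config)
    x0 = np.concatenate([f0, q0])
    val0, _ = prob.value_and_grad(x0)
    ftol = config.rel_ftol * max(val0, 1e-6)
    bounds = [(0.0, 1.0)] * prob.K + [(None, None)] * prob.n_q

    cons = [
        {"type": "eq",
         "fun": lambda x: np.array([x[: prob.K].sum() - 1.0]),
         "jac": lambda x: np.concatenate([np.ones(prob.K), np.zeros(prob.n_q)])[None]},
        {"type": "ineq",
         "fun": lambda x: prob.Y0 + prob.Yq @ x[prob.K:],
         "jac": lambda x: np.hstack([np.zeros((prob.Yq.shape[0], prob.K)), prob.Yq])},
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(prob.value_and_grad, x0, jac=True, method="SLSQP",
                       bounds=bounds, constraints=cons,
                       options={"maxiter": config.max_iter, "ftol": ftol})
    f, q = prob.split(res.x)
    f, q = _feasibility_polish(prob, f, q)
    p = np.concatenate(([P00], q))
    H = assemble_response(f, dictionary, s0)
    val, _ = prob.value_and_grad(np.concatenate([f, q]))

    if norm.amplitudes is not None:
        model = shm.spherical_convolve_coeffs(np.tensordot(f, prob.G, axes=1), p,
                                              config.lmax) * prob.mask
        pred = norm.predicted_amplitudes(model) * s0
        resid = signal.amplitudes - pred
        fit_rmse = rmse(signal.amplitudes, pred)
        rss = float(resid @ resid)
        n_obs = resid.size
    else:
        model = shm.spherical_convolve_coeffs(np.tensordot(f, prob.G, axes=1), p,
                                              config.lmax) * prob.mask
        resid = (norm.S - model) * s0
        rss = float(np.einsum("bi,bi->", resid, resid))
        n_obs = int(prob.mask.sum())
        fit_rmse = np.sqrt(rss / n_obs)

    k = parameter_count("lore_sd", lmax=config.lmax, grid=config.grid)
    return VoxelFit(
        f=f, p=p, H=H, rmse=fit_rmse, objective_value=val,
        n_iterations=int(res.nit), converged=bool(res.success), aic=aic(rss, n_obs, k),
        k_params=k,
    )


def rmse(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean square of per-volume residuals in raw signal space."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.size == 0:
        raise ValueError("rmse of empty input is undefined")
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted must have equal length")
    r = measured - predicted
    return float(np.sqrt(np.mean(r * r)))


def parameter_count(model: str, lmax: int = 8,
                    grid: DiffusivityGrid | None = None, n_iso: int = 2) -> int:
    """Free-parameter count for model comparison.

    lore_sd:   SH coefficients + grid nodes, minus the sum-to-unity and the
               ODF-normalisation constraints (45 + 55 - 2 = 98 at defaults).
    msmt_csd:  SH coefficients + one fraction per isotropic tissue
               (45 + 2 = 47 with two isotropic tissues).
    """
    nc = shm.n_coeffs(lmax)
    if model == "lore_sd":
        grid = grid or DiffusivityGrid()
        return nc + grid.n_nodes - 2
    if model == "msmt_csd":
        return nc + n_iso
    raise ValueError(f"unknown model {model!r}")


def aic(rss: float, n_obs: int, k: int) -> float:
    """Gaussian-residual AIC with the noise variance profiled out."""
    if rss < 0 or n_obs <= 0:
        raise ValueError("rss must be >= 0 and n_obs > 0")
    if rss == 0:
        log.warning("rss = 0: AIC is -inf")
        return -np.inf
    return n_obs * np.log(rss / n_obs) + 2 * k


def fit_volume(dwi: np.ndarray, mask: np.ndarray, scheme: AcquisitionScheme,
               config: FitConfig | None = None,
               dictionary: GaussianDictionary | None = None) -> dict[str, np.ndarray]:
    """Fit every voxel inside the mask; embarrassingly parallel and
    deterministic regardless of thread count.

    Returns a dict of images: ``odf`` (..., n_coeffs), ``mixture``
    (..., n_nodes), ``rmse``, ``converged``, and the four named contrast maps.
    """
    config = config or FitConfig()
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, volumes)")
    if dwi.shape[:3] != mask.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image {dwi.shape[:3]}")
    if dwi.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"image has {dwi.shape[3]} volumes but scheme has {scheme.n_volumes}")
    dictionary = dictionary or build_dictionary(config.grid, scheme, config.lmax)
    nc = shm.n_coeffs(config.lmax)
    shape = mask.shape
    out = {
        "odf": np.zeros(shape + (nc,)),
        "mixture": np.zeros(shape + (dictionary.n_nodes,)),
        "rmse": np.zeros(shape),
        "converged": np.zeros(shape, dtype=bool),
    }
    contrasts = {name: contrast_matrix(name, config.grid)
                 for name in ("intra", "extra", "free_water", "anisotropy")}
    for name in contrasts:
        out[name] = np.zeros(shape)
    voxels = np.argwhere(mask)
    if voxels.size == 0:
        return out

    def _one(ix):
        sig = ShellSignal.from_amplitudes(dwi[tuple(ix)], scheme, config.lmax)
        return fit_voxel(sig, dictionary, config)

    fits = Parallel(n_jobs=config.n_threads)(delayed(_one)(ix) for ix in voxels)
    for ix, fit in zip(voxels, fits):
        t = tuple(ix)
        out["odf"][t] = fit.p
        out["mixture"][t] = fit.f
        out["rmse"][t] = fit.rmse
        out["converged"][t] = fit.converged
        for name, W in contrasts.items():
            out[name][t] = contrast_value(W, fit.f)
    return out
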
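"""Gaussian kernel dictionary on the diffusivity grid, response assembly,
contrast matrices and ODF modulation.

The local response function is a convex mixture of axially symmetric Gaussian
kernels G(b, alpha | lpar, lperp) = exp(-b*lperp) * exp(-b*(lpar-lperp)*cos^2(alpha))
placed on a triangular grid of (axial, radial) diffusivities with
lperp <= lpar.  Mixture fractions live on that grid; scalar contrasts are
inner products of the fractions with a per-node weight matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import harmonics as shm
from .scheme import AcquisitionScheme

log = logging.getLogger(__name__)

__all__ = [
    "DiffusivityGrid",
    "GaussianDictionary",
    "ResponseFunction",
    "ContrastMatrix",
    "gaussian_kernel_zh",
    "build_dictionary",
    "assemble_response",
    "contrast_matrix",
    "contrast_value",
    "modulate_odf",
    "check_mixture",
]


@dataclass(frozen=True)
class DiffusivityGrid:
    """Triangular grid of (lpar, lperp) pairs with lperp <= lpar, in um^2/ms."""

    n_per_axis: int = 10
    lam_range: tuple[float, float] = (0.0, 4.0)

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.lam_range[0], self.lam_range[1], self.n_per_axis)

    @property
    def nodes(self) -> np.ndarray:
        """(n_nodes, 2) array of (lpar, lperp), lpar-major ordering."""
        ax = self.axis
        return np.array([(ax[i], ax[j]) for i in range(self.n_per_axis) for j in range(i + 1)])

    @property
    def n_nodes(self) -> int:
        return self.n_per_axis * (self.n_per_axis + 1) // 2


def gaussian_kernel_zh(
    node: tuple[float, float],
    scheme: AcquisitionScheme,
    lmax: int,
    n_quad: int = 64,
) -> np.ndarray:
    """Zonal-harmonic coefficients of one axially symmetric Gaussian kernel.

    Returns (n_shells, n_orders) with orders l = 0, 2, ..., lmax.  The b = 0
    row is the constant function 1 (only the l = 0 coefficient, sqrt(4*pi)).
    Diffusivities in um^2/ms and b in ms/um^2, so exponents are dimensionless.
    """
    lpar, lperp = float(node[0]), float(node[1])
    if lperp < 0 or lpar < lperp:
        raise ValueError(f"require 0 <= lperp <= lpar, got ({lpar}, {lperp})")
    t, w = shm.gauss_legendre_nodes(n_quad, with_weights=True)
    n_orders = lmax // 2 + 1
    H = np.zeros((len(scheme.shells), n_orders))
    for i, shell in enumerate(scheme.shells):
        b = shell.b
        if shell.is_b0:
            H[i, 0] = np.sqrt(4 * np.pi)
            continue
        samples = np.exp(-b * lperp) * np.exp(-b * (lpar - lperp) * t**2)
        H[i] = shm.zonal_projection(samples, t, lmax, weights=w)
    return H


@dataclass
class GaussianDictionary:
    """Per-node kernel coefficient matrices for one scheme and lmax."""

    grid: DiffusivityGrid
    scheme: AcquisitionScheme
    lmax: int
    G: np.ndarray = field(init=False)  # (n_nodes, n_shells, n_orders)

    def __post_init__(self):
        self.G = np.stack(
            [gaussian_kernel_zh(node, self.scheme, self.lmax) for node in self.grid.nodes]
        )

    @property
    def n_nodes(self) -> int:
        return self.grid.n_nodes


def build_dictionary(
    grid: DiffusivityGrid, scheme: AcquisitionScheme, lmax: int
) -> GaussianDictionary:
    return GaussianDictionary(grid=grid, scheme=scheme, lmax=lmax)


@dataclass
class ResponseFunction:
    """Zonal response coefficients h_{l,b}: rows = shells, cols = even orders."""

    H: np.ndarray
    lmax: int
    shell_bvals: np.ndarray

    def profile(self, shell_index: int, cos_alpha: np.ndarray) -> np.ndarray:
        """Amplitude as a function of cos(alpha) on one shell."""
        B = shm.zonal_basis_matrix(cos_alpha, self.lmax)
        return B @ self.H[shell_index]


def check_mixture(f: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if (f < -atol).any() or (f > 1 + atol).any():
        raise ValueError("mixture fractions must lie in [0, 1]")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"mixture fractions must sum to 1, got {f.sum():.8f}")
    return f


def assemble_response(
    f: np.ndarray, dictionary: GaussianDictionary, s0: float = 1.0
) -> ResponseFunction:
    """H = S0 * sum_k f_k G_k — linear in both the fractions and S0."""
    f = np.asarray(f, dtype=float)
    if f.size != dictionary.n_nodes:
        raise ValueError("fraction count does not match dictionary nodes")
    if s0 < 0:
        log.warning("negative S0 (%.4g) passed to assemble_response; proceeding", s0)
    H = s0 * np.tensordot(f, dictionary.G, axes=1)
    return ResponseFunction(H=H, lmax=dictionary.lmax, shell_bvals=dictionary.scheme.shell_bvals)


# -- contrasts ---------------------------------------------------------------

CONTRAST_NAMES = ("intra", "extra", "free_water", "anisotropy")


@dataclass(frozen=True)
class ContrastMatrix:
    """One scalar weight per grid node; contrasts are <W, f> inner products."""

    W: np.ndarray
    name: str
    grid: DiffusivityGrid


def _fa(lpar: np.ndarray, lperp: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of an axially symmetric tensor (lperp doubled).

    FA = (lpar - lperp) / sqrt(lpar^2 + 2 lperp^2), with the degenerate
    node (0, 0) defined as 0.
    """
    denom = np.sqrt(lpar**2 + 2 * lperp**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(denom > 0, (lpar - lperp) / np.where(denom > 0, denom, 1.0), 0.0)
    return fa


def contrast_matrix(
    name: str,
    grid: DiffusivityGrid,
    d: float = 10.0,
    fw_threshold: float = 2.6,
    require_both: bool = True,
) -> ContrastMatrix:
    """Build one of the named contrast matrices on a diffusivity grid.

    intra:      W = exp(-d * lperp), d in ms/um^2 (default 10) for a smooth
                decay away from zero radial diffusivity.
    free_water: 1 where the node is fast in both directions (>= fw_threshold,
                default 2.6 um^2/ms), else 0.  ``require_both=False`` relaxes
                the test to the axial diffusivity only.
    extra:      1 - intra - free_water (clipped at 0 with a warning if custom
                parameters make it negative).
    anisotropy: the FA of each node's axially symmetric tensor.
    """
    nodes = grid.nodes
    lpar, lperp = nodes[:, 0], nodes[:, 1]
    if name == "intra":
        W = np.exp(-d * lperp)
    elif name == "free_water":
        cond = (lpar >= fw_threshold) & (lperp >= fw_threshold) if require_both \
            else lpar >= fw_threshold
        W = cond.astype(float)
    elif name == "extra":
        Wi = np.exp(-d * lperp)
        Wfw = contrast_matrix("free_water", grid, fw_threshold=fw_threshold,
                              require_both=require_both).W
        W = 1.0 - Wi - Wfw
        # at default parameters W only dips below 0 at float precision
        # (exp(-d*lperp) ~ 1e-12 inside the free-water block); clip only
        # materially negative weights so the triplet partition stays exact
        if (W < -1e-9).any():
            log.warning("extra-axonal weights negative at %d nodes; clipping to 0",
                        int((W < -1e-9).sum()))
            W = np.clip(W, 0.0, None)
    elif name == "anisotropy":
        W = _fa(lpar, lperp)
    else:
        raise ValueError(f"unknown contrast {name!r}; choose from {CONTRAST_NAMES}")
    return ContrastMatrix(W=W, name=name, grid=grid)


def contrast_value(W: ContrastMatrix, f: np.ndarray) -> float:
    """Scalar contrast <W, f> for one voxel's mixture fractions."""
    f = np.asarray(f, dtype=float)
    if f.size != W.W.size:
        raise ValueError("mixture fractions and contrast matrix use different grids")
    return float(W.W @ f)


def modulate_odf(p: np.ndarray, s: float) -> np.ndarray:
    """Scale every ODF coefficient by a nonnegative contrast value.

    Drops unit normalisation but preserves the angular correlation to the
    input exactly (for s > 0).
    """
    if s < 0:
        raise ValueError("modulation scalar must be non-negative")
    return np.asarray(p, dtype=float) * s
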
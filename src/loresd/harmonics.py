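"""Real symmetric spherical-harmonics machinery.

Everything in this package lives in the orthonormal basis of real, even-order
spherical harmonics Y_lm (l = 0, 2, ..., lmax; m = -l..l), the convention used
throughout the constrained-spherical-deconvolution literature.  Axially
symmetric kernels are represented by their zonal (m = 0) coefficients per
shell, and spherical convolution reduces to a scaled outer product per order.

Coefficient ordering is fixed once here: blocks of increasing even l, each
block running m = -l, ..., l.  All modules share this ordering.
"""

from __future__ import annotations

import functools
import importlib.resources

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "n_coeffs",
    "coeff_orders",
    "order_slice",
    "zonal_indices",
    "conv_normalisation",
    "sh_basis_matrix",
    "fit_shell_sh",
    "zonal_projection",
    "zonal_basis_matrix",
    "spherical_convolve_coeffs",
    "uniform_directions",
    "minimum_angle",
    "constraint_directions",
    "apodised_delta",
    "apodisation_taper",
    "acc",
]


def n_coeffs(lmax: int) -> int:
    """Number of real symmetric SH coefficients for even orders l <= lmax."""
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be even and non-negative, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def coeff_orders(lmax: int) -> np.ndarray:
    """Order l of every coefficient in the declared ordering."""
    return np.concatenate([np.full(2 * l + 1, l) for l in range(0, lmax + 1, 2)])


def order_slice(l: int) -> slice:
    """Slice of the coefficient vector holding the m = -l..l block of order l."""
    start = n_coeffs(l) - (2 * l + 1) if l else 0
    return slice(start, start + 2 * l + 1)


def zonal_indices(lmax: int) -> np.ndarray:
    """Coefficient indices of the m = 0 entries, one per even order."""
    return np.array([order_slice(l).start + l for l in range(0, lmax + 1, 2)])


def conv_normalisation(lmax: int) -> np.ndarray:
    """Per-order convolution factors N_l = sqrt(4*pi / (2l + 1)).

    With these factors, convolving a (symmetrised) delta ODF with a kernel
    reproduces the kernel's own profile — the defining normalisation of the
    zonal convolution theorem.
    """
    l = np.arange(0, lmax + 1, 2)
    return np.sqrt(4 * np.pi / (2 * l + 1))


def _check_unit(directions: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise ValueError("directions must be (n, 3)")
    norms = np.linalg.norm(directions, axis=-1)
    if not np.allclose(norms, 1.0, atol=tol):
        raise ValueError("directions must have unit Euclidean norm")
    return directions


def sh_basis_matrix(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the real symmetric SH basis on a set of unit vectors.

    Returns a matrix with one row per direction and one column per (l, m)
    pair in the declared ordering.  Real basis built from the complex
    harmonics: m < 0 -> sqrt(2)*(-1)^m Im(Y_l^|m|), m = 0 -> Y_l^0,
    m > 0 -> sqrt(2)*(-1)^m Re(Y_l^m); orthonormal over the sphere.
    """
    directions = _check_unit(directions)
    if lmax % 2:
        raise ValueError("lmax must be even")
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                col = np.sqrt(2.0) * (-1.0) ** m * y.imag
            elif m == 0:
                col = y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * y.real
            cols.append(col)
    return np.column_stack(cols)


def fit_shell_sh(amplitudes: np.ndarray, directions: np.ndarray, lmax: int) -> np.ndarray:
    """Least-squares SH coefficients of amplitudes sampled on directions.

    Exact for band-limited signals when the directions are non-degenerate.
    Raises if the system is underdetermined (too few directions for lmax).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    directions = _check_unit(directions)
    nc = n_coeffs(lmax)
    if directions.shape[0] < nc:
        raise ValueError(
            f"{directions.shape[0]} directions cannot determine {nc} coefficients; "
            f"lower lmax (need at least {nc} directions for lmax={lmax})"
        )
    Y = sh_basis_matrix(directions, lmax)
    coeffs, *_ = np.linalg.lstsq(Y, amplitudes, rcond=None)
    return coeffs


def zonal_basis_matrix(cos_alpha: np.ndarray, lmax: int) -> np.ndarray:
    """Zonal harmonics Y_l0 as functions of cos(alpha), one column per even l."""
    t = np.asarray(cos_alpha, dtype=float)
    l = np.arange(0, lmax + 1, 2)
    scale = np.sqrt((2 * l + 1) / (4 * np.pi))
    return scale * eval_legendre(l[None, :], t[:, None])


def zonal_projection(kernel_samples: np.ndarray, cos_alpha: np.ndarray, lmax: int,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Zonal-harmonic coefficients of an axially symmetric kernel.

    The kernel is given as samples of its amplitude as a function of
    cos(alpha) on nodes covering [-1, 1].  With quadrature ``weights`` the
    coefficients are the exact L2 projection 2*pi * sum(w * k * Y_l0);
    without, a least-squares Legendre fit is used.  Consistent with
    ``sh_basis_matrix``: evaluating the coefficients through the full basis
    along the kernel axis reproduces the profile for band-limited kernels.
    """
    t = np.asarray(cos_alpha, dtype=float)
    samples = np.asarray(kernel_samples, dtype=float)
    n_orders = lmax // 2 + 1
    if t.size < n_orders:
        raise ValueError(f"need at least {n_orders} quadrature nodes for lmax={lmax}")
    if t.min() > -0.99 or t.max() < 0.99:
        raise ValueError("quadrature nodes must cover [-1, 1]")
    B = zonal_basis_matrix(t, lmax)
    if weights is not None:
        return 2 * np.pi * (B.T @ (np.asarray(weights, dtype=float) * samples))
    coeffs, *_ = np.linalg.lstsq(B, samples, rcond=None)
    return coeffs


def gauss_legendre_nodes(n: int = 64, with_weights: bool = False):
    """Gauss-Legendre nodes (optionally weights) on [-1, 1] for kernel sampling."""
    nodes, w = np.polynomial.legendre.leggauss(n)
    return (nodes, w) if with_weights else nodes


def spherical_convolve_coeffs(H: np.ndarray, p: np.ndarray, lmax: int) -> np.ndarray:
    """Per-shell signal SH coefficients S_l = N_l * h_{l,b} * p_l^T.

    H is (n_shells, n_orders) zonal response coefficients, p a coefficient
    vector of length n_coeffs(lmax).  Returns (n_shells, n_coeffs); the
    caller masks orders a shell cannot measure.
    """
    p = np.asarray(p, dtype=float)
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if p.size != n_coeffs(lmax) or H.shape[1] != lmax // 2 + 1:
        raise ValueError("lmax mismatch between response, ODF and requested order")
    N = conv_normalisation(lmax)
    out = np.empty((H.shape[0], p.size))
    for j, l in enumerate(range(0, lmax + 1, 2)):
        sl = order_slice(l)
        out[:, sl] = N[j] * np.outer(H[:, j], p[sl])
    return out


def uniform_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Deterministic quasi-uniform, antipodally-aware unit vectors.

    Starts from a Fibonacci spiral on the hemisphere (with a tiny seeded
    rotation to break symmetry) and relaxes the points by electrostatic
    repulsion acting between every pair of axes (each point repels both the
    other points and their antipodes), projected back to the sphere each
    step.  Deterministic for a given (n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    phi = 2 * np.pi * i / golden + rng.uniform(0, 2 * np.pi)
    z = (i + 0.5) / n  # hemisphere
    r = np.sqrt(1 - z**2)
    x = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if n == 1:
        return x / np.linalg.norm(x, axis=1, keepdims=True)
    if n > 384:  # spiral is already quasi-uniform; O(n^2) relaxation not worth it
        return x

    def forces_energy(x):
        diff = x[:, None, :] - x[None, :, :]
        dsum = x[:, None, :] + x[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        s2 = np.einsum("ijk,ijk->ij", dsum, dsum)
        np.fill_diagonal(d2, np.inf)
        s2[s2 < 1e-12] = np.inf
        energy = 0.5 * (1 / np.sqrt(d2) + 1 / np.sqrt(s2)).sum()
        force = (diff / d2[..., None] ** 1.5).sum(axis=1) + (
            dsum / s2[..., None] ** 1.5
        ).sum(axis=1)
        return force, energy

    step = 0.05
    _, energy = forces_energy(x)
    for _ in range(n_iter):
        force, _ = forces_energy(x)
        fmax = np.linalg.norm(force, axis=1).max()
        trial = x + (step / fmax) * force
        trial /= np.linalg.norm(trial, axis=1, keepdims=True)
        _, e_trial = forces_energy(trial)
        if e_trial < energy:
            x, energy = trial, e_trial
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-6:
                break
    return x


def minimum_angle(directions: np.ndarray) -> float:
    """Smallest pairwise angle (degrees) between axes (antipodes identified)."""
    d = _check_unit(directions)
    if d.shape[0] < 2:
        return 180.0
    c = np.abs(d @ d.T)
    np.fill_diagonal(c, 0.0)
    return float(np.degrees(np.arccos(np.clip(c.max(), -1, 1))))


@functools.lru_cache(maxsize=None)
def constraint_directions(n: int = 300) -> np.ndarray:
    """The fixed direction set used for ODF nonnegativity constraints.

    The 300-direction set ships with the package so constraint matrices are
    bit-stable across installations; other sizes are generated on the fly.
    """
    if n == 300:
        ref = importlib.resources.files("loresd.data").joinpath("directions300.txt")
        with ref.open("r") as fh:
            dirs = np.loadtxt(fh)
        return dirs
    return uniform_directions(n, seed=0)


APODISATION_LMAX = 8


@functools.lru_cache(maxsize=None)
def apodisation_taper(lmax: int = APODISATION_LMAX) -> tuple[float, ...]:
    """Per-order taper weights of the apodised delta, w_0 = 1.

    The apodised profile is the square of the order-(lmax/2) truncated delta
    expansion (a Fejer-type kernel), normalised to unit integral: exactly
    band-limited at lmax, nonnegative everywhere by construction, and as
    peaked as the band limit allows.  For lmax < 4 the squared kernel has no
    anisotropic content, so the (also nonnegative) monomial profile
    (n . mu)^lmax is used instead.  The weights are the ratio of the tapered
    coefficients to the true delta's coefficients Y_lm(mu).
    """
    t, wq = np.polynomial.legendre.leggauss(4 * max(lmax, 2))
    inner = (lmax // 2) // 2 * 2
    if inner >= 2:
        g = zonal_basis_matrix(t, inner) @ (
            np.sqrt((2 * np.arange(0, inner + 1, 2) + 1) / (4 * np.pi)))
        prof = g**2
    else:
        prof = t**lmax if lmax > 0 else np.ones_like(t)
    prof = prof / (2 * np.pi * (wq @ prof))  # unit integral over the sphere
    h = zonal_projection(prof, t, lmax)
    w = conv_normalisation(lmax) * h
    return tuple(w)


def apodised_delta(orientation: np.ndarray, lmax: int = APODISATION_LMAX) -> np.ndarray:
    """Unit-normalised, band-limited ODF sharply peaked at +/- orientation.

    A true (symmetrised) delta has coefficients Y_lm(orientation); the
    per-order taper removes the ringing that would make the truncated
    expansion negative away from the peak while keeping the profile
    nonnegative everywhere (see ``apodisation_taper``).  The l = 0
    coefficient is 1/sqrt(4*pi), so the ODF integrates to one;
    rotation-equivariant by construction.
    """
    orientation = np.asarray(orientation, dtype=float)
    nrm = np.linalg.norm(orientation)
    if nrm < 1e-12:
        raise ValueError("orientation must be a nonzero vector")
    orientation = orientation / nrm
    Y = sh_basis_matrix(orientation[None, :], lmax)[0]
    taper = np.asarray(apodisation_taper(lmax))[coeff_orders(lmax) // 2]
    return taper * Y


def acc(u: np.ndarray, v: np.ndarray) -> float:
    """Angular correlation coefficient of two SH coefficient vectors.

    Normalised inner product over the l >= 2 coefficients only, so the value
    is blind to each argument's isotropic (l = 0) term and to positive
    rescaling.  Raises if either argument has no l >= 2 energy, where the
    coefficient is undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size:
        raise ValueError("coefficient vectors must share lmax")
    u2, v2 = u[1:], v[1:]  # l = 0 is always the single leading coefficient
    nu, nv = np.linalg.norm(u2), np.linalg.norm(v2)
    if nu < 1e-14 or nv < 1e-14:
        raise ValueError("ACC undefined: an argument has no l >= 2 energy")
    return float(np.dot(u2, v2) / (nu * nv))
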
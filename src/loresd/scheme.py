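"""Acquisition schemes and per-shell SH signal representations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import harmonics as shm

#: b-values within this distance of a shell centre belong to that shell (ms/um^2).
SHELL_TOLERANCE = 0.1
#: b-values below this count as b = 0 (ms/um^2).
B0_THRESHOLD = 0.05


def _to_ms_per_um2(bvals: np.ndarray) -> np.ndarray:
    """Accept b-values in s/mm^2 or ms/um^2; store ms/um^2 (1000 s/mm^2 = 1)."""
    bvals = np.asarray(bvals, dtype=float)
    if bvals.max(initial=0.0) > 100:  # plainly s/mm^2
        bvals = bvals / 1000.0
    return bvals


def max_lmax_for(n_directions: int) -> int:
    """Largest even order whose coefficient count fits n_directions samples."""
    l = 0
    while shm.n_coeffs(l + 2) <= n_directions:
        l += 2
    return l


@dataclass(frozen=True)
class Shell:
    b: float                 # representative b-value, ms/um^2
    indices: np.ndarray      # volume indices belonging to the shell
    lmax: int                # largest even order supported by the direction count

    @property
    def is_b0(self) -> bool:
        return self.b < B0_THRESHOLD


@dataclass
class AcquisitionScheme:
    """b-values (ms/um^2), unit gradient directions and their shell grouping."""

    bvals: np.ndarray
    bvecs: np.ndarray
    shells: list[Shell] = field(init=False)

    def __post_init__(self):
        self.bvals = _to_ms_per_um2(self.bvals)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match {self.bvals.size} b-values"
            )
        if (self.bvals < 0).any():
            raise ValueError("b-values must be non-negative")
        dw = self.bvals >= B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit norm for b > 0")
        self.shells = self._group_shells()

    def _group_shells(self) -> list[Shell]:
        order = np.argsort(self.bvals)
        shells: list[list[int]] = []
        centres: list[float] = []
        for idx in order:
            b = self.bvals[idx]
            if b < B0_THRESHOLD:
                b = 0.0
            if centres and abs(b - centres[-1]) <= SHELL_TOLERANCE:
                shells[-1].append(idx)
                centres[-1] = float(np.mean([self.bvals[i] for i in shells[-1]]))
                if centres[-1] < B0_THRESHOLD:
                    centres[-1] = 0.0
            else:
                shells.append([idx])
                centres.append(b)
        out = []
        for b, idx in zip(centres, shells):
            idx = np.array(sorted(idx))
            lmax = 0 if b < B0_THRESHOLD else max_lmax_for(idx.size)
            out.append(Shell(b=float(b), indices=idx, lmax=lmax))
        return out

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def shell_bvals(self) -> np.ndarray:
        return np.array([s.b for s in self.shells])

    def shell_lmax(self, global_lmax: int) -> np.ndarray:
        return np.array([min(s.lmax, global_lmax) for s in self.shells])

    def shell_directions(self, shell: Shell) -> np.ndarray:
        return self.bvecs[shell.indices]


@dataclass
class ShellSignal:
    """Per-shell SH coefficients of one voxel's signal plus its raw amplitudes.

    ``coeffs`` is (n_shells, n_coeffs(lmax)); entries of orders a shell cannot
    measure are zero and excluded from any data term via the scheme's
    per-shell lmax.  ``s0`` is the mean raw amplitude over b = 0 volumes.
    """

    coeffs: np.ndarray
    s0: float
    lmax: int
    scheme: AcquisitionScheme
    amplitudes: np.ndarray | None = None  # raw per-volume signal, if known

    @classmethod
    def from_amplitudes(
        cls, amplitudes: np.ndarray, scheme: AcquisitionScheme, lmax: int
    ) -> "ShellSignal":
        amplitudes = np.asarray(amplitudes, dtype=float)
        if amplitudes.size != scheme.n_volumes:
            raise ValueError("amplitude count does not match scheme volume count")
        nc = shm.n_coeffs(lmax)
        coeffs = np.zeros((len(scheme.shells), nc))
        s0 = 0.0
        for i, shell in enumerate(scheme.shells):
            amps = amplitudes[shell.indices]
            if shell.is_b0:
                s0 = float(amps.mean())
                coeffs[i, 0] = s0 * np.sqrt(4 * np.pi)
            else:
                l = min(shell.lmax, lmax)
                c = shm.fit_shell_sh(amps, scheme.shell_directions(shell), l)
                coeffs[i, : c.size] = c
        if not any(s.is_b0 for s in scheme.shells):
            # no b=0 shell: reference amplitude falls back to the overall mean
            s0 = float(amplitudes.mean())
        return cls(coeffs=coeffs, s0=s0, lmax=lmax, scheme=scheme, amplitudes=amplitudes)

    def predicted_amplitudes(self, model_coeffs: np.ndarray) -> np.ndarray:
        """Evaluate per-shell coefficient rows at the acquisition directions."""
        out = np.empty(self.scheme.n_volumes)
        for i, shell in enumerate(self.scheme.shells):
            l = min(shell.lmax, self.lmax)
            nc = shm.n_coeffs(l)
            Y = shm.sh_basis_matrix(self.scheme.shell_directions(shell), l) \
                if not shell.is_b0 else None
            if shell.is_b0:
                out[shell.indices] = model_coeffs[i, 0] / np.sqrt(4 * np.pi)
            else:
                out[shell.indices] = Y @ model_coeffs[i, :nc]
        return out
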
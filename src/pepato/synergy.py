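"""Motor-module extraction and per-module metrics.

The m x t matrix of normalized EMG envelopes (m muscles, t = cycles x 200
phase points, cycles concatenated) is factorized as EMG ~ W @ P with
non-negative muscle weights W (m x n) and basic activation patterns
P (n x t). Reconstruction quality is the variance accounted for,
VAF = 1 - SSE/SST with SST taken about the row (muscle) means. Pattern
shape metrics are the full width at half maximum (FWHM, % of cycle) and the
center of activity (CoA), the angle of the first trigonometric moment of
the cycle-averaged pattern treated as a circular distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .errors import ParameterError, PreconditionError, UndefinedMetricError
from .preprocessing import EnvelopeTensor

#: Convergence settings of the multiplicative-update factorization.
NMF_MAX_ITER = 1000
NMF_TOL = 1e-6


@dataclass
class SynergyDecomposition:
    """Best-of-restarts non-negative factorization of an envelope matrix."""

    W: np.ndarray                    # muscles x modules
    P: np.ndarray                    # modules x (cycles*n_phase)
    n_modules: int
    n_phase: int
    vaf_total: float
    vaf_per_muscle: np.ndarray
    rmse: float
    restart_rmse: np.ndarray         # diagnostics: rmse of every restart
    muscle_names: list[str] | None = None

    @property
    def patterns_avg(self) -> np.ndarray:
        """Cycle-averaged patterns, shape (modules, n_phase)."""
        n_cycles = self.P.shape[1] // self.n_phase
        return self.P.reshape(self.n_modules, n_cycles, self.n_phase).mean(axis=1)

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.P


def _as_matrix(tensor: EnvelopeTensor | np.ndarray) -> tuple[np.ndarray, int, list[str] | None]:
    """Muscles x time matrix from a tensor (cycles concatenated) or array."""
    if isinstance(tensor, EnvelopeTensor):
        data = tensor.envelopes_norm
        if data is None:
            raise PreconditionError("tensor must be amplitude-normalized first")
        # cycles x phase x muscles -> muscles x (cycles*phase)
        mat = np.transpose(data, (2, 0, 1)).reshape(data.shape[2], -1)
        return mat, tensor.n_phase, list(tensor.muscle_names)
    mat = np.asarray(tensor, dtype=float)
    if mat.ndim != 2:
        raise ParameterError("expected a 2-D muscles x time matrix")
    return mat, mat.shape[1], None


def compute_vaf(emg: np.ndarray, W: np.ndarray, P: np.ndarray) -> float:
    """Total variance accounted for by the reconstruction W @ P.

    VAF = 1 - SSE/SST where SSE is the summed squared residual and SST the
    summed squared deviation of the data from its row (muscle) means.
    """
    emg = np.asarray(emg, dtype=float)
    resid = emg - W @ P
    sse = float(np.sum(resid**2))
    sst = float(np.sum((emg - emg.mean(axis=1, keepdims=True)) ** 2))
    if sst == 0:
        raise UndefinedMetricError("VAF undefined: data has zero variance about row means")
    return 1.0 - sse / sst


def vaf_per_muscle(emg: np.ndarray, W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Per-row VAF; NaN for rows with zero variance about their mean."""
    emg = np.asarray(emg, dtype=float)
    resid = emg - W @ P
    sse = np.sum(resid**2, axis=1)
    sst = np.sum((emg - emg.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - sse / sst
    out[sst == 0] = np.nan
    return out


def extract_synergies(
    tensor: EnvelopeTensor | np.ndarray,
    n: int,
    seed: int = 0,
    restarts: int = 10,
) -> SynergyDecomposition:
    """Factorize normalized envelopes into ``n`` motor modules.

    Runs ``restarts`` random-initialized multiplicative-update factorizations
    (squared-error objective, max 1000 iterations, relative tolerance 1e-6)
    and keeps the one with the lowest root-mean-squared reconstruction error.
    Deterministic for a fixed ``seed``. For reporting, each pattern is scaled
    to unit maximum with the inverse scale absorbed into the weights, so
    weights are comparable across subjects.
    """
    mat, n_phase, names = _as_matrix(tensor)
    m = mat.shape[0]
    if np.any(mat < 0):
        raise PreconditionError("envelope matrix must be non-negative")
    if not 1 <= n <= m:
        raise ParameterError(f"module count {n} outside 1..{m}")
    if restarts < 1:
        raise ParameterError("restarts must be >= 1")

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=restarts)
    best = None
    restart_rmse = np.empty(restarts)
    for i, s in enumerate(sub_seeds):
        model = NMF(
            n_components=n,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=NMF_MAX_ITER,
            tol=NMF_TOL,
            random_state=int(s),
        )
        with warnings.catch_warnings():
            # hitting the iteration cap is acceptable; best-of-restarts decides
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(mat)
        P = model.components_
        rmse = float(np.sqrt(np.mean((mat - W @ P) ** 2)))
        restart_rmse[i] = rmse
        if best is None or rmse < best[0]:
            best = (rmse, W, P)
    rmse, W, P = best

    # unit-maximum patterns; inverse scale into W
    scale = P.max(axis=1)
    scale[scale == 0] = 1.0
    P = P / scale[:, None]
    W = W * scale[None, :]

    return SynergyDecomposition(
        W=W,
        P=P,
        n_modules=n,
        n_phase=n_phase,
        vaf_total=compute_vaf(mat, W, P),
        vaf_per_muscle=vaf_per_muscle(mat, W, P),
        rmse=rmse,
        restart_rmse=restart_rmse,
        muscle_names=names,
    )


def vaf_curve(
    tensor: EnvelopeTensor | np.ndarray,
    n_max: int = 8,
    seed: int = 0,
    restarts: int = 3,
) -> np.ndarray:
    """VAF(n) for n = 1..min(n_max, m), shared seed policy across n."""
    mat, _, _ = _as_matrix(tensor)
    n_max = min(n_max, mat.shape[0])
    return np.array(
        [extract_synergies(mat, n, seed=seed, restarts=restarts).vaf_total
         for n in range(1, n_max + 1)]
    )


def best_linear_fit_n(vafs: np.ndarray, mse_threshold: float = 1e-4) -> int:
    """Smallest n whose tail of the VAF curve is linear.

    For each candidate n0, a least-squares line is fitted to the points
    {(k, VAF(k)) : k = n0..n_max}; the smallest n0 whose residual mean
    square falls below ``mse_threshold`` wins. The single-point fit at
    n0 = n_max has zero residual by construction and is the fallback.
    """
    vafs = np.asarray(vafs, dtype=float)
    n_max = vafs.size
    for n0 in range(1, n_max + 1):
        ks = np.arange(n0, n_max + 1)
        ys = vafs[n0 - 1 :]
        if ks.size <= 2:
            return n0
        coef = np.polyfit(ks, ys, 1)
        resid = ys - np.polyval(coef, ks)
        if np.mean(resid**2) < mse_threshold:
            return n0
    return n_max


def select_module_number(
    tensor: EnvelopeTensor | np.ndarray,
    method: str = "best_linear_fit",
    *,
    vaf_threshold: float = 0.90,
    fixed_n: int = 4,
    n_max: int = 8,
    seed: int = 0,
    restarts: int = 3,
) -> int:
    """Choose the number of motor modules.

    ``best_linear_fit``: smallest n such that a line fitted to the VAF vs n
    curve from n upward has residual mean square < 1e-4. ``vaf_threshold``:
    smallest n with VAF >= threshold (falls back to the largest tested n
    with a warning if none qualifies). ``fixed``: the configured n.
    """
    if method == "fixed":
        return fixed_n
    vafs = vaf_curve(tensor, n_max=n_max, seed=seed, restarts=restarts)
    if method == "vaf_threshold":
        above = np.nonzero(vafs >= vaf_threshold)[0]
        if above.size == 0:
            import warnings

            warnings.warn(
                f"no n reaches VAF {vaf_threshold}; returning n_max={vafs.size}",
                stacklevel=2,
            )
            return vafs.size
        return int(above[0]) + 1
    if method == "best_linear_fit":
        return best_linear_fit_n(vafs)
    raise ParameterError(f"unknown module-number method {method!r}")


def compute_fwhm(pattern: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Full width at half maximum of a cyclic pattern, in % of the cycle.

    Counts the samples strictly above half of the pattern maximum; multiple
    bursts contribute the sum of their widths. Also returns the contiguous
    above-half-max runs as (start, stop) index pairs for diagnostics
    (stop exclusive; runs are reported on the linear index, so a burst
    wrapping the cycle boundary appears as two runs).
    """
    p = np.asarray(pattern, dtype=float)
    if p.ndim != 1:
        raise ParameterError("pattern must be 1-D")
    peak = p.max()
    if peak <= 0:
        raise UndefinedMetricError("FWHM undefined for a non-positive pattern")
    above = p > peak / 2
    width = 100.0 * above.sum() / p.size
    runs: list[tuple[int, int]] = []
    i = 0
    while i < p.size:
        if above[i]:
            j = i
            while j + 1 < p.size and above[j + 1]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return width, runs


def compute_coa(pattern: np.ndarray, *, rel_tol: float = 1e-9) -> tuple[float | None, bool]:
    """Center of activity of a cyclic pattern, in % of the cycle.

    Each phase sample t (1-based) sits at angle theta_t = 2*pi*(t-1)/T on the
    cycle circle; the CoA is the four-quadrant angle of the resultant
    (A, B) = (sum cos(theta)*p, sum sin(theta)*p), wrapped to [0, 2*pi) and
    reported as 100*angle/(2*pi). When the resultant is negligible relative
    to the total activation (uniform pattern), the CoA is undefined and
    ``(None, False)`` is returned.
    """
    p = np.asarray(pattern, dtype=float)
    if p.ndim != 1:
        raise ParameterError("pattern must be 1-D")
    if np.any(p < 0):
        raise PreconditionError("pattern must be non-negative")
    theta = 2 * np.pi * np.arange(p.size) / p.size
    a = float(np.sum(np.cos(theta) * p))
    b = float(np.sum(np.sin(theta) * p))
    if np.hypot(a, b) < rel_tol * max(p.sum(), 1e-300):
        return None, False
    angle = np.arctan2(b, a) % (2 * np.pi)
    return float(100.0 * angle / (2 * np.pi)), True
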
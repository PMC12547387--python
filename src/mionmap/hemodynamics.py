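"""Contrast-agent hemodynamics and GLM design-matrix construction.

MION (a blood-pool iron-oxide contrast agent) makes neural activation appear
as a signal *decrease*: increased cerebral blood volume brings more agent
into the voxel and shortens T2*.  The impulse response used to predict the
measured signal from stimulus timing therefore has a reversed sign, a long
tail and no post-stimulus undershoot.  We model it as a sign-flipped
gamma-variate kernel

    h(t) = -c * (t / theta)**(k - 1) * exp(-t / theta),   t >= 0,

whose single extremum sits at t = (k - 1) * theta.  The functional form
cannot produce an undershoot or a positive lobe, which is exactly the
qualitative constraint the agent imposes.

Because the sign reversal is baked into the kernel, regression coefficients
and t statistics downstream come out in *neural* polarity: a positive
coefficient means a stronger neural response, even though the raw intensity
went down.

Task regressors are built on a fine time grid (default 10 ms, comfortably
below the 50 ms inter-stimulus interval of the protocol) and then evaluated
at the non-uniform acquisition timestamps of the clustered sparse-sampling
schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "ResponseFunction",
    "DesignMatrix",
    "mion_rf",
    "build_task_regressors",
    "assemble_design_matrix",
]


@dataclass(frozen=True)
class ResponseFunction:
    """Sampled impulse response of the contrast-agent hemodynamics.

    Attributes
    ----------
    k, theta_s : gamma shape (dimensionless, > 1) and timescale (seconds).
    duration_s : length of the sampled support.
    step_s : sampling step of the kernel grid (<= 0.05 s).
    normalization : ``"unit-peak"`` (minimum of h is exactly -1) or
        ``"unit-area"`` (sum of h times step is -1).
    t, h : the sample grid and kernel values (h <= 0 everywhere).
    """

    k: float
    theta_s: float
    duration_s: float
    step_s: float
    normalization: str
    t: np.ndarray = field(repr=False)
    h: np.ndarray = field(repr=False)

    @property
    def peak_time_s(self) -> float:
        """Location of the (single) extremum, (k - 1) * theta."""
        return (self.k - 1.0) * self.theta_s


def mion_rf(
    k: float = 3.0,
    theta_s: float = 4.0,
    duration_s: float = 60.0,
    normalization: str = "unit-peak",
    step_s: float = 0.01,
) -> ResponseFunction:
    """Build the reversed-sign gamma-variate response function.

    Parameters follow the package defaults (k=3, theta=4 s, 60 s support)
    chosen to give a ~8 s time-to-peak and a long tail; they are conventions,
    not a reconstruction of any particular scanner's response.
    """
    if not k > 1:
        raise ValueError(f"shape parameter k must be > 1, got {k}")
    if not theta_s > 0:
        raise ValueError(f"timescale theta_s must be > 0, got {theta_s}")
    if not step_s > 0 or step_s > 0.05:
        raise ValueError(f"step_s must be in (0, 0.05], got {step_s}")
    if duration_s < 5.0 * (k - 1.0) * theta_s:
        raise ValueError(
            "duration_s must cover at least 5 peak times "
            f"(>= {5.0 * (k - 1.0) * theta_s:g} s), got {duration_s}"
        )
    if normalization not in ("unit-peak", "unit-area"):
        raise ValueError(f"unknown normalization {normalization!r}")

    t = np.arange(0.0, duration_s + 0.5 * step_s, step_s)
    x = t / theta_s
    base = np.power(x, k - 1.0) * np.exp(-x)
    if normalization == "unit-peak":
        # analytic peak value of the unnormalized kernel, at t = (k-1)*theta
        peak = (k - 1.0) ** (k - 1.0) * np.exp(-(k - 1.0))
        c = 1.0 / peak
    else:
        # integral over [0, inf) of (t/theta)^(k-1) exp(-t/theta) dt = theta * Gamma(k)
        c = 1.0 / (theta_s * _gamma(k))
    h = -c * base
    return ResponseFunction(
        k=float(k),
        theta_s=float(theta_s),
        duration_s=float(duration_s),
        step_s=float(step_s),
        normalization=normalization,
        t=t,
        h=h,
    )


def _gamma(k: float) -> float:
    from scipy.special import gamma

    return float(gamma(k))


def _rf_on_grid(rf: ResponseFunction, step_s: float) -> np.ndarray:
    """Kernel samples on a grid with the requested step (interpolated)."""
    if abs(step_s - rf.step_s) < 1e-12:
        return rf.h
    t = np.arange(0.0, rf.duration_s + 0.5 * step_s, step_s)
    return np.interp(t, rf.t, rf.h)


def build_task_regressors(
    design,
    rf: ResponseFunction,
    conditions: Sequence[str],
    label_map: Mapping[str, str] | None = None,
    step_s: float = 0.01,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Convolve condition boxcars with the response function and sample them
    at the acquired volume timestamps.

    Parameters
    ----------
    design : phantom_sim.RunDesign
        The timed block/acquisition schedule of one run.
    conditions : regressor names; either stimulus subcategories or main
        categories.  Silence is the implicit baseline and gets no column.
    label_map : optional mapping from block condition labels to regressor
        names (used to pool subcategory blocks into main-category columns).

    Returns
    -------
    values : (n_volumes, n_conditions) regressor matrix
    names : condition names, in input order
    timestamps : acquisition times of each volume (seconds)
    """
    timestamps = design.volume_times
    n_fine = int(np.ceil((design.run_duration_s + rf.duration_s) / step_s)) + 1
    grid_t = np.arange(n_fine) * step_s
    kernel = _rf_on_grid(rf, step_s)

    cols = np.zeros((timestamps.size, len(conditions)))
    cell_lo = (np.arange(n_fine) - 0.5) * step_s  # samples are cell centers
    for j, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        n_blocks = 0
        for blk in design.blocks:
            label = blk.condition
            if label == "silence":
                continue
            if label_map is not None:
                label = label_map.get(label, label)
            if label != cond:
                continue
            # coverage-weighted boxcar: fractional occupancy of each grid
            # cell, so block edges are resolved below the grid step
            lo, hi = blk.onset_s, blk.onset_s + blk.duration_s
            overlap = np.clip(
                np.minimum(hi, cell_lo + step_s) - np.maximum(lo, cell_lo), 0.0, step_s
            )
            box += overlap / step_s
            n_blocks += 1
        if n_blocks == 0:
            raise ValueError(f"condition {cond!r} has no blocks in this design")
        conv = np.convolve(box, kernel)[:n_fine] * step_s
        cols[:, j] = np.interp(timestamps, grid_t, conv)
    return cols, list(conditions), timestamps


@dataclass
class DesignMatrix:
    """GLM design matrix for one run: task, drift and nuisance columns.

    Rows are acquired volumes ordered by timestamp.  Drift columns are
    orthonormal polynomials in the (non-uniform) acquisition timestamps; the
    first drift column is the constant term, so silence needs no explicit
    baseline column.
    """

    matrix: np.ndarray
    names: list[str]
    kinds: list[str]  # "task" | "drift" | "nuisance", one per column
    timestamps: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def task_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "task"], dtype=int)

    @property
    def task_names(self) -> list[str]:
        return [n for n, k in zip(self.names, self.kinds) if k == "task"]

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "timestamp_s", self.timestamps)
        df.to_csv(path, sep="\t", index=False)


def _drift_basis(timestamps: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal polynomial drift basis (constant first), via QR."""
    t = np.asarray(timestamps, dtype=float)
    span = t[-1] - t[0]
    x = (2.0 * (t - t[0]) / span - 1.0) if span > 0 else np.zeros_like(t)
    V = np.vander(x, N=order + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    # fix signs so each column positively correlates with its monomial
    for j in range(Q.shape[1]):
        s = np.dot(Q[:, j], V[:, j])
        if s < 0:
            Q[:, j] = -Q[:, j]
    return Q


def assemble_design_matrix(
    task_values: np.ndarray,
    task_names: Sequence[str],
    timestamps: np.ndarray,
    drift_order: int = 3,
    nuisance: np.ndarray | None = None,
    nuisance_names: Sequence[str] | None = None,
) -> DesignMatrix:
    """Stack task, drift and nuisance columns into a full-rank design.

    Raises
    ------
    ValueError
        on shape mismatch, an all-zero task column, duplicated names, or a
        rank-deficient matrix (the error names the dependent columns).
    """
    task_values = np.atleast_2d(np.asarray(task_values, dtype=float))
    timestamps = np.asarray(timestamps, dtype=float)
    n = timestamps.size
    if task_values.shape[0] != n:
        raise ValueError(
            f"task columns have {task_values.shape[0]} rows, expected {n}"
        )
    if drift_order < 0:
        raise ValueError("drift_order must be >= 0")
    for j, name in enumerate(task_names):
        if not np.any(task_values[:, j]):
            raise ValueError(f"task column {name!r} is all zero")

    blocks = [task_values]
    names = list(task_names)
    kinds = ["task"] * len(task_names)

    drift = _drift_basis(timestamps, drift_order)
    blocks.append(drift)
    names += [f"drift_{d}" for d in range(drift_order + 1)]
    kinds += ["drift"] * (drift_order + 1)

    if nuisance is not None and np.size(nuisance):
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n:
            raise ValueError(
                f"nuisance columns have {nuisance.shape[0]} rows, expected {n}"
            )
        if nuisance_names is None:
            nuisance_names = [f"nuisance_{j}" for j in range(nuisance.shape[1])]
        blocks.append(nuisance)
        names += list(nuisance_names)
        kinds += ["nuisance"] * nuisance.shape[1]

    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate column names: {dupes}")

    X = np.hstack(blocks)
    # pivoted QR exposes (near-)dependent columns by tiny |R| diagonal
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad or X.shape[1] > n:
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")
    return DesignMatrix(matrix=X, names=names, kinds=kinds, timestamps=timestamps)
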
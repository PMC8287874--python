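"""Univariate block-design GLM.

Builds per-run design matrices — three condition boxcars convolved with a
two-gamma hemodynamic response function (HRF), six motion nuisance
regressors and a constant — fits ordinary least squares per voxel or on an
ROI-mean time course, and reports condition beta weights in percent signal
change (100 * beta / constant-term beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HrfParams",
    "DesignMatrix",
    "BetaEstimates",
    "two_gamma_hrf",
    "condition_boxcars",
    "build_design",
    "fit_glm",
    "roi_contrast",
    "dct_highpass_set",
]

CONDITIONS = ("upright", "inverted", "random")


@dataclass(frozen=True)
class HrfParams:
    """Canonical two-gamma HRF: positive peak lobe minus a late undershoot.

    Defaults: peak at 6 s, undershoot at 16 s, unit dispersions,
    peak:undershoot amplitude ratio 6, 32 s support.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("delays must be positive")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.peak_undershoot_ratio <= 0:
            raise ValueError("peak:undershoot ratio must be positive")


def two_gamma_hrf(params: HrfParams = HrfParams(), tr_s: float = 2.0,
                  oversample: int = 1) -> np.ndarray:
    """Sample the two-gamma HRF kernel at the TR, normalized to unit peak.

    Each lobe is a gamma density with mode at its delay (shape =
    delay/dispersion + 1, scale = dispersion); the undershoot is scaled by
    1/ratio and subtracted.  The kernel is zero at t = 0.
    """
    if tr_s <= 0:
        raise ValueError("tr must be positive")
    dt = tr_s / oversample
    t = np.arange(0.0, params.duration_s + dt / 2, dt)
    peak = gamma_dist.pdf(t, params.peak_delay_s / params.peak_dispersion + 1.0,
                          scale=params.peak_dispersion)
    under = gamma_dist.pdf(t, params.undershoot_delay_s / params.undershoot_dispersion + 1.0,
                           scale=params.undershoot_dispersion)
    h = peak - under / params.peak_undershoot_ratio
    return h / h.max()


@dataclass
class DesignMatrix:
    """Design matrix with labelled columns (3 condition + 6 motion + constant)."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("matrix/label shape mismatch")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def condition_boxcars(block_onsets: dict[str, list[float]], block_duration_s: float,
                      n_volumes: int, tr_s: float = 2.0,
                      conditions: tuple[str, ...] = CONDITIONS) -> np.ndarray:
    """Volume-sampled 0/1 boxcars, one column per condition (genders pooled)."""
    t = np.arange(n_volumes) * tr_s
    box = np.zeros((n_volumes, len(conditions)))
    for j, cond in enumerate(conditions):
        for onset in block_onsets.get(cond, []):
            box[(t >= onset) & (t < onset + block_duration_s), j] = 1.0
    return box


def build_design(block_onsets: dict[str, list[float]], motion: np.ndarray,
                 n_volumes: int, tr_s: float = 2.0,
                 hrf: HrfParams = HrfParams(), block_duration_s: float = 16.0,
                 conditions: tuple[str, ...] = CONDITIONS,
                 highpass_cycles: int | None = None) -> DesignMatrix:
    """Assemble the run design matrix.

    Condition regressors are 16-s boxcars convolved with the two-gamma HRF
    and truncated to the run length; motion regressors are appended as
    provided; the final column is the constant.  Optionally appends a
    discrete-cosine high-pass nuisance set (up to ``highpass_cycles``
    cycles per run) instead of pre-filtering the data.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise ValueError(f"motion must be ({n_volumes}, 6), got {motion.shape}")
    box = condition_boxcars(block_onsets, block_duration_s, n_volumes, tr_s, conditions)
    kernel = two_gamma_hrf(hrf, tr_s)
    conv = np.column_stack([
        np.convolve(box[:, j], kernel)[:n_volumes] for j in range(box.shape[1])
    ])
    cols = [conv, motion]
    labels = list(conditions) + [f"motion_{k}" for k in range(6)]
    if highpass_cycles:
        cols.append(dct_highpass_set(n_volumes, highpass_cycles))
        labels += [f"dct_{k}" for k in range(1, highpass_cycles + 1)]
    cols.append(np.ones((n_volumes, 1)))
    labels.append("constant")
    return DesignMatrix(matrix=np.hstack(cols), labels=labels)


def dct_highpass_set(n_volumes: int, n_cycles: int) -> np.ndarray:
    """Discrete-cosine nuisance regressors for cycles 1..n_cycles per run."""
    t = np.arange(n_volumes)
    return np.column_stack([
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, n_cycles + 1)
    ])


@dataclass
class BetaEstimates:
    """OLS solution: beta per design column per voxel, plus residual variance."""

    beta: np.ndarray  # (n_columns, n_voxels)
    labels: list[str]
    residual_variance: np.ndarray  # (n_voxels,)
    dof: int

    def for_column(self, label: str) -> np.ndarray:
        return self.beta[self.labels.index(label)]

    def percent_signal_change(self, conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
        """100 * condition beta / constant beta, per voxel."""
        const = self.for_column("constant")
        if np.any(const == 0):
            raise ZeroDivisionError("constant-term beta is zero for some voxel")
        return pd.DataFrame({c: 100.0 * self.for_column(c) / const for c in conditions})


def fit_glm(signals: np.ndarray, design: DesignMatrix) -> BetaEstimates:
    """Ordinary least squares fit of each voxel time course on the design.

    Raises on row mismatch or rank deficiency; the error names the
    collinear columns.
    """
    y = np.asarray(signals, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"signals have {y.shape[0]} rows, design has {x.shape[0]}")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        dependent = [design.labels[i] for i in np.flatnonzero(
            np.abs(np.diag(r)) < 1e-10 * np.abs(np.diag(r)).max())]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {dependent or 'undetermined'}")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = y.shape[0] - x.shape[1]
    resvar = (resid ** 2).sum(axis=0) / max(dof, 1)
    return BetaEstimates(beta=beta, labels=list(design.labels),
                         residual_variance=resvar, dof=dof)


def roi_contrast(signals: np.ndarray, design: DesignMatrix,
                 roi_groups: dict[str, np.ndarray],
                 conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Per-ROI condition betas in percent signal change.

    Each ROI's voxel time courses are averaged into one time course first
    and that mean course is fitted, rather than averaging voxelwise fits.
    Returns a tidy frame (roi, condition, beta_psc).
    """
    rows = []
    for roi, voxels in roi_groups.items():
        voxels = np.asarray(voxels)
        if voxels.size == 0:
            raise ValueError(f"ROI {roi!r} is empty")
        mean_course = np.asarray(signals, dtype=float)[:, voxels].mean(axis=1)
        est = fit_glm(mean_course, design)
        psc = est.percent_signal_change(conditions)
        for cond in conditions:
            rows.append({"roi": roi, "condition": cond,
                         "beta_psc": float(psc[cond].iloc[0])})
    return pd.DataFrame(rows)
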
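"""Region time-course extraction and trial-window preparation.

Each region's voxel x time matrix is reduced to a single representative
course — the first principal component of the time-indexed voxel data —
sign-anchored to the across-voxel mean so that downstream correlations are
well defined.  The stimulation design (boxcar plus temporal derivative) is
regressed out of the whole-session course, and per-trial plateau windows
(default: the final 15 volumes of each stimulation period, ~30 s at
TR 1.96 s) are cut for the connectivity stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def plateau_samples(window_s: float = 30.0, tr: float = 1.96) -> int:
    """Number of whole volumes inside the final ``window_s`` seconds.

    With the default TR of 1.96 s, a 30 s plateau holds exactly 15 volumes.
    """
    return int(math.floor(window_s / tr + 1e-9))


def stimulation_samples(duration_s: float = 40.0, tr: float = 1.96) -> int:
    """Whole volumes covered by a stimulation period (default 40 s -> 20)."""
    return int(round(duration_s / tr))


# ---------------------------------------------------------------------------
# first principal component per region
# ---------------------------------------------------------------------------


def extract_first_component(voxel_matrix: np.ndarray) -> np.ndarray:
    """First principal-component score series of a voxel x time matrix.

    Voxels are the variables, time points the observations; voxel courses
    are demeaned over time (no variance normalization).  The returned score
    series has unit sample variance and is sign-fixed so that its
    correlation with the across-voxel mean course is nonnegative.
    """
    X = np.asarray(voxel_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D voxel x time matrix")
    n_vox, n_t = X.shape
    if n_vox < 2 or n_t < 3:
        raise ValueError("need >= 2 voxels and >= 3 time points")
    if not np.all(np.isfinite(X)):
        raise ValueError("voxel matrix contains non-finite values")
    Xc = X - X.mean(axis=1, keepdims=True)
    # SVD of (time x voxel): left singular vectors are component scores
    U, s, _ = np.linalg.svd(Xc.T, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise ValueError("degenerate region: constant voxel matrix")
    scores = U[:, 0] * s[0]
    anchor = Xc.mean(axis=0)
    if scores @ anchor < 0:
        scores = -scores
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate region: zero-variance component")
    return scores / sd


# ---------------------------------------------------------------------------
# stimulation design matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignMatrix:
    """Stimulation regressors sharing the session time axis."""

    matrix: np.ndarray            # (T, k)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def build_design(
    onsets: np.ndarray,
    session_len: int,
    plateau_len: int = 15,
    stim_samples: int | None = None,
    tr: float = 1.96,
    stim_duration_s: float = 40.0,
) -> DesignMatrix:
    """Boxcar + temporal-derivative design for the stimulation periods.

    ``onsets`` are plateau-onset samples (one per trial); each stimulation
    period is taken to *end* with its plateau, i.e. it covers the
    ``stim_samples`` samples up to and including the last plateau sample.
    Columns: stimulation boxcar, its first temporal difference, intercept —
    returned unnormalized.
    """
    if stim_samples is None:
        stim_samples = stimulation_samples(stim_duration_s, tr)
    if stim_samples < plateau_len:
        raise ValueError("stimulation period shorter than plateau window")
    onsets = np.asarray(onsets, dtype=int)
    box = np.zeros(session_len)
    covered = np.zeros(session_len, dtype=bool)
    for onset in onsets:
        end = onset + plateau_len          # exclusive
        start = end - stim_samples
        if start < 0 or end > session_len:
            raise ValueError(
                f"stimulation period [{start}, {end}) outside session "
                f"of length {session_len}"
            )
        if covered[start:end].any():
            raise ValueError("overlapping stimulation periods")
        covered[start:end] = True
        box[start:end] = 1.0
    deriv = np.diff(box, prepend=0.0)
    mat = np.column_stack([box, deriv, np.ones(session_len)])
    return DesignMatrix(matrix=mat, names=("stim", "stim_derivative", "intercept"))


def residualize(course: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Remove the least-squares projection of ``course`` onto the design.

    The residual is orthogonal to every design column (checked to 1e-8
    relative tolerance).
    """
    y = np.asarray(course, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("course and design have different time axes")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    resid = y - X @ beta
    scale = max(np.linalg.norm(y), 1.0)
    dots = X.T @ resid
    if np.any(np.abs(dots) > 1e-8 * scale * np.linalg.norm(X, axis=0).max()):
        raise AssertionError("residual not orthogonal to design")
    return resid


# ---------------------------------------------------------------------------
# trial windows
# ---------------------------------------------------------------------------


def cut_windows(
    course: np.ndarray, trials: pd.DataFrame, plateau_len: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial plateau values in acquisition order.

    Returns ``(windows, indices)`` with shapes (n_trials, plateau_len);
    ``indices`` holds the sample indices of each window.  Raises if any
    trial's window extends past the session end, naming the trial.
    """
    y = np.asarray(course, dtype=float)
    onsets = trials["onset_sample"].to_numpy(dtype=int)
    n = len(onsets)
    windows = np.empty((n, plateau_len))
    indices = np.empty((n, plateau_len), dtype=int)
    used = np.zeros(y.shape[0], dtype=bool)
    for k, onset in enumerate(onsets):
        end = onset + plateau_len
        if onset < 0 or end > y.shape[0]:
            label = trials.iloc[k].get("trial", k)
            raise ValueError(
                f"trial {label!r}: plateau window [{onset}, {end}) outside "
                f"session of length {y.shape[0]}"
            )
        if used[onset:end].any():
            label = trials.iloc[k].get("trial", k)
            raise ValueError(f"trial {label!r}: plateau window overlaps another")
        used[onset:end] = True
        windows[k] = y[onset:end]
        indices[k] = np.arange(onset, end)
    return windows, indices


def extract_all(
    voxel_data: dict[tuple[str, str], np.ndarray],
    regions: list[str],
    trials: pd.DataFrame,
    session_len: int,
    plateau_len: int = 15,
    tr: float = 1.96,
    stim_duration_s: float = 40.0,
    regress_design: bool = True,
) -> dict[str, np.ndarray]:
    """Voxel matrices -> residualized region-course matrices per subject.

    ``voxel_data`` maps (subject, region) -> voxel x time matrix.  Returns
    subject -> (R, T) course matrices in ``regions`` order, PCA-reduced and
    (optionally) residualized against that subject's stimulation design.
    """
    subjects = sorted({s for s, _ in voxel_data})
    out: dict[str, np.ndarray] = {}
    for subject in subjects:
        sub_trials = trials[trials["subject"] == subject]
        design = build_design(
            sub_trials["onset_sample"].to_numpy(),
            session_len,
            plateau_len=plateau_len,
            tr=tr,
            stim_duration_s=stim_duration_s,
        )
        mat = np.empty((len(regions), session_len))
        for r, region in enumerate(regions):
            key = (subject, region)
            if key not in voxel_data:
                raise KeyError(f"missing voxel data for subject {subject!r}, region {region!r}")
            course = extract_first_component(voxel_data[key])
            if regress_design:
                course = residualize(course, design)
            mat[r] = course
        out[subject] = mat
    return out
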
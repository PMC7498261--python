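"""Per-trial edge connectivity: Grubbs outlier rejection, Pearson r, Fisher Z.

Each trial contributes one plateau window (default 15 samples) per region.
Within a window each region's samples are screened with an iterative
two-sided Grubbs test; every unordered region pair is then correlated over
the intersection of both regions' retained samples, and the correlation is
variance-stabilized with the Fisher Z transform ``z = atanh(r)``.

For R regions there are R(R-1)/2 unordered pairs; the canonical enumeration
(lexicographic in atlas order) fixes the layout of every downstream edge
vector and square matrix.  R = 371 gives 68 635 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ParcelAtlas

R_CLAMP = 1.0 - 1e-7  # keeps atanh finite for degenerate |r| = 1 windows


# ---------------------------------------------------------------------------
# edge enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical enumeration of unordered distinct region pairs."""

    regions: tuple[str, ...]

    @classmethod
    def from_atlas(cls, atlas: ParcelAtlas) -> "EdgeIndex":
        return cls(tuple(atlas.regions))

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        r = len(self.regions)
        return r * (r - 1) // 2

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.regions, 2))

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer region indices (i, j) per edge, i < j."""
        r = len(self.regions)
        iu = np.triu_indices(r, k=1)
        return iu[0], iu[1]

    def index_of(self, region_a: str, region_b: str) -> int:
        """Position of the unordered pair in the canonical enumeration."""
        ia = self.regions.index(region_a)
        ib = self.regions.index(region_b)
        if ia == ib:
            raise ValueError(f"self-pair {region_a!r}")
        i, j = sorted((ia, ib))
        r = len(self.regions)
        # edges preceding row i plus offset within row i
        return i * r - i * (i + 1) // 2 + (j - i - 1)

    def to_frame(self) -> pd.DataFrame:
        i, j = self.pair_arrays()
        regions = np.asarray(self.regions)
        return pd.DataFrame({"region_a": regions[i], "region_b": regions[j]})


# ---------------------------------------------------------------------------
# Grubbs outlier rejection
# ---------------------------------------------------------------------------


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size ``n``.

    ``G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))`` with ``t`` the upper
    ``alpha/(2n)`` quantile of Student's t on ``n-2`` degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs filter; returns a boolean keep-mask.

    The single most extreme point (largest ``|x - mean| / sd``) is removed
    while its G statistic exceeds the critical value, re-testing the reduced
    sample, and never reducing the sample below three retained points.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample")
    keep = np.ones(x.size, dtype=bool)
    while keep.sum() > 3:
        xs = x[keep]
        sd = xs.std(ddof=1)
        if sd == 0:
            break
        resid = np.abs(xs - xs.mean())
        g = resid.max() / sd
        if g <= grubbs_critical(xs.size, alpha):
            break
        worst = np.flatnonzero(keep)[np.argmax(resid)]
        keep[worst] = False
    return keep


def _grubbs_mask_many(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Vectorized iterative Grubbs over many windows.

    ``values`` has shape (n_windows, window_len); returns a boolean mask of
    the same shape.  Semantics match :func:`grubbs_filter` applied per row,
    except that zero-variance rows are retained whole instead of raising
    (degenerate windows are handled downstream as missing edges).
    """
    x = np.asarray(values, dtype=float)
    n_win, L = x.shape
    keep = np.ones_like(x, dtype=bool)
    if L < 3:
        return keep
    # precompute critical values for every possible retained count
    crit = np.full(L + 1, np.inf)
    for n in range(3, L + 1):
        crit[n] = grubbs_critical(n, alpha)
    active = np.ones(n_win, dtype=bool)
    for _ in range(L - 3):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        xa = x[idx]
        ka = keep[idx]
        n_ret = ka.sum(axis=1)
        xm = np.where(ka, xa, 0.0)
        mean = xm.sum(axis=1) / n_ret
        dev = np.where(ka, xa - mean[:, None], 0.0)
        ss = (dev * dev).sum(axis=1)
        sd = np.sqrt(ss / np.maximum(n_ret - 1, 1))
        resid = np.where(ka, np.abs(dev), -np.inf)
        worst = np.argmax(resid, axis=1)
        gmax = resid[np.arange(len(idx)), worst]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(sd > 0, gmax / sd, 0.0)
        hit = (g > crit[n_ret]) & (n_ret > 3)
        if not hit.any():
            active[idx] = False
            continue
        rows = idx[hit]
        keep[rows, worst[hit]] = False
        active[idx[~hit]] = False
    return keep


# ---------------------------------------------------------------------------
# per-trial edge vectors
# ---------------------------------------------------------------------------


def _masked_pairwise_z(
    window: np.ndarray, mask: np.ndarray, min_samples: int
) -> np.ndarray:
    """Fisher-Z correlation matrix over pairwise-complete retained samples.

    ``window``: (R, L) values; ``mask``: (R, L) keep flags.  Returns an
    (R, R) matrix with NaN where the retained intersection is smaller than
    ``min_samples`` or a region is constant over the intersection.
    """
    B = mask.astype(float)
    X = np.where(mask, window, 0.0)
    N = B @ B.T
    Sa = X @ B.T          # sum of x_a over the (a, b) intersection
    Saa = (X * X) @ B.T   # sum of x_a^2 over the intersection
    Sab = X @ X.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = N * Sab - Sa * Sa.T
        var_a = N * Saa - Sa * Sa
        denom = var_a * var_a.T
        r = np.where(denom > 0, cov / np.sqrt(np.where(denom > 0, denom, 1.0)), np.nan)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z[N < min_samples] = np.nan
    return z


def trial_edge_z(
    window: np.ndarray,
    alpha: float = 0.05,
    min_samples: int = 10,
    filter_timepoints: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Edge vector for one trial.

    Parameters
    ----------
    window:
        (R, L) array of region values over the trial's plateau samples.
    alpha:
        Grubbs significance level for time-point screening.
    min_samples:
        Pairs whose retained-sample intersection falls below this are marked
        missing (NaN).  Must be >= 3.
    filter_timepoints:
        If False, skip Grubbs screening (all samples retained).

    Returns
    -------
    z : (E,) Fisher-Z values in canonical pair order (upper triangle).
    n_retained : (R,) retained sample counts per region.
    """
    if min_samples < 3:
        raise ValueError("min_samples must be >= 3")
    window = np.asarray(window, dtype=float)
    if filter_timepoints:
        mask = _grubbs_mask_many(window, alpha)
    else:
        mask = np.ones_like(window, dtype=bool)
    zmat = _masked_pairwise_z(window, mask, min_samples)
    iu = np.triu_indices(window.shape[0], k=1)
    return zmat[iu], mask.sum(axis=1)


# ---------------------------------------------------------------------------
# the edge tensor
# ---------------------------------------------------------------------------


@dataclass
class EdgeTensor:
    """Fisher-Z edge values for every (subject, trial) row.

    ``z`` has one row per trial-table row and one column per canonical edge;
    NaN marks missing edges.  ``n_retained`` records per-region retained
    sample counts after outlier screening.
    """

    z: np.ndarray                   # (n_rows, n_edges)
    n_retained: np.ndarray          # (n_rows, n_regions)
    trials: pd.DataFrame            # row-aligned trial table
    edge_index: EdgeIndex
    grubbs_alpha: float = 0.05
    min_samples: int = 10
    filter_mode: str = "timepoints"

    def __post_init__(self) -> None:
        if self.z.shape[0] != len(self.trials):
            raise ValueError("z rows must align with trial table")
        if self.z.shape[1] != self.edge_index.n_edges:
            raise ValueError("z columns must match edge enumeration")

    def to_long_frame(self) -> pd.DataFrame:
        """Long TSV layout: one row per (trial row, edge)."""
        pairs = self.edge_index.to_frame()
        n_rows, n_edges = self.z.shape
        base = self.trials.loc[
            self.trials.index.repeat(n_edges),
            ["subject", "condition", "trial"],
        ].reset_index(drop=True)
        base["region_a"] = np.tile(pairs["region_a"].to_numpy(), n_rows)
        base["region_b"] = np.tile(pairs["region_b"].to_numpy(), n_rows)
        base["z"] = self.z.ravel()
        return base


def build_edge_tensor(
    courses: dict[str, np.ndarray],
    trials: pd.DataFrame,
    atlas: ParcelAtlas,
    plateau_len: int = 15,
    grubbs_alpha: float = 0.05,
    min_samples: int = 10,
    filter_mode: str = "timepoints",
) -> EdgeTensor:
    """Assemble the full (subject, trial) x edge Fisher-Z tensor.

    Parameters
    ----------
    courses:
        Mapping subject -> (R, T) region-course matrix, region order equal to
        the atlas order.
    trials:
        Trial table with columns subject, condition, trial, onset_sample,
        rating; ``onset_sample`` is the first plateau sample of the trial.
    filter_mode:
        ``"timepoints"`` screens the plateau samples per region with the
        Grubbs test before correlating (default).  ``"coefficients"``
        computes unscreened correlations and instead Grubbs-screens each
        edge's Fisher-Z values across a subject's trials, masking outlier
        trials as missing.  ``"none"`` disables screening.
    """
    if filter_mode not in ("timepoints", "coefficients", "none"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    edge_index = EdgeIndex.from_atlas(atlas)
    n_regions = atlas.n_regions
    n_rows = len(trials)
    z = np.full((n_rows, edge_index.n_edges), np.nan)
    n_retained = np.zeros((n_rows, n_regions), dtype=int)

    trials = trials.reset_index(drop=True)
    for subject, sub in trials.groupby("subject", sort=False):
        if subject not in courses:
            raise KeyError(f"missing region courses for subject {subject!r}")
        mat = np.asarray(courses[subject], dtype=float)
        if mat.shape[0] != n_regions:
            raise ValueError(
                f"subject {subject!r}: courses have {mat.shape[0]} regions, "
                f"atlas has {n_regions}"
            )
        for row, onset in zip(sub.index, sub["onset_sample"].to_numpy()):
            onset = int(onset)
            if onset < 0 or onset + plateau_len > mat.shape[1]:
                raise ValueError(
                    f"subject {subject!r} trial row {row}: plateau window "
                    f"[{onset}, {onset + plateau_len}) outside session"
                )
            window = mat[:, onset : onset + plateau_len]
            z[row], n_retained[row] = trial_edge_z(
                window,
                alpha=grubbs_alpha,
                min_samples=min_samples,
                filter_timepoints=(filter_mode == "timepoints"),
            )

    if filter_mode == "coefficients":
        # screen each edge's z values across a subject's trials instead
        for _, sub in trials.groupby("subject", sort=False):
            rows = sub.index.to_numpy()
            block = z[rows]
            finite = np.isfinite(block)
            for e in range(block.shape[1]):
                col = block[:, e]
                ok = finite[:, e]
                if ok.sum() >= 3 and np.ptp(col[ok]) > 0:
                    keep = grubbs_filter(col[ok], grubbs_alpha)
                    bad = rows[ok][~keep]
                    z[bad, e] = np.nan

    return EdgeTensor(
        z=z,
        n_retained=n_retained,
        trials=trials,
        edge_index=edge_index,
        grubbs_alpha=grubbs_alpha,
        min_samples=min_samples,
        filter_mode=filter_mode,
    )
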
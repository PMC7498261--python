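"""Max-|t| permutation inference for family-wise error control.

Behavioural ratings are shuffled (within subject by default, preserving
each subject's rating level under the random-intercept structure), the
entire mass edge-wise analysis is refit, and the largest absolute t over
all fitted edges is recorded per repetition.  The resulting null
distribution of the maximum — right-skewed, as extreme-value distributions
are — yields FWER-corrected p-values

    p_edge = (1 + #{null max >= |t_obs|}) / (n_perms + 1)

(add-one smoothed, never exactly zero) and the alpha-level significance
threshold as the matching upper quantile of the null maxima.  The max is
taken over the edges actually fitted, identically in the observed and null
passes.

Each repetition draws its permutation from a seed spawned per repetition
off the master seed, so results are bit-identical regardless of how many
workers execute the repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .connectivity import EdgeTensor
from . import lmm

DEFAULT_N_PERMS = 5000


# ---------------------------------------------------------------------------
# rating shuffles
# ---------------------------------------------------------------------------


def _permute_vector(
    ratings: np.ndarray,
    subjects: np.ndarray,
    rng: np.random.Generator,
    mode: str = "within_subject",
) -> np.ndarray:
    out = ratings.copy()
    if mode == "global":
        return ratings[rng.permutation(len(ratings))]
    if mode != "within_subject":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    for subject in pd.unique(subjects):
        idx = np.flatnonzero(subjects == subject)
        out[idx] = ratings[idx[rng.permutation(len(idx))]]
    return out


def permute_ratings(
    trials: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    mode: str = "within_subject",
) -> pd.DataFrame:
    """Return a trial table with ratings permuted, all else unchanged.

    ``mode="within_subject"`` (default) permutes each subject's ratings
    across that subject's trials, all conditions pooled; ``mode="global"``
    permutes across the whole table.  Each subject must contribute at least
    2 trials.
    """
    counts = trials.groupby("subject").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"subjects with fewer than 2 trials: {bad}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = trials.copy()
    out["rating"] = _permute_vector(
        trials["rating"].to_numpy(dtype=float),
        trials["subject"].to_numpy(),
        rng,
        mode=mode,
    )
    return out


# ---------------------------------------------------------------------------
# null distribution of the maximum statistic
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Per-repetition maxima of |t| over the fitted edge set."""

    condition: str
    model: str
    max_abs_t: np.ndarray
    n_perms: int
    seed: int
    shuffle_mode: str = "within_subject"
    n_edges_fitted: int = 0

    def __post_init__(self) -> None:
        self.max_abs_t = np.asarray(self.max_abs_t, dtype=float)
        if len(self.max_abs_t) != self.n_perms:
            raise ValueError("max_abs_t length must equal n_perms")
        if not np.all(np.isfinite(self.max_abs_t)) or np.any(self.max_abs_t < 0):
            raise ValueError("null maxima must be finite and nonnegative")

    def threshold(self, alpha: float = 0.05) -> float:
        """Critical |t|: edges strictly above it are significant at alpha."""
        m = int(np.floor(alpha * (self.n_perms + 1))) - 1
        if m < 0:
            return np.inf
        return float(np.sort(self.max_abs_t)[::-1][m])

    def skewness(self) -> float:
        from scipy import stats

        return float(stats.skew(self.max_abs_t))


def _perm_matrix(
    ratings: np.ndarray,
    subjects: np.ndarray,
    seeds: list[np.random.SeedSequence],
    mode: str,
) -> np.ndarray:
    cols = [
        _permute_vector(ratings, subjects, np.random.default_rng(s), mode)
        for s in seeds
    ]
    return np.column_stack(cols)


def build_null(
    tensor: EdgeTensor,
    model: str = "M1",
    condition: str | None = None,
    unmodulated: str | None = None,
    structural: dict[str, np.ndarray] | None = None,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = 0,
    shuffle_mode: str = "within_subject",
    max_missing: float = 0.2,
    n_jobs: int = 1,
    chunk_size: int = 100,
) -> NullDistribution:
    """Shuffle ratings, refit the whole edge set, record max |t| per rep.

    Deterministic given ``seed``; the repetition seeds are spawned per
    repetition so the result is independent of ``n_jobs`` and
    ``chunk_size``.  M1/M3 run through the batched REML engine (all edges
    and a chunk of repetitions fitted simultaneously); M2 refits edge by
    edge and is intended for small edge sets.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_perms)
    chunks = [
        list(range(start, min(start + chunk_size, n_perms)))
        for start in range(0, n_perms, chunk_size)
    ]

    if model in ("M1", "M3"):
        problem = lmm.prepare_slope_mass(
            tensor,
            model=model,
            condition=condition,
            unmodulated=unmodulated,
            structural=structural,
            max_missing=max_missing,
        )
        n_fitted = int(problem.fitted_mask.sum())
        if n_fitted == 0:
            raise ValueError("no fittable edges")

        def run_chunk(idx: list[int]) -> np.ndarray:
            Y = _perm_matrix(
                problem.y, problem.subjects, [seeds[i] for i in idx], shuffle_mode
            )
            t = problem.fit_outcomes(Y)["tstat"]
            return np.nanmax(np.abs(t), axis=0)

    elif model == "M2":
        stats0 = lmm.mass_fit(
            tensor,
            model="M2",
            condition=condition,
            unmodulated=unmodulated,
            max_missing=max_missing,
        )
        n_fitted = int((~stats0["skipped"]).sum())
        if n_fitted == 0:
            raise ValueError("no fittable edges")
        trials = tensor.trials

        def run_chunk(idx: list[int]) -> np.ndarray:
            out = np.empty(len(idx))
            for k, i in enumerate(idx):
                rng = np.random.default_rng(seeds[i])
                shuffled = trials.copy()
                shuffled["rating"] = _permute_vector(
                    trials["rating"].to_numpy(dtype=float),
                    trials["subject"].to_numpy(),
                    rng,
                    shuffle_mode,
                )
                perm_tensor = replace(tensor, trials=shuffled)
                stats = lmm.mass_fit(
                    perm_tensor,
                    model="M2",
                    condition=condition,
                    unmodulated=unmodulated,
                    max_missing=max_missing,
                )
                out[k] = np.nanmax(np.abs(stats["t"].to_numpy()))
            return out

    else:
        raise ValueError(f"unknown model {model!r}")

    if n_jobs == 1:
        results = [run_chunk(c) for c in chunks]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(run_chunk)(c) for c in chunks)
    max_abs_t = np.concatenate(results)
    cond_label = condition if condition is not None else tensor.trials["condition"].iloc[0]
    return NullDistribution(
        condition=cond_label,
        model=model,
        max_abs_t=max_abs_t,
        n_perms=n_perms,
        seed=seed,
        shuffle_mode=shuffle_mode,
        n_edges_fitted=n_fitted,
    )


# ---------------------------------------------------------------------------
# corrected p-values and significance report
# ---------------------------------------------------------------------------


@dataclass
class SignificanceReport:
    """FWER-corrected edge-level significance at a given alpha."""

    edges: pd.DataFrame            # EdgeStats columns + p_corrected, significant
    threshold_t: float
    alpha: float
    n_perms: int
    model: str
    condition: str

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.edges.loc[self.edges["significant"]]


def corrected_pvalues(
    observed: pd.DataFrame,
    null: NullDistribution,
    alpha: float = 0.05,
) -> SignificanceReport:
    """Attach max-statistic corrected p-values to an EdgeStats table.

    For each edge, ``p = (1 + #{null max >= |t|}) / (n_perms + 1)``; an edge
    is significant iff ``p <= alpha``, equivalently iff ``|t|`` strictly
    exceeds the report's ``threshold_t`` (the matching upper quantile of the
    null maxima) — the two criteria agree by construction, ties resolved
    conservatively.
    """
    edges = observed.copy()
    sorted_null = np.sort(null.max_abs_t)
    t_abs = np.abs(edges["t"].to_numpy(dtype=float))
    n_ge = null.n_perms - np.searchsorted(sorted_null, t_abs, side="left")
    p = (1.0 + n_ge) / (null.n_perms + 1.0)
    p[~np.isfinite(t_abs)] = np.nan
    edges["p_corrected"] = p
    edges["significant"] = p <= alpha
    edges.loc[~np.isfinite(t_abs), "significant"] = False
    return SignificanceReport(
        edges=edges,
        threshold_t=null.threshold(alpha),
        alpha=alpha,
        n_perms=null.n_perms,
        model=null.model,
        condition=null.condition,
    )
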
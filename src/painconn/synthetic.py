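"""Synthetic multi-subject dataset generator for the connectivity pipeline.

Emulates the statistical structure the analysis assumes, without any image
data: ~20 subjects undergo four conditions (the first unmodulated) of 12
tonic-pain trials each; every trial has a 10 s rest and a 40 s stimulation
period sampled at TR 1.96 s, of which the final 15 volumes form the
analysis plateau.  Ratings live on a 0-100 visual-analogue scale in steps
of five.

Generative model
----------------
Region courses are unit-variance AR(1) noise sharing a compound-symmetric
baseline correlation.  Each trial carries a latent attenuation performance
``u ~ N(0, 1)``.  For every *planted* edge (a, b) the within-plateau
correlation is steered to ``r = tanh(z0 + gain * u)`` by mixing a fresh
shared signal into both regions with a trial-specific weight, so the
per-trial Pearson r is monotone in ``u``.  The pain rating of a trial is

    rating = condition_mean + subject_intercept
             + sum_coupled  beta  * z_std
             + sum_mediated gamma * w_subj * z_std
             + noise,

rounded to the rating step and clipped to [0, 100], where ``z_std`` is the
*realized* plateau Fisher-Z of the edge (standardized over the whole
dataset) — so planted slopes are in rating units per SD of Fisher-Z, the
scale on which the mass mixed-model fit estimates them — and ``w_subj`` is
the subject's standardized ``log(1 + streamline count)`` for that edge, so
subjects with more streamlines have a larger-magnitude functional slope.

Streamline-count matrices are symmetric, zero-diagonal, overdispersed
negative-binomial draws, resembling probabilistic-tractography output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import ParcelAtlas

DEFAULT_CONDITIONS = ("unmodulated", "counting", "safeplace", "reappraisal")

# Default planted effect sizes (rating units per SD of Fisher-Z):
# -8 for a group-level coupled edge, a strong single-edge effect on a
# 0-100 rating scale; 3.5 per SD of structural weight for mediated edges,
# a moderate interindividual modulation about half the group-level size —
# large enough for reliable detection at 20 subjects, small enough that a
# subject-permutation of streamline counts leaves no detectable effect.
DEFAULT_COUPLING_BETA = -8.0
DEFAULT_MEDIATION_COEF = 3.5


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the generator.

    Planted edges are (region_index_a, region_index_b, coefficient) triples;
    all planted edges must reference pairwise-distinct regions.  ``beta``
    for coupled edges and the mediation coefficient for mediated edges are
    in rating units per SD of Fisher-Z (the mediation coefficient per SD of
    Fisher-Z per SD of structural weight).
    """

    n_subjects: int = 20
    n_regions: int = 12
    n_voxels_per_region: int = 10
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    trials_per_condition: int = 12
    plateau_len: int = 15
    tr: float = 1.96
    stim_duration_s: float = 40.0
    rest_duration_s: float = 10.0
    coupled_edges: list = field(default_factory=list)
    mediated_edges: list = field(default_factory=list)
    condition_means: tuple[float, ...] | None = None   # default: 60, then 40s
    subject_intercept_sd: float = 10.0
    rating_noise_sd: float = 10.0
    rating_step: float = 5.0
    baseline_corr: float = 0.1
    ar1_coef: float = 0.3
    coupling_base_z: float = math.atanh(0.3)
    coupling_gain: float = 0.35
    activation_amp_mean: float = 0.5
    activation_amp_sd: float = 0.3
    voxel_noise_sd: float = 0.5
    streamline_mean: float = 300.0
    streamline_dispersion: float = 2.0
    seed: int = 0

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration_s / self.tr))

    @property
    def stim_samples(self) -> int:
        return int(round(self.stim_duration_s / self.tr))

    @property
    def trial_samples(self) -> int:
        return self.rest_samples + self.stim_samples

    @property
    def session_len(self) -> int:
        return len(self.conditions) * self.trials_per_condition * self.trial_samples

    @property
    def cond_means(self) -> tuple[float, ...]:
        if self.condition_means is not None:
            return tuple(self.condition_means)
        return (60.0,) + (40.0,) * (len(self.conditions) - 1)

    def planted_edges(self) -> list[tuple[int, int, float, str]]:
        out = [(a, b, coef, "coupled") for a, b, coef in self.coupled_edges]
        out += [(a, b, coef, "mediated") for a, b, coef in self.mediated_edges]
        return out

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_regions < 2:
            raise ValueError("need at least 2 subjects and 2 regions")
        if len(self.conditions) < 1 or self.trials_per_condition < 1:
            raise ValueError("need at least one condition with one trial")
        if len(self.cond_means) != len(self.conditions):
            raise ValueError("condition_means must match conditions")
        if self.plateau_len > self.stim_samples:
            raise ValueError("plateau longer than stimulation period")
        if not (0.0 <= self.baseline_corr < 1.0):
            raise ValueError("baseline_corr must be in [0, 1)")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must be in [0, 1)")
        sigma = self.baseline_correlation_matrix()
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "baseline correlation matrix is not positive definite "
                f"(baseline_corr={self.baseline_corr})"
            ) from err
        used: set[int] = set()
        for a, b, coef, kind in self.planted_edges():
            for r in (a, b):
                if not (0 <= int(r) < self.n_regions):
                    raise ValueError(f"{kind} edge references invalid region {r}")
            if a == b:
                raise ValueError(f"{kind} edge ({a}, {b}) is a self-pair")
            if a in used or b in used:
                raise ValueError(
                    "planted edges must reference pairwise-distinct regions"
                )
            used.update((int(a), int(b)))

    def baseline_correlation_matrix(self) -> np.ndarray:
        r = self.n_regions
        return (1.0 - self.baseline_corr) * np.eye(r) + self.baseline_corr * np.ones(
            (r, r)
        )


@dataclass
class SimOutput:
    """Generated dataset plus the ground truth that produced it."""

    config: SimConfig
    atlas: ParcelAtlas
    region_timeseries: dict[str, np.ndarray]      # subject -> (R, T)
    trial_table: pd.DataFrame
    structural_matrix: dict[str, np.ndarray]      # subject -> (R, R) int counts
    truth: dict

    @property
    def subjects(self) -> list[str]:
        return list(self.region_timeseries)


def session_layout(cfg: SimConfig) -> pd.DataFrame:
    """Per-trial layout (condition, trial, onset of the plateau window).

    Blocks follow ``cfg.conditions`` order; within a block trials are
    consecutive, each ``rest + stimulation`` samples long, and the plateau
    is the final ``plateau_len`` samples of the stimulation period.
    """
    rows = []
    pos = 0
    for cond in cfg.conditions:
        for trial in range(cfg.trials_per_condition):
            stim_end = pos + cfg.trial_samples          # exclusive
            onset = stim_end - cfg.plateau_len
            rows.append((cond, trial, onset))
            pos = stim_end
    return pd.DataFrame(rows, columns=["condition", "trial", "onset_sample"])


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], phi: float) -> np.ndarray:
    innov = rng.standard_normal(shape)
    if phi == 0.0:
        return innov
    out = lfilter([1.0], [1.0, -phi], innov * math.sqrt(1.0 - phi * phi), axis=-1)
    return out


def _planted_pair(
    rng: np.random.Generator, r_target: float, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fresh unit-variance signal pair with population correlation r_target.

    Both series are built from independent innovations plus a shared
    component with weight ``|r|`` (sign-flipped in the second series for
    negative targets), so the pair's correlation is ``r_target`` while the
    correlation of either series with everything else in the session is
    exactly zero — planted effects do not leak into adjacent edges.
    """
    aw = abs(r_target)
    shared = rng.standard_normal(length)
    e_a = rng.standard_normal(length)
    e_b = rng.standard_normal(length)
    x_a = math.sqrt(1.0 - aw) * e_a + math.sqrt(aw) * shared
    x_b = math.sqrt(1.0 - aw) * e_b + math.copysign(math.sqrt(aw), r_target) * shared
    return x_a, x_b


def simulate_dataset(cfg: SimConfig) -> SimOutput:
    """Generate region courses, ratings, and streamline counts.

    Deterministic given ``cfg.seed`` (bit-identical on re-run).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    atlas = ParcelAtlas.simple(cfg.n_regions)
    layout = session_layout(cfg)
    n_trials = len(layout)
    subjects = [f"s{i + 1:02d}" for i in range(cfg.n_subjects)]
    planted = cfg.planted_edges()
    chol = np.linalg.cholesky(cfg.baseline_correlation_matrix())

    stim_box = np.zeros(cfg.session_len)
    for onset in layout["onset_sample"]:
        end = int(onset) + cfg.plateau_len
        stim_box[end - cfg.stim_samples : end] = 1.0

    intercepts = rng.normal(0.0, cfg.subject_intercept_sd, size=cfg.n_subjects)
    courses: dict[str, np.ndarray] = {}
    u_all = np.empty((cfg.n_subjects, n_trials))
    z_real = np.empty((len(planted), cfg.n_subjects, n_trials))

    for s, subject in enumerate(subjects):
        base = chol @ _ar1_noise(rng, (cfg.n_regions, cfg.session_len), cfg.ar1_coef)
        u = rng.standard_normal(n_trials)
        u_all[s] = u
        for k, (a, b, _, _) in enumerate(planted):
            for tix, onset in enumerate(layout["onset_sample"]):
                sl = slice(int(onset), int(onset) + cfg.plateau_len)
                r_target = math.tanh(cfg.coupling_base_z + cfg.coupling_gain * u[tix])
                base[a, sl], base[b, sl] = _planted_pair(
                    rng, r_target, cfg.plateau_len
                )
        for k, (a, b, _, _) in enumerate(planted):
            for tix, onset in enumerate(layout["onset_sample"]):
                sl = slice(int(onset), int(onset) + cfg.plateau_len)
                r = np.corrcoef(base[a, sl], base[b, sl])[0, 1]
                z_real[k, s, tix] = math.atanh(max(min(r, 1 - 1e-7), -1 + 1e-7))
        amp = rng.normal(cfg.activation_amp_mean, cfg.activation_amp_sd, cfg.n_regions)
        courses[subject] = base + amp[:, None] * stim_box[None, :]

    # structural streamline counts: symmetric, zero diagonal, overdispersed
    structural: dict[str, np.ndarray] = {}
    k_disp = cfg.streamline_dispersion
    p_nb = k_disp / (k_disp + cfg.streamline_mean)
    iu = np.triu_indices(cfg.n_regions, k=1)
    for subject in subjects:
        upper = rng.negative_binomial(k_disp, p_nb, size=len(iu[0]))
        mat = np.zeros((cfg.n_regions, cfg.n_regions), dtype=int)
        mat[iu] = upper
        mat += mat.T
        structural[subject] = mat

    # standardized realized Fisher-Z per planted edge, over the whole dataset
    z_mean = z_real.reshape(len(planted), -1).mean(axis=1) if planted else np.empty(0)
    z_sd = z_real.reshape(len(planted), -1).std(axis=1) if planted else np.empty(0)

    struct_w = np.zeros((len(planted), cfg.n_subjects))
    for k, (a, b, _, kind) in enumerate(planted):
        if kind != "mediated":
            continue
        counts = np.array([structural[subj][a, b] for subj in subjects], dtype=float)
        logc = np.log1p(counts)
        sd = logc.std()
        if sd == 0:
            raise ValueError("degenerate streamline counts for mediated edge")
        struct_w[k] = (logc - logc.mean()) / sd

    cond_mean = dict(zip(cfg.conditions, cfg.cond_means))
    rows = []
    for s, subject in enumerate(subjects):
        noise = rng.normal(0.0, cfg.rating_noise_sd, n_trials)
        for tix, (cond, trial, onset) in enumerate(
            layout.itertuples(index=False, name=None)
        ):
            raw = cond_mean[cond] + intercepts[s] + noise[tix]
            for k, (a, b, coef, kind) in enumerate(planted):
                z_std = (z_real[k, s, tix] - z_mean[k]) / z_sd[k]
                if kind == "coupled":
                    raw += coef * z_std
                else:
                    raw += coef * struct_w[k, s] * z_std
            rating = float(
                np.clip(np.round(raw / cfg.rating_step) * cfg.rating_step, 0.0, 100.0)
            )
            rows.append((subject, cond, trial, int(onset), rating))
    trial_table = pd.DataFrame(
        rows, columns=["subject", "condition", "trial", "onset_sample", "rating"]
    )

    truth = {
        "subject_intercepts": dict(zip(subjects, intercepts)),
        "latent_performance": u_all,
        "condition_means": cond_mean,
        "planted_edges": [
            {
                "region_a": atlas.regions[a],
                "region_b": atlas.regions[b],
                "region_index_a": int(a),
                "region_index_b": int(b),
                "kind": kind,
                "coef": float(coef),
                "z_mean": float(z_mean[k]),
                "z_sd": float(z_sd[k]),
                "realized_z": z_real[k],
                "struct_weight": struct_w[k] if kind == "mediated" else None,
            }
            for k, (a, b, coef, kind) in enumerate(planted)
        ],
        "layout": layout,
        "session_len": cfg.session_len,
        "rest_samples": cfg.rest_samples,
        "stim_samples": cfg.stim_samples,
    }
    return SimOutput(
        config=cfg,
        atlas=atlas,
        region_timeseries=courses,
        trial_table=trial_table,
        structural_matrix=structural,
        truth=truth,
    )


def simulate_voxel_rois(
    cfg: SimConfig, region_timeseries: dict[str, np.ndarray]
) -> dict[tuple[str, str], np.ndarray]:
    """Expand region courses into voxel x time matrices.

    Each region's voxels are the region course scaled by random positive
    loadings plus independent Gaussian noise, so the first principal
    component recovers the region course up to sign and scale.
    """
    if cfg.n_voxels_per_region < 2:
        raise ValueError("need at least 2 voxels per region")
    rng = np.random.default_rng([cfg.seed, 0x5EED])
    atlas = ParcelAtlas.simple(cfg.n_regions)
    out: dict[tuple[str, str], np.ndarray] = {}
    for subject in sorted(region_timeseries):
        mat = region_timeseries[subject]
        for r, region in enumerate(atlas.regions):
            loadings = rng.uniform(0.5, 1.5, cfg.n_voxels_per_region)
            noise = rng.standard_normal((cfg.n_voxels_per_region, mat.shape[1]))
            out[(subject, region)] = (
                loadings[:, None] * mat[r][None, :] + cfg.voxel_noise_sd * noise
            )
    return out
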
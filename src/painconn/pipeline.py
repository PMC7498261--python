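"""End-to-end pipeline orchestration with reproducible configuration.

Stages (each resumable from the working directory):

1. simulate — generate a synthetic dataset (optional; real course/trial
   tables can be supplied instead),
2. extract  — regress the stimulation design out of each region course
   (optionally reducing voxel matrices to region courses first),
3. connect  — build the per-trial Fisher-Z edge tensor,
4. fit      — mass mixed-model edge statistics per condition,
5. permute  — max-|t| permutation null distributions,
6. report   — corrected significance, hub tables, summary JSON.

All randomness flows from one master seed through named substreams, so a
rerun with the same configuration is byte-identical regardless of worker
count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import io, lmm, report as report_mod
from .atlas import ParcelAtlas
from .connectivity import build_edge_tensor
from .extraction import build_design, extract_first_component, residualize
from .permutation import build_null, corrected_pvalues
from .synthetic import SimConfig, simulate_dataset, simulate_voxel_rois

log = logging.getLogger("painconn")


@dataclasses.dataclass
class PipelineConfig:
    """Flat configuration mirroring the pipeline stages."""

    seed: int = 0
    simulate: dict | None = None          # SimConfig fields, or None to load
    atlas_path: str | None = None
    courses_path: str | None = None
    trials_path: str | None = None
    structural_path: str | None = None
    from_voxels: bool = False
    regress_design: bool = True
    plateau_len: int = 15
    tr: float = 1.96
    stim_duration_s: float = 40.0
    grubbs_alpha: float = 0.05
    min_samples: int = 10
    filter_mode: str = "timepoints"
    models: tuple[str, ...] = ("M1",)
    conditions: tuple[str, ...] | None = None   # default: all but unmodulated
    unmodulated: str | None = None              # default: first condition
    n_perms: int = 5000
    alpha: float = 0.05
    shuffle_mode: str = "within_subject"
    mediation_t_threshold: float = 2.0
    min_degree: int = 3
    nps_analysis: bool = False
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("models", "conditions"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> SimConfig:
        fields = dict(self.simulate or {})
        fields.setdefault("seed", self.seed)
        for key in ("coupled_edges", "mediated_edges"):
            if key in fields:
                fields[key] = [tuple(e) for e in fields[key]]
        if "conditions" in fields:
            fields["conditions"] = tuple(fields["conditions"])
        if "condition_means" in fields and fields["condition_means"] is not None:
            fields["condition_means"] = tuple(fields["condition_means"])
        return SimConfig(**fields)

    def validate_inputs(self) -> None:
        """Fail fast on missing input files before any computation."""
        if self.simulate is not None:
            return
        for label, path in (
            ("atlas", self.atlas_path),
            ("courses", self.courses_path),
            ("trials", self.trials_path),
        ):
            if path is None:
                raise ValueError(f"{label} path required when simulate is disabled")
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.structural_path is not None and not Path(self.structural_path).exists():
            raise FileNotFoundError(
                f"structural directory not found: {self.structural_path}"
            )


def tensor_from_simulation(
    sim,
    regress_design: bool = True,
    grubbs_alpha: float = 0.05,
    min_samples: int = 10,
    filter_mode: str = "timepoints",
):
    """Simulated dataset -> edge tensor (residualize, window, correlate).

    Library-level shortcut through the extract and connect stages, used for
    calibration studies where no files need to hit disk.
    """
    cfg = sim.config
    courses: dict[str, np.ndarray] = {}
    for subject, mat in sim.region_timeseries.items():
        if regress_design:
            sub = sim.trial_table[sim.trial_table["subject"] == subject]
            design = build_design(
                sub["onset_sample"].to_numpy(),
                mat.shape[1],
                plateau_len=cfg.plateau_len,
                tr=cfg.tr,
                stim_duration_s=cfg.stim_duration_s,
            )
            mat = np.vstack([residualize(row, design) for row in mat])
        courses[subject] = mat
    return build_edge_tensor(
        courses,
        sim.trial_table,
        sim.atlas,
        plateau_len=cfg.plateau_len,
        grubbs_alpha=grubbs_alpha,
        min_samples=min_samples,
        filter_mode=filter_mode,
    )


def _substream_seed(master: int, *tags: int) -> int:
    """Deterministic child seed below 2**31 for a named substream."""
    ss = np.random.SeedSequence([int(master), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", stage, time.perf_counter() - self.t0)

    return _Timer()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, workdir: Path) -> None:
    if cfg.simulate is None:
        raise ValueError("config has no simulate section")
    with _timed("simulate"):
        sim = simulate_dataset(cfg.sim_config())
        sim.atlas.to_tsv(workdir / io.ATLAS_TSV)
        io.write_trials(sim.trial_table, workdir / io.TRIALS_TSV)
        io.write_courses(sim.region_timeseries, workdir / io.RAW_COURSES_NPZ)
        io.write_structural(sim.structural_matrix, sim.atlas, workdir / io.STRUCTURAL_DIR)
        truth = dict(sim.truth)
        truth["layout"] = sim.truth["layout"]
        io.write_json(truth, workdir / io.TRUTH_JSON)


def _load_inputs(cfg: PipelineConfig, workdir: Path):
    if cfg.simulate is not None:
        atlas = ParcelAtlas.from_tsv(workdir / io.ATLAS_TSV)
        trials = io.read_trials(workdir / io.TRIALS_TSV)
        courses = io.read_courses(workdir / io.RAW_COURSES_NPZ)
        structural_dir = workdir / io.STRUCTURAL_DIR
        structural = (
            io.read_structural(structural_dir) if structural_dir.exists() else None
        )
    else:
        cfg.validate_inputs()
        atlas = ParcelAtlas.from_tsv(cfg.atlas_path)
        trials = io.read_trials(cfg.trials_path)
        courses = io.read_courses(cfg.courses_path)
        structural = (
            io.read_structural(cfg.structural_path)
            if cfg.structural_path is not None
            else None
        )
    return atlas, trials, courses, structural


def stage_extract(cfg: PipelineConfig, workdir: Path) -> None:
    atlas, trials, courses, _ = _load_inputs(cfg, workdir)
    with _timed("extract"):
        if cfg.from_voxels:
            if cfg.simulate is None:
                raise ValueError("voxel-level input is only generated in simulation mode")
            voxels = simulate_voxel_rois(cfg.sim_config(), courses)
            courses = {
                subject: np.vstack(
                    [
                        extract_first_component(voxels[(subject, region)])
                        for region in atlas.regions
                    ]
                )
                for subject in courses
            }
        out: dict[str, np.ndarray] = {}
        for subject, mat in courses.items():
            sub_trials = trials[trials["subject"] == subject]
            if cfg.regress_design:
                design = build_design(
                    sub_trials["onset_sample"].to_numpy(),
                    mat.shape[1],
                    plateau_len=cfg.plateau_len,
                    tr=cfg.tr,
                    stim_duration_s=cfg.stim_duration_s,
                )
                mat = np.vstack([residualize(row, design) for row in mat])
            out[subject] = mat
        io.write_courses(out, workdir / io.COURSES_NPZ)


def stage_connect(cfg: PipelineConfig, workdir: Path) -> None:
    atlas, trials, _, _ = _load_inputs(cfg, workdir)
    courses = io.read_courses(workdir / io.COURSES_NPZ)
    with _timed("connect"):
        tensor = build_edge_tensor(
            courses,
            trials,
            atlas,
            plateau_len=cfg.plateau_len,
            grubbs_alpha=cfg.grubbs_alpha,
            min_samples=cfg.min_samples,
            filter_mode=cfg.filter_mode,
        )
        io.write_edge_tensor(tensor, workdir)


def _conditions(cfg: PipelineConfig, trials) -> tuple[str, list[str]]:
    unmod = cfg.unmodulated or trials["condition"].iloc[0]
    if cfg.conditions is not None:
        conds = list(cfg.conditions)
    else:
        conds = [c for c in trials["condition"].unique() if c != unmod]
    return unmod, conds


def stage_fit(cfg: PipelineConfig, workdir: Path) -> None:
    tensor = io.read_edge_tensor(workdir)
    _, _, _, structural = _load_inputs(cfg, workdir)
    unmod, conds = _conditions(cfg, tensor.trials)
    with _timed("fit"):
        for model in cfg.models:
            for cond in conds:
                stats = lmm.mass_fit(
                    tensor,
                    model=model,
                    condition=cond,
                    unmodulated=unmod,
                    structural=structural if model == "M3" else None,
                )
                io.write_edge_stats(stats, workdir / io.stats_name(model, cond))


def stage_permute(cfg: PipelineConfig, workdir: Path) -> None:
    tensor = io.read_edge_tensor(workdir)
    _, _, _, structural = _load_inputs(cfg, workdir)
    unmod, conds = _conditions(cfg, tensor.trials)
    with _timed("permute"):
        for mi, model in enumerate(cfg.models):
            for ci, cond in enumerate(conds):
                null = build_null(
                    tensor,
                    model=model,
                    condition=cond,
                    unmodulated=unmod,
                    structural=structural if model == "M3" else None,
                    n_perms=cfg.n_perms,
                    seed=_substream_seed(cfg.seed, 7, mi, ci),
                    shuffle_mode=cfg.shuffle_mode,
                    n_jobs=cfg.n_jobs,
                )
                io.write_null(null, workdir / io.null_name(model, cond))


def stage_report(cfg: PipelineConfig, workdir: Path) -> None:
    tensor = io.read_edge_tensor(workdir)
    atlas, trials, _, _ = _load_inputs(cfg, workdir)
    unmod, conds = _conditions(cfg, tensor.trials)
    summary: dict = {"alpha": cfg.alpha, "unmodulated": unmod, "conditions": {}}
    with _timed("report"):
        m1_reports = {}
        for model in cfg.models:
            for cond in conds:
                stats = io.read_edge_stats(workdir / io.stats_name(model, cond))
                null = io.read_null(workdir / io.null_name(model, cond))
                rep = corrected_pvalues(stats, null, alpha=cfg.alpha)
                io.write_report(rep, workdir / io.report_name(model, cond))
                report_mod.significance_matrix(rep).to_csv(
                    workdir / io.sigmatrix_name(model, cond), sep="\t"
                )
                hubs = report_mod.hub_regions(rep, min_degree=cfg.min_degree)
                hubs.to_csv(workdir / io.hubs_name(model, cond), sep="\t", index=False)
                counts = report_mod.count_significant(rep)
                cond_summary = summary["conditions"].setdefault(cond, {})
                cond_summary[model] = {
                    "counts": counts,
                    "threshold_t": rep.threshold_t,
                    "n_hubs": int(hubs["hub"].sum()),
                    "most_connected": (
                        hubs["region"].iloc[0] if len(hubs) else None
                    ),
                }
                if model == "M1":
                    m1_reports[cond] = rep
        if m1_reports:
            summary["hub_union"] = report_mod.cross_condition_union(
                m1_reports, min_degree=cfg.min_degree
            )
            summary["conjunction_count"] = len(
                report_mod.conjunction_edges(m1_reports)
            )
        if cfg.nps_analysis and atlas.nps_regions:
            summary["nps"] = {}
            for cond in conds:
                res = report_mod.nps_trial_analysis(tensor, atlas, cond, unmod)
                summary["nps"][cond] = {
                    "beta": res.beta,
                    "t": res.tstat,
                    "p_uncorrected": res.p_uncorrected,
                    "n_edges": res.n_edges,
                }
    io.write_json(summary, workdir / io.SUMMARY_JSON)


STAGES = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "connect": stage_connect,
    "fit": stage_fit,
    "permute": stage_permute,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, workdir) -> Path:
    """Execute every stage; returns the working directory.

    Writes a manifest with the configuration hash and seed so outputs are
    regenerable; reruns with the same configuration are byte-identical.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg.validate_inputs()
    cfg_dict = cfg.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "package": "painconn 0.1.0",
    }
    io.write_json(manifest, workdir / io.MANIFEST_JSON)
    stages = ["simulate"] if cfg.simulate is not None else []
    stages += ["extract", "connect", "fit", "permute", "report"]
    for name in stages:
        try:
            STAGES[name](cfg, workdir)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
    return workdir
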
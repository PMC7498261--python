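"""Serialization of pipeline artifacts.

Tables are tab-separated text with headers, array stacks are numpy ``.npz``
containers, metadata is JSON.  Filenames inside a pipeline working
directory are canonical so that each stage can locate its inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .connectivity import EdgeIndex, EdgeTensor
from .permutation import NullDistribution, SignificanceReport

TRIALS_TSV = "trials.tsv"
ATLAS_TSV = "atlas.tsv"
RAW_COURSES_NPZ = "courses_raw.npz"
COURSES_NPZ = "courses.npz"
STRUCTURAL_DIR = "structural"
TRUTH_JSON = "truth.json"
TENSOR_NPZ = "tensor.npz"
TENSOR_TRIALS_TSV = "tensor_trials.tsv"
TENSOR_META_JSON = "tensor_meta.json"
MANIFEST_JSON = "manifest.json"
SUMMARY_JSON = "summary.json"


def stats_name(model: str, condition: str) -> str:
    return f"stats_{model}_{condition}.tsv"


def null_name(model: str, condition: str) -> str:
    return f"null_{model}_{condition}.tsv"


def report_name(model: str, condition: str) -> str:
    return f"report_{model}_{condition}.tsv"


def sigmatrix_name(model: str, condition: str) -> str:
    return f"sigmatrix_{model}_{condition}.tsv"


def hubs_name(model: str, condition: str) -> str:
    return f"hubs_{model}_{condition}.tsv"


# -- trial table -------------------------------------------------------------


def write_trials(trials: pd.DataFrame, path) -> None:
    cols = ["subject", "condition", "trial", "onset_sample", "rating"]
    trials[cols].to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject": str, "condition": str})


# -- course stacks -----------------------------------------------------------


def write_courses(courses: dict[str, np.ndarray], path) -> None:
    np.savez_compressed(path, **{str(k): v for k, v in courses.items()})


def read_courses(path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


# -- structural matrices -----------------------------------------------------


def write_structural(
    structural: dict[str, np.ndarray], atlas: ParcelAtlas, directory
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for subject, mat in structural.items():
        frame = pd.DataFrame(mat, index=atlas.regions, columns=atlas.regions)
        frame.to_csv(directory / f"{subject}.tsv", sep="\t")


def read_structural(directory) -> dict[str, np.ndarray]:
    out = {}
    for path in sorted(Path(directory).glob("*.tsv")):
        frame = pd.read_csv(path, sep="\t", index_col=0)
        out[path.stem] = frame.to_numpy()
    return out


# -- truth record ------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# -- edge tensor -------------------------------------------------------------


def write_edge_tensor(tensor: EdgeTensor, workdir) -> None:
    workdir = Path(workdir)
    np.savez_compressed(
        workdir / TENSOR_NPZ, z=tensor.z, n_retained=tensor.n_retained
    )
    trials = tensor.trials.copy()
    write_trials(trials, workdir / TENSOR_TRIALS_TSV)
    write_json(
        {
            "regions": list(tensor.edge_index.regions),
            "grubbs_alpha": tensor.grubbs_alpha,
            "min_samples": tensor.min_samples,
            "filter_mode": tensor.filter_mode,
        },
        workdir / TENSOR_META_JSON,
    )


def read_edge_tensor(workdir) -> EdgeTensor:
    workdir = Path(workdir)
    meta = read_json(workdir / TENSOR_META_JSON)
    with np.load(workdir / TENSOR_NPZ) as data:
        z = data["z"]
        n_retained = data["n_retained"]
    trials = read_trials(workdir / TENSOR_TRIALS_TSV)
    return EdgeTensor(
        z=z,
        n_retained=n_retained,
        trials=trials,
        edge_index=EdgeIndex(tuple(meta["regions"])),
        grubbs_alpha=meta["grubbs_alpha"],
        min_samples=meta["min_samples"],
        filter_mode=meta["filter_mode"],
    )


def write_edge_tensor_long(tensor: EdgeTensor, path) -> None:
    tensor.to_long_frame().to_csv(path, sep="\t", index=False)


# -- statistics, nulls, reports ----------------------------------------------


def write_edge_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_edge_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def write_null(null: NullDistribution, path_tsv) -> None:
    path_tsv = Path(path_tsv)
    pd.DataFrame({"max_abs_t": null.max_abs_t}).to_csv(
        path_tsv, sep="\t", index=False
    )
    write_json(
        {
            "condition": null.condition,
            "model": null.model,
            "n_perms": null.n_perms,
            "seed": null.seed,
            "shuffle_mode": null.shuffle_mode,
            "n_edges_fitted": null.n_edges_fitted,
        },
        path_tsv.with_suffix(".json"),
    )


def read_null(path_tsv) -> NullDistribution:
    path_tsv = Path(path_tsv)
    meta = read_json(path_tsv.with_suffix(".json"))
    values = pd.read_csv(path_tsv, sep="\t")["max_abs_t"].to_numpy()
    return NullDistribution(
        condition=meta["condition"],
        model=meta["model"],
        max_abs_t=values,
        n_perms=meta["n_perms"],
        seed=meta["seed"],
        shuffle_mode=meta["shuffle_mode"],
        n_edges_fitted=meta["n_edges_fitted"],
    )


def write_report(report: SignificanceReport, path) -> None:
    report.edges.to_csv(path, sep="\t", index=False, na_rep="NA")
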
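"""Network-level summaries of edge-wise significance reports.

Turns corrected edge statistics into the quantities a whole-brain
connectivity study reports: counts of significantly modulated connections
by sign, per-region degree and hub tables (a hub has at least three
significant connections), cross-condition hub unions and conjunctions,
condition-unique contrast counts, and the pain-signature ("NPS") subset
analysis in which connectivity is averaged over all edges internal to a
flagged region set before a single mixed-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .connectivity import EdgeTensor
from . import lmm
from .permutation import NullDistribution, SignificanceReport, corrected_pvalues


# ---------------------------------------------------------------------------
# edge counting and hubs
# ---------------------------------------------------------------------------


def count_significant(report: SignificanceReport) -> dict:
    """Totals of significant edges, split by slope sign.

    ``attenuation_encoding`` edges have negative slope: stronger
    connectivity in trials with lower pain ratings (better attenuation).
    """
    sig = report.significant_edges
    n_att = int(sig["attenuation_encoding"].sum())
    return {
        "total": len(sig),
        "attenuation_encoding": n_att,
        "opposite_sign": len(sig) - n_att,
    }


def hub_regions(report: SignificanceReport, min_degree: int = 3) -> pd.DataFrame:
    """Per-region degree over significant edges; hubs have degree >= min_degree.

    Returns a table (region, degree, hub) sorted by decreasing degree; the
    first row is the most-connected region.  The handshake identity (degree
    sum = 2 x edge count) holds by construction.
    """
    sig = report.significant_edges
    degrees = (
        pd.concat([sig["region_a"], sig["region_b"]])
        .value_counts()
        .rename_axis("region")
        .reset_index(name="degree")
    )
    degrees["hub"] = degrees["degree"] >= min_degree
    degrees["condition"] = report.condition
    return degrees.sort_values(
        ["degree", "region"], ascending=[False, True]
    ).reset_index(drop=True)


def cross_condition_union(
    reports: dict[str, SignificanceReport], min_degree: int = 3
) -> list[str]:
    """Regions that are hubs (>= min_degree significant edges) in any condition."""
    if not reports:
        raise ValueError("need at least one condition report")
    union: set[str] = set()
    for report in reports.values():
        hubs = hub_regions(report, min_degree=min_degree)
        union.update(hubs.loc[hubs["hub"], "region"])
    return sorted(union)


def conjunction_edges(reports: dict[str, SignificanceReport]) -> pd.DataFrame:
    """Edges significant in every condition (intersection of significant sets)."""
    if not reports:
        raise ValueError("need at least one condition report")
    keys = None
    for report in reports.values():
        sig = report.significant_edges
        pairs = set(zip(sig["region_a"], sig["region_b"]))
        keys = pairs if keys is None else keys & pairs
    rows = sorted(keys)
    return pd.DataFrame(rows, columns=["region_a", "region_b"])


# ---------------------------------------------------------------------------
# NPS-subset trial analysis
# ---------------------------------------------------------------------------


@dataclass
class NpsResult:
    """Mean within-subset connectivity per trial plus its mixed-model fit."""

    per_trial: pd.DataFrame        # subject, condition, trial, mean_z, rating
    fit: lmm.LmeFit
    condition: str
    regions: list[str]
    n_edges: int

    @property
    def beta(self) -> float:
        return float(self.fit.params["mean_z"])

    @property
    def tstat(self) -> float:
        return float(self.fit.tstat["mean_z"])

    @property
    def p_uncorrected(self) -> float:
        return float(self.fit.pvalues()["mean_z"])


def nps_trial_analysis(
    tensor: EdgeTensor,
    atlas: ParcelAtlas,
    condition: str,
    unmodulated: str | None = None,
    regions: list[str] | None = None,
) -> NpsResult:
    """Average connectivity over all edges internal to the flagged region set.

    Per trial, the mean Fisher-Z over all unordered pairs internal to the
    NPS (pain-signature) region set; a random-intercept model of rating on
    that mean (condition plus unmodulated trials) gives a single subset-level
    slope and an *uncorrected* p-value — this analysis is reported without
    multiple-comparison correction, by design.
    """
    if regions is None:
        regions = atlas.nps_regions
    if len(regions) < 2:
        raise ValueError("need at least 2 flagged regions")
    trials = tensor.trials
    if unmodulated is None:
        unmodulated = trials["condition"].iloc[0]
    region_set = set(regions)
    pairs = tensor.edge_index.to_frame()
    internal = (
        pairs["region_a"].isin(region_set) & pairs["region_b"].isin(region_set)
    ).to_numpy()
    if internal.sum() < 1:
        raise ValueError("no internal edges for the flagged region set")
    mask = lmm.select_condition_rows(trials, condition, unmodulated)
    rows = np.flatnonzero(mask)
    mean_z = np.nanmean(tensor.z[np.ix_(rows, np.flatnonzero(internal))], axis=1)
    per_trial = trials.iloc[rows][
        ["subject", "condition", "trial", "rating"]
    ].copy()
    per_trial["mean_z"] = mean_z
    fit = lmm.fit_random_intercept(per_trial, predictor="mean_z")
    return NpsResult(
        per_trial=per_trial.reset_index(drop=True),
        fit=fit,
        condition=condition,
        regions=sorted(region_set),
        n_edges=int(internal.sum()),
    )


# ---------------------------------------------------------------------------
# condition contrasts (M2)
# ---------------------------------------------------------------------------


def condition_contrast_report(
    stats_m2: dict[str, pd.DataFrame],
    nulls_m2: dict[str, NullDistribution],
    alpha: float = 0.05,
    m1_reports: dict[str, SignificanceReport] | None = None,
) -> dict:
    """Condition-unique edges: M2 interaction terms surviving max-t correction.

    Returns per-condition unique-edge counts and significant-edge tables;
    if per-condition M1 reports are supplied, the conjunction (edges
    significant in all conditions) is included as well.
    """
    unique_counts: dict[str, int] = {}
    unique_edges: dict[str, pd.DataFrame] = {}
    for cond, stats in stats_m2.items():
        report = corrected_pvalues(stats, nulls_m2[cond], alpha=alpha)
        sig = report.significant_edges
        unique_counts[cond] = len(sig)
        unique_edges[cond] = sig.reset_index(drop=True)
    out = {"unique_counts": unique_counts, "unique_edges": unique_edges}
    if m1_reports is not None:
        conj = conjunction_edges(m1_reports)
        out["conjunction_edges"] = conj
        out["conjunction_count"] = len(conj)
    return out


# ---------------------------------------------------------------------------
# matrix renderings
# ---------------------------------------------------------------------------


def significance_matrix(report: SignificanceReport) -> pd.DataFrame:
    """Square signed significance matrix (+1 attenuation-encoding, -1 opposite).

    Mirrored across the diagonal, zero elsewhere — the red/blue matrix
    encoding of the edge-wise results.
    """
    edges = report.edges
    regions = list(
        dict.fromkeys(edges["region_a"].tolist() + edges["region_b"].tolist())
    )
    idx = {r: i for i, r in enumerate(regions)}
    mat = np.zeros((len(regions), len(regions)), dtype=int)
    for _, row in report.significant_edges.iterrows():
        sign = 1 if row["attenuation_encoding"] else -1
        i, j = idx[row["region_a"]], idx[row["region_b"]]
        mat[i, j] = sign
        mat[j, i] = sign
    return pd.DataFrame(mat, index=regions, columns=regions)


def tstat_matrix(stats: pd.DataFrame) -> pd.DataFrame:
    """Square t-statistic matrix from an EdgeStats table (NaN diagonal)."""
    regions = list(
        dict.fromkeys(stats["region_a"].tolist() + stats["region_b"].tolist())
    )
    idx = {r: i for i, r in enumerate(regions)}
    mat = np.full((len(regions), len(regions)), np.nan)
    for ra, rb, t in zip(stats["region_a"], stats["region_b"], stats["t"]):
        i, j = idx[ra], idx[rb]
        mat[i, j] = t
        mat[j, i] = t
    return pd.DataFrame(mat, index=regions, columns=regions)


def plot_significance_matrix(report: SignificanceReport, path=None):
    """Optional heatmap rendering (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = significance_matrix(report)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mat.to_numpy(), cmap="bwr", vmin=-1, vmax=1)
    ax.set_title(f"{report.model} {report.condition}: signed significance")
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
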
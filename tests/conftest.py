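import numpy as np
import pandas as pd
import pytest

import painconn as pc


@pytest.fixture(scope="session")
def small_null_sim():
    """Small global-null dataset (no planted effects)."""
    cfg = pc.SimConfig(
        n_subjects=8,
        n_regions=6,
        conditions=("unmodulated", "counting"),
        trials_per_condition=8,
        seed=41,
    )
    return pc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_sim():
    """Dataset with one coupled edge (slope -8) and one mediated edge."""
    cfg = pc.SimConfig(
        n_subjects=20,
        n_regions=8,
        conditions=("unmodulated", "counting"),
        trials_per_condition=12,
        coupled_edges=[(0, 1, -8.0)],
        mediated_edges=[(2, 3, 3.5)],
        seed=77,
    )
    return pc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_tensor(planted_sim):
    return pc.tensor_from_simulation(planted_sim)


def lme4_tstats(frames: list[pd.DataFrame]) -> np.ndarray:
    """Independent oracle: lme4 REML t-values for rating ~ z + (1|subject).

    Runs one Rscript call for all datasets; returns an array of
    (t_intercept, t_slope) rows in dataset order.
    """
    import os
    import subprocess
    import tempfile

    tagged = []
    for i, df in enumerate(frames):
        d = df[["subject", "z", "rating"]].copy()
        d["dataset"] = i
        tagged.append(d)
    alldf = pd.concat(tagged)
    with tempfile.TemporaryDirectory() as td:
        csv = os.path.join(td, "d.csv")
        out = os.path.join(td, "o.csv")
        alldf.to_csv(csv, index=False)
        script = f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
res <- do.call(rbind, lapply(split(d, d$dataset), function(s) {{
  m <- lmer(rating ~ z + (1|subject), data=s, REML=TRUE,
            control=lmerControl(optCtrl=list(xtol_abs=1e-12, ftol_abs=1e-12)))
  co <- summary(m)$coefficients
  data.frame(dataset=s$dataset[1], t_int=co[1,"t value"], t_z=co[2,"t value"])
}}))
res <- res[order(res$dataset),]
write.csv(res, "{out}", row.names=FALSE)
"""
        subprocess.run(
            ["Rscript", "-e", script], check=True, capture_output=True
        )
        res = pd.read_csv(out).sort_values("dataset")
    return res[["t_int", "t_z"]].to_numpy()


def make_grouped_data(
    rng,
    n_groups: int = 10,
    per_group: int = 12,
    slope: float = 0.5,
    group_sd: float = 1.5,
    noise_sd: float = 2.0,
) -> pd.DataFrame:
    """Random-intercept regression dataset with known structure."""
    subj = np.repeat([f"g{i}" for i in range(n_groups)], per_group)
    x = rng.standard_normal(n_groups * per_group)
    intercepts = np.repeat(rng.normal(0.0, group_sd, n_groups), per_group)
    y = 10.0 + slope * x + intercepts + rng.normal(0.0, noise_sd, len(x))
    return pd.DataFrame({"subject": subj, "z": x, "rating": y})
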
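"""Parcellation atlas: the ordered region list that defines all matrix axes.

A whole-brain parcellation of the kind used here subdivides each cortical
hemisphere into 180 surface regions and adds a small set of subcortical
nuclei relevant to pain processing (thalamus, amygdala, PAG, ...), giving
371 regions in total.  Region *order* is load-bearing: edge vectors, edge
statistics and significance matrices are all aligned to the canonical
unordered-pair enumeration over this order.

Membership flags (e.g. the "NPS" pain-signature subset) are data, not code:
they live in a column of the atlas table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REQUIRED_COLUMNS = ("region_id", "name", "hemisphere", "cortical")


@dataclass(frozen=True)
class ParcelAtlas:
    """Ordered list of brain regions with hemisphere / subset annotations.

    Parameters
    ----------
    table:
        One row per region, in canonical order.  Required columns:
        ``region_id`` (unique string), ``name``, ``hemisphere``
        (``"L"``/``"R"``/``"X"`` for midline or bilateral structures) and
        ``cortical`` (bool).  An optional boolean ``nps`` column flags
        membership of the pain-signature subset.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        ids = self.table["region_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate region ids: {dupes}")

    @property
    def regions(self) -> list[str]:
        return self.table["region_id"].tolist()

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def nps_regions(self) -> list[str]:
        if "nps" not in self.table.columns:
            return []
        return self.table.loc[self.table["nps"].astype(bool), "region_id"].tolist()

    def hemisphere(self, hemi: str) -> list[str]:
        return self.table.loc[self.table["hemisphere"] == hemi, "region_id"].tolist()

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        table = pd.read_csv(path, sep="\t", dtype={"region_id": str, "name": str})
        for col in ("cortical", "nps"):
            if col in table.columns:
                table[col] = table[col].astype(bool)
        return cls(table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def template(
        cls,
        n_per_hemisphere: int = 180,
        n_subcortical: int = 11,
        nps_regions: list[str] | None = None,
    ) -> "ParcelAtlas":
        """Build a label-only atlas with the standard region layout.

        The default sizes (180 cortical regions per hemisphere plus 11
        subcortical regions) reproduce the 371-region layout of the
        multimodal cortical parcellation extended with pain-relevant
        subcortical nuclei.  Names are synthetic placeholders; real atlas
        tables should be loaded with :meth:`from_tsv`.
        """
        rows = []
        for hemi in ("L", "R"):
            for i in range(n_per_hemisphere):
                rid = f"{hemi}_ctx{i + 1:03d}"
                rows.append((rid, rid, hemi, True))
        for i in range(n_subcortical):
            rid = f"X_sub{i + 1:02d}"
            rows.append((rid, rid, "X", False))
        table = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
        if nps_regions is not None:
            table["nps"] = table["region_id"].isin(nps_regions)
        return cls(table)

    @classmethod
    def simple(cls, n_regions: int, nps: list[str] | None = None) -> "ParcelAtlas":
        """Small flat atlas (``r001`` ... ``rNNN``) for simulations and tests."""
        ids = [f"r{i + 1:03d}" for i in range(n_regions)]
        table = pd.DataFrame(
            {
                "region_id": ids,
                "name": ids,
                "hemisphere": ["X"] * n_regions,
                "cortical": [True] * n_regions,
            }
        )
        if nps is not None:
            table["nps"] = table["region_id"].isin(nps)
        return cls(table)
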
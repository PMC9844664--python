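"""The analysis input: ordinal symptom severities plus covariates.

A :class:`SymptomDataset` holds an n x p integer matrix of 0-10 severity
ratings (the 13 severity items of the MD Anderson Symptom Inventory by
default), an optional covariate block, and an optional survivorship-stratum
label per row.  Rows with any missing value are removed at construction
(listwise deletion), so every downstream estimator sees a single complete n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SymptomDataset", "MDASI_ITEMS", "SURVIVORSHIP_GROUPS"]

#: The 13 severity items of the MD Anderson Symptom Inventory.
MDASI_ITEMS = [
    "pain",
    "fatigue",
    "disturbed_sleep",
    "distress",
    "shortness_of_breath",
    "drowsiness",
    "dry_mouth",
    "sadness",
    "difficulty_remembering",
    "numbness",
    "lack_of_appetite",
    "nausea",
    "vomiting",
]

#: Survivorship strata; half-open at 5 years, closed at 10.
SURVIVORSHIP_GROUPS = ["<5y", "5-10y", ">10y"]

SCORE_MIN, SCORE_MAX = 0, 10


def survivorship_group(years: float) -> str:
    """Stratum label for a survivorship duration: [0,5), [5,10], (10,inf)."""
    if years < 5:
        return "<5y"
    if years <= 10:
        return "5-10y"
    return ">10y"


@dataclass
class SymptomDataset:
    """Complete-case ordinal symptom data with covariates.

    Parameters
    ----------
    items : DataFrame
        n x p integer severity scores in [0, 10].
    covariates : DataFrame or None
        n x q numeric covariates (binary 0/1 or continuous), row-aligned.
    group : Series or None
        Per-row survivorship stratum label.
    """

    items: pd.DataFrame
    covariates: pd.DataFrame | None = None
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        items = pd.DataFrame(self.items)
        cov = None if self.covariates is None else pd.DataFrame(self.covariates)
        grp = None if self.group is None else pd.Series(self.group)

        keep = ~items.isna().any(axis=1)
        if cov is not None:
            cov = cov.reset_index(drop=True)
            keep = keep.reset_index(drop=True) & ~cov.isna().any(axis=1)
            items = items.reset_index(drop=True)
            if grp is not None:
                grp = grp.reset_index(drop=True)
        items = items.loc[np.asarray(keep)].reset_index(drop=True)
        if cov is not None:
            cov = cov.loc[np.asarray(keep)].reset_index(drop=True)
        if grp is not None:
            grp = grp.loc[np.asarray(keep)].reset_index(drop=True)

        vals = items.to_numpy()
        if vals.size == 0:
            raise ValueError("dataset has no complete rows")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite severity scores after deletion")
        if np.any(vals != np.round(vals)):
            raise ValueError("severity scores must be integers")
        if vals.min() < SCORE_MIN or vals.max() > SCORE_MAX:
            raise ValueError(f"severity scores must lie in [{SCORE_MIN}, {SCORE_MAX}]")
        self.items = items.astype(int)
        self.covariates = cov
        self.group = grp

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def p(self) -> int:
        return self.items.shape[1]

    @property
    def item_labels(self) -> list[str]:
        return list(self.items.columns)

    @property
    def covariate_labels(self) -> list[str]:
        return [] if self.covariates is None else list(self.covariates.columns)

    def values(self) -> np.ndarray:
        return self.items.to_numpy()

    def total_severity(self) -> np.ndarray:
        """Row sum over all severity items (0-130 for the 13-item MDASI)."""
        return self.items.to_numpy().sum(axis=1)

    def subset(self, rows) -> "SymptomDataset":
        """Row subset (bootstrap resamples, case-dropping subsamples)."""
        rows = np.asarray(rows)
        return SymptomDataset(
            self.items.iloc[rows],
            None if self.covariates is None else self.covariates.iloc[rows],
            None if self.group is None else self.group.iloc[rows],
        )

    def group_split(self) -> dict[str, "SymptomDataset"]:
        if self.group is None:
            raise ValueError("dataset has no group labels")
        out = {}
        for g in self.group.unique():
            out[str(g)] = self.subset(np.nonzero((self.group == g).to_numpy())[0])
        return out

    # -- wide-CSV round trip ----------------------------------------------

    def to_csv(self, path) -> None:
        """Write wide CSV: ``id, group, sym_01..sym_p, cov_*``."""
        df = pd.DataFrame({"id": np.arange(1, self.n + 1)})
        df["group"] = "" if self.group is None else self.group.to_numpy()
        for j, lab in enumerate(self.item_labels, start=1):
            df[f"sym_{j:02d}"] = self.items[lab].to_numpy()
        if self.covariates is not None:
            for lab in self.covariate_labels:
                df[f"cov_{lab}"] = self.covariates[lab].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, item_labels: list[str] | None = None) -> "SymptomDataset":
        """Read the wide CSV written by :meth:`to_csv`.

        ``sym_*`` columns become items (renamed to ``item_labels`` when
        given, defaulting to the MDASI names for 13 items), ``cov_*``
        columns become covariates, and a non-empty ``group`` column becomes
        the stratum label.
        """
        df = pd.read_csv(path)
        sym_cols = sorted(c for c in df.columns if c.startswith("sym_"))
        if not sym_cols:
            raise ValueError("no sym_* columns found")
        if item_labels is None:
            item_labels = MDASI_ITEMS if len(sym_cols) == 13 else sym_cols
        items = df[sym_cols].copy()
        items.columns = list(item_labels)
        cov_cols = [c for c in df.columns if c.startswith("cov_")]
        cov = None
        if cov_cols:
            cov = df[cov_cols].copy()
            cov.columns = [c[len("cov_"):] for c in cov_cols]
        grp = None
        if "group" in df.columns and df["group"].notna().any():
            g = df["group"].astype(str)
            if (g != "").any():
                grp = g
        return cls(items, cov, grp)
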
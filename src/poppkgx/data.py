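"""Longitudinal PK dataset handling (NONMEM-style rectangular layout).

Columns: ID, TIME (h), DV (mg/L), AMT (mg), EVID (0 observation, 1 dose),
OCC (occasion index), MDV (missing DV), BLQ (below limit of
quantification), WT (kg), HT (m), SEX (0 male / 1 female), ARM
(0 TDF / 1 TAF), AGE (years, optional), GENO (genotype string such as
"C/C", empty when not genotyped).

The dataframe is the interchange format; :class:`Subject` is the compiled
per-subject view the estimation engine consumes.  BLQ observations are
retained in the data but excluded from the likelihood (M1 handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk import compute_ffm

__all__ = ["Subject", "PKDataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = [
    "ID", "TIME", "DV", "AMT", "EVID", "OCC", "MDV", "BLQ", "WT", "HT", "SEX", "ARM",
]


@dataclass
class Subject:
    """Compiled per-subject record."""

    id: object
    ffm: float
    sex: int
    arm: int
    age: float
    geno: str | None  # None = not genotyped
    dose_times: np.ndarray
    dose_amts: np.ndarray
    dose_occ: np.ndarray
    obs_times: np.ndarray  # non-BLQ observations entering the likelihood
    obs_dv: np.ndarray
    obs_occ: np.ndarray
    n_blq: int = 0
    occasions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    dose_groups: list = field(default_factory=list)  # [(occ, times, amts)]

    def __post_init__(self) -> None:
        self.occasions = np.unique(np.concatenate([self.dose_occ, self.obs_occ]))
        self.dose_groups = [
            (int(o), self.dose_times[self.dose_occ == o], self.dose_amts[self.dose_occ == o])
            for o in np.unique(self.dose_occ)
        ]


class PKDataset:
    """A NONMEM-style PK dataset with compiled per-subject views."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.copy()
        if "AGE" not in df.columns:
            df["AGE"] = np.nan
        if "GENO" not in df.columns:
            df["GENO"] = ""
        df["GENO"] = df["GENO"].fillna("")
        self.df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(
            drop=True
        )
        self.subjects = [self._compile(g) for _, g in self.df.groupby("ID", sort=True)]

    @staticmethod
    def _compile(g: pd.DataFrame) -> Subject:
        doses = g[g["EVID"] == 1]
        obs = g[(g["EVID"] == 0) & (g["MDV"] == 0)]
        keep = obs["BLQ"] == 0
        wt = float(g["WT"].iloc[0])
        ht = float(g["HT"].iloc[0])
        sex = int(g["SEX"].iloc[0])
        geno = str(g["GENO"].iloc[0]) or None
        return Subject(
            id=g["ID"].iloc[0],
            ffm=compute_ffm(wt, ht, "female" if sex == 1 else "male"),
            sex=sex,
            arm=int(g["ARM"].iloc[0]),
            age=float(g["AGE"].iloc[0]),
            geno=geno,
            dose_times=doses["TIME"].to_numpy(float),
            dose_amts=doses["AMT"].to_numpy(float),
            dose_occ=doses["OCC"].to_numpy(int),
            obs_times=obs.loc[keep, "TIME"].to_numpy(float),
            obs_dv=obs.loc[keep, "DV"].to_numpy(float),
            obs_occ=obs.loc[keep, "OCC"].to_numpy(int),
            n_blq=int((~keep).sum()),
        )

    # ------------------------------------------------------------------ io
    @classmethod
    def from_csv(cls, path) -> "PKDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    # ------------------------------------------------------------- summary
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return int(sum(s.obs_times.size for s in self.subjects))

    @property
    def n_blq(self) -> int:
        return int(sum(s.n_blq for s in self.subjects))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PKDataset(n_subjects={self.n_subjects}, "
            f"n_observations={self.n_observations}, n_blq={self.n_blq})"
        )
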
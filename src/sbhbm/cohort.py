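"""Phenotype cleaning, median-split stratification and design assembly.

Participants are stratified into four groups per social index by crossing
recorded sex with a dichotomized social trait: group id
``2*(sex==female) + (trait==high)``, i.e. 0 = male/low, 1 = male/high,
2 = female/low, 3 = female/high.  "Low/high" reads as less/more social
support, lives alone / lives with others, and unhappy/happy with friendships.

Ordinal item coding (larger = more of the trait):

* ``social_support``: answer to "How often are you able to confide in someone
  close to you?", coded 1 = never or almost never .. 7 = almost daily.
* ``household_size``: number of people in the household (>= 1).
* ``friendship_satisfaction``: coded 1 = extremely unhappy .. 6 = extremely
  happy.

Non-answers are the literal strings ``do_not_know`` / ``prefer_not_to_answer``
or empty cells; they are preserved by the readers and removed by
:func:`clean_responses`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .atlas import Atlas, load_atlas
from .roi_extraction import RegionVolumeMatrix, zscore_columns

__all__ = [
    "SOCIAL_INDICES",
    "GROUP_LABELS",
    "NON_ANSWERS",
    "CohortError",
    "DesignMatrix",
    "read_phenotypes",
    "clean_responses",
    "median_split",
    "dichotomize_household",
    "assign_groups",
    "build_design",
]

logger = logging.getLogger(__name__)

#: The three social indices, each fit as an independent model.
SOCIAL_INDICES = ("support", "household", "friendship")

#: Phenotype column backing each social index.
INDEX_COLUMNS = {
    "support": "social_support",
    "household": "household_size",
    "friendship": "friendship_satisfaction",
}

#: Group id -> human-readable label, per social index.
GROUP_LABELS = {
    "support": ("male/less support", "male/more support",
                "female/less support", "female/more support"),
    "household": ("male/lives alone", "male/lives with others",
                  "female/lives alone", "female/lives with others"),
    "friendship": ("male/unhappy friendships", "male/happy friendships",
                   "female/unhappy friendships", "female/happy friendships"),
}

NON_ANSWERS = ("do_not_know", "prefer_not_to_answer")

_CONFOUND_COLUMNS = ["body_mass", "head_size_scaling"]
_REQUIRED_COLUMNS = [
    "participant_id", "sex", "age",
    "social_support", "household_size", "friendship_satisfaction",
] + _CONFOUND_COLUMNS


class CohortError(ValueError):
    """Raised for phenotype-table or design-assembly contract violations."""


@dataclass
class DesignMatrix:
    """Inputs to the hierarchical regression for one social index.

    ``X`` holds z-scored region volumes, ``y`` z-scored age, ``C`` z-scored
    confounds (body mass, head-size scaling), ``g`` group ids in 0..3.
    ``network_index`` maps each X column to its network (0..3), in atlas
    region order.
    """

    X: np.ndarray
    y: np.ndarray
    C: np.ndarray
    g: np.ndarray
    social_index: str
    region_names: list[str]
    network_index: np.ndarray
    participant_ids: list[str] = field(default_factory=list)
    n_groups: int = 4

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2:
            C = C.reshape(len(self.y), -1) if C.size else C.reshape(len(self.y), 0)
        self.C = C
        self.g = np.asarray(self.g, dtype=int).ravel()
        self.network_index = np.asarray(self.network_index, dtype=int).ravel()
        n = self.X.shape[0]
        if not (len(self.y) == len(self.g) == self.C.shape[0] == n):
            raise CohortError("X, y, C, g row counts disagree")
        if self.X.shape[1] != len(self.region_names) or len(self.region_names) != len(self.network_index):
            raise CohortError("region bookkeeping disagrees with X columns")
        for a in (self.X, self.y, self.C):
            if a.size and not np.all(np.isfinite(a)):
                raise CohortError("design contains non-finite values")
        if n and (self.g.min() < 0 or self.g.max() >= self.n_groups):
            raise CohortError("group ids out of range")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_regions(self) -> int:
        return self.X.shape[1]

    @property
    def n_confounds(self) -> int:
        return self.C.shape[1]

    def group_counts(self) -> np.ndarray:
        return np.bincount(self.g, minlength=self.n_groups)


def read_phenotypes(path: Union[str, Path]) -> pd.DataFrame:
    """Read a phenotype CSV, preserving non-answer codes as strings."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"phenotype file {path}: missing column(s) {missing}")
    return df


def _numeric_or_nan(col: pd.Series) -> pd.Series:
    """Parse to float; non-answers and empty strings become NaN."""
    s = col.astype(str).str.strip().str.lower()
    s = s.where(~s.isin(NON_ANSWERS) & (s != ""), other=np.nan)
    return pd.to_numeric(s, errors="coerce")


def clean_responses(records: pd.DataFrame, social_index: str) -> pd.DataFrame:
    """Drop participants unusable for the given social index.

    Removes rows with non-answers/missing values on the index item, or with
    missing sex, age or confounds.  Parsed numeric columns replace the raw
    strings in the returned frame; removal counts are logged.
    """
    if social_index not in SOCIAL_INDICES:
        raise CohortError(f"unknown social index {social_index!r}; expected one of {SOCIAL_INDICES}")
    df = records.copy()
    item = INDEX_COLUMNS[social_index]
    for col in [item, "age"] + _CONFOUND_COLUMNS:
        df[col] = _numeric_or_nan(df[col])
    sex = df["sex"].astype(str).str.strip().str.lower()
    df["sex"] = sex.where(sex.isin(["male", "female"]), other=np.nan)

    keep = df[[item, "sex", "age"] + _CONFOUND_COLUMNS].notna().all(axis=1)
    n_removed = int((~keep).sum())
    logger.info("clean_responses(%s): removed %d of %d records", social_index, n_removed, len(df))
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise CohortError(f"cleaning removed every participant for index {social_index!r}")
    return out


def median_split(values: Sequence[float]) -> np.ndarray:
    """Dichotomize at the sample median: high iff strictly above, ties go low.

    Returns an int array (0 = low, 1 = high).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise CohortError("median split needs >= 2 distinct values")
    med = np.median(v)
    high = v > med
    n_ties = int((v == med).sum())
    logger.info("median_split: median=%g, low=%d high=%d (ties at median: %d, assigned low)",
                med, int((~high).sum()), int(high.sum()), n_ties)
    return high.astype(int)


def dichotomize_household(sizes: Sequence[float]) -> np.ndarray:
    """0 = lives alone (size 1), 1 = lives with others (size >= 2)."""
    v = np.asarray(sizes, dtype=float)
    if np.any(v < 1):
        raise CohortError("household sizes must be >= 1 (the respondent counts themself)")
    return (v >= 2).astype(int)


def dichotomize(values: Sequence[float], social_index: str, *, household_median: bool = False) -> np.ndarray:
    """Index-appropriate low/high coding of the raw item values."""
    if social_index == "household" and not household_median:
        return dichotomize_household(values)
    return median_split(values)


def assign_groups(sex: Sequence[str], trait_binary: Sequence[int]) -> np.ndarray:
    """Group ids ``2*(sex==female) + trait`` for cleaned, dichotomized inputs."""
    sex_arr = np.asarray([str(s).strip().lower() for s in sex])
    trait = np.asarray(trait_binary, dtype=int)
    if sex_arr.shape != trait.shape:
        raise CohortError("sex and trait vectors differ in length")
    bad = set(np.unique(sex_arr)) - {"male", "female"}
    if bad:
        raise CohortError(f"unknown sex code(s): {sorted(bad)}")
    if trait.size and (trait.min() < 0 or trait.max() > 1):
        raise CohortError("trait vector must be binary 0/1")
    return 2 * (sex_arr == "female").astype(int) + trait


def build_design(
    volumes: RegionVolumeMatrix,
    records: pd.DataFrame,
    social_index: str,
    *,
    atlas: Optional[Atlas] = None,
    household_median: bool = False,
) -> DesignMatrix:
    """Assemble the model design for one social index.

    Aligns the volume matrix with the phenotype records by participant id
    (row order canonicalized by id), cleans, dichotomizes, z-scores volumes,
    age and confounds, and stratifies into the four sex x trait groups.
    """
    atlas = atlas if atlas is not None else load_atlas("default")
    if list(volumes.values.columns) != atlas.names:
        raise CohortError(
            "volume matrix columns do not match atlas region names "
            f"({list(volumes.values.columns)[:3]}... vs {atlas.names[:3]}...)"
        )
    cleaned = clean_responses(records, social_index)
    cleaned = cleaned.assign(participant_id=cleaned["participant_id"].astype(str))
    vol_ids = set(volumes.values.index.astype(str))
    missing = [pid for pid in cleaned["participant_id"] if pid not in vol_ids]
    if missing:
        raise CohortError(
            f"{len(missing)} cleaned participant(s) lack volume rows, e.g. {missing[:5]}"
        )
    cleaned = cleaned.sort_values("participant_id").reset_index(drop=True)
    vol = volumes.values.loc[cleaned["participant_id"].to_numpy()]

    item = INDEX_COLUMNS[social_index]
    trait = dichotomize(cleaned[item].to_numpy(), social_index, household_median=household_median)
    g = assign_groups(cleaned["sex"].to_numpy(), trait)
    counts = np.bincount(g, minlength=4)
    if np.any(counts == 0):
        raise CohortError(f"empty group(s) after stratification: counts={counts.tolist()}")

    X = vol.to_numpy(dtype=float)
    if not volumes.zscored:
        X = zscore_columns(X)
    y = zscore_columns(cleaned["age"].to_numpy())[:, 0]
    C = zscore_columns(cleaned[_CONFOUND_COLUMNS].to_numpy())
    return DesignMatrix(
        X=X, y=y, C=C, g=g,
        social_index=social_index,
        region_names=atlas.names,
        network_index=atlas.network_index,
        participant_ids=cleaned["participant_id"].tolist(),
    )
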
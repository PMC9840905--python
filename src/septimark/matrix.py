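"""Feature-by-sample abundance matrices with an explicit processing state.

Plasma miRNA and DIA protein intensities are carried as a
:class:`AbundanceMatrix`: a pandas DataFrame (rows = features, columns =
samples, NaN = missing) plus a ``state`` tag that records how far along the
processing chain (raw -> normalized -> log2 -> imputed) the values are.
Operations in :mod:`septimark.abundance` check the tag so that, e.g., a
moderated test can never silently run on un-normalized or un-imputed data.

On-disk format is TSV with a ``feature`` first column, sample ids as the
remaining column headers, and empty cells for missing values.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Legal processing states, in pipeline order.
STATES = ("raw", "normalized", "log2", "imputed")

SAMPLE_COLUMNS = ("sample_id", "group", "day")
GROUPS = ("C", "NS", "S")


class AbundanceMatrix:
    """An intensity matrix with missingness mask and processing state.

    Parameters
    ----------
    values
        DataFrame of float intensities, features as index, samples as
        columns.  NaN marks a missing (unobserved) cell.
    state
        One of ``raw``, ``normalized``, ``log2``, ``imputed``.
    """

    def __init__(self, values: pd.DataFrame, state: str = "raw"):
        if state not in STATES:
            raise ValidationError(f"unknown matrix state {state!r}; expected one of {STATES}")
        if not isinstance(values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame (features x samples)")
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = values.astype(float)
        if state == "imputed" and values.isna().any().any():
            raise ValidationError("an imputed matrix must not contain missing values")
        self.values = values
        self.state = state

    # -- basic introspection -------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nf, ns = self.values.shape
        return f"AbundanceMatrix({nf} features x {ns} samples, state={self.state!r})"

    def with_values(self, values: pd.DataFrame, state: str) -> "AbundanceMatrix":
        """Return a new matrix with replaced values and state."""
        return AbundanceMatrix(values, state=state)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not present in matrix: {missing}")
        return AbundanceMatrix(self.values.loc[:, sample_ids], state=self.state)

    # -- IO ------------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path, state: str = "raw") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, state=state)


def hstack(matrices: Iterable[AbundanceMatrix]) -> AbundanceMatrix:
    """Column-concatenate matrices sharing the same feature index.

    Used to pool per-day protein matrices (plus the day-0 control matrix)
    into one table for pooled normalization, PCA, and trend analysis.
    """
    mats = list(matrices)
    if not mats:
        raise ValidationError("hstack requires at least one matrix")
    states = {m.state for m in mats}
    if len(states) > 1:
        raise ValidationError(f"cannot pool matrices in different states: {sorted(states)}")
    index = mats[0].values.index
    for m in mats[1:]:
        if not m.values.index.equals(index):
            raise ValidationError("matrices must share an identical feature index")
    return AbundanceMatrix(pd.concat([m.values for m in mats], axis=1), state=mats[0].state)


# -- sample metadata ---------------------------------------------------------


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table (sample_id, group, day) and normalize types."""
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValidationError(f"sample table lacks required column {col!r}")
    samples = samples.copy()
    samples["sample_id"] = samples["sample_id"].astype(str)
    samples["group"] = samples["group"].astype(str)
    samples["day"] = samples["day"].astype(int)
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in sample table: {dupes}")
    bad = sorted(set(samples["group"]) - set(GROUPS))
    if bad:
        raise ValidationError(f"unknown group labels {bad}; expected {GROUPS}")
    return samples


def load_samples(path) -> pd.DataFrame:
    return validate_samples(pd.read_csv(path, sep="\t"))


def save_samples(samples: pd.DataFrame, path) -> None:
    validate_samples(samples).to_csv(path, sep="\t", index=False)


def samples_in_group(samples: pd.DataFrame, group: str, day: int | None = None) -> list[str]:
    """Sample ids belonging to a group (optionally restricted to one day)."""
    mask = samples["group"] == group
    if day is not None:
        mask &= samples["day"] == int(day)
    return samples.loc[mask, "sample_id"].tolist()
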
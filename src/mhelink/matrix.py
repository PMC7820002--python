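"""Feature-by-sample omics matrices with group labels.

The :class:`OmicsMatrix` is the common currency of every pipeline stage:
a numeric features x samples table (genes, serum metabolites or cytokines)
together with the case/control label of each sample.  Values may contain
NaN for below-detection measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "MHE"
CONTROL = "CTRL"


@dataclass
class OmicsMatrix:
    """A features x samples numeric table with sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids.
    groups
        Series mapping sample id -> group label; must cover every column.
    omic
        Tag, one of ``"gene"``, ``"metabolite"``, ``"cytokine"`` (free-form
        tags are tolerated).
    case, control
        The two group labels; ``case`` is the affected group (MHE).
    """

    values: pd.DataFrame
    groups: pd.Series
    omic: str = "gene"
    case: str = CASE
    control: str = CONTROL
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        extra = set(self.groups.unique()) - {self.case, self.control}
        if extra:
            raise ValueError(f"unknown group labels: {sorted(extra)}")

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == self.case])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == self.control])

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids) -> "OmicsMatrix":
        ids = [i for i in ids if i in self.values.index]
        return OmicsMatrix(self.values.loc[ids], self.groups, self.omic,
                           self.case, self.control, self.meta)

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values, self.groups, self.omic, self.case,
                           self.control, self.meta)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        df = self.values.copy()
        df.index.name = "feature"
        df.to_csv(path, sep="\t", float_format=float_format)

    @staticmethod
    def from_tsv(path: str | Path, groups: pd.Series | str | Path,
                 omic: str = "gene", case: str = CASE,
                 control: str = CONTROL) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not isinstance(groups, pd.Series):
            groups = read_groups(groups)
        return OmicsMatrix(df, groups, omic, case, control)


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column sample table (sample, group) as a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns 'sample' and 'group'")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def write_groups(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False)


def check_same_samples(*matrices: OmicsMatrix) -> None:
    """Raise if the matrices do not share the same ordered sample ids."""
    ref = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ref:
            raise ValueError(
                "sample ids differ between matrices: "
                f"{sorted(set(ref) ^ set(m.sample_ids)) or 'same set, different order'}")


def group_sizes_ok(matrix: OmicsMatrix, min_per_group: int = 2) -> bool:
    g = matrix.groups
    return ((g == matrix.case).sum() >= min_per_group
            and (g == matrix.control).sum() >= min_per_group)
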
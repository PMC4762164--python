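"""Reference signature matrices: loading, validation, subsetting, writing.

A signature set is a k x 96 row-stochastic matrix: each row is one
mutational process expressed as a probability distribution over the 96
trinucleotide substitution classes.  Published catalogs (the 2013
pan-cancer set, the COSMIC v2 30-signature table) are accepted as TSV input
with "A[C>A]A"-style column headers; they are not bundled with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import CONTEXT_ORDER

#: Published rounding means row sums can be slightly off unity; rows within
#: this relative tolerance are renormalized, anything further off is an error.
ROW_SUM_TOLERANCE = 0.01


class SignatureError(ValueError):
    """Invalid signature matrix."""


@dataclass
class SignatureSet:
    """k signatures x 96 context fractions, rows summing to 1."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CONTEXT_ORDER if c not in self.df.columns]
        if missing:
            raise SignatureError(f"missing context columns: {missing[:3]}...")
        if self.df.index.duplicated().any():
            dupes = list(self.df.index[self.df.index.duplicated()])
            raise SignatureError(f"duplicate signature names: {dupes}")
        df = self.df.loc[:, list(CONTEXT_ORDER)].astype(float)
        if (df.to_numpy() < 0).any():
            raise SignatureError("negative entries in signature matrix")
        sums = df.sum(axis=1)
        off = (sums - 1.0).abs() > ROW_SUM_TOLERANCE
        if off.any():
            bad = {name: float(s) for name, s in sums[off].items()}
            raise SignatureError(f"signature rows do not sum to 1: {bad}")
        self.df = df.div(sums, axis=0)

    @property
    def names(self) -> list[str]:
        return list(self.df.index)

    @property
    def k(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        """k x 96 array in canonical context order."""
        return self.df.to_numpy(dtype=float)

    def row(self, name: str) -> np.ndarray:
        return self.df.loc[name].to_numpy(dtype=float)


def load_signatures(path: str | Path) -> SignatureSet:
    """Load a signature TSV: one name column plus the 96 context columns.

    Column order is arbitrary; columns are reindexed to the canonical
    context order.  Rows are renormalized to sum to exactly 1 when within
    1 % of unity, otherwise an error is raised.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureSet(df)


def write_signatures(S: SignatureSet, path: str | Path) -> None:
    """Write the TSV dialect that :func:`load_signatures` reads."""
    S.df.rename_axis("signature").to_csv(path, sep="\t")


def subset_signatures(S: SignatureSet, names: list[str]) -> SignatureSet:
    """Row-subset in the requested order; unknown names are an error."""
    unknown = [n for n in names if n not in S.df.index]
    if unknown:
        raise SignatureError(f"unknown signature names: {unknown}")
    return SignatureSet(S.df.loc[names])


def merge_signatures(S: SignatureSet, group: list[str], merged_name: str) -> SignatureSet:
    """Average a group of signatures into one row (e.g. clock-like 1A + 1B).

    Some published catalogs split a process into sub-signatures that
    downstream analyses treat as one; the merged row is the mean of the
    group (itself row-stochastic) and replaces the group at the position of
    its first member.  Off by default everywhere; opt-in.
    """
    unknown = [n for n in group if n not in S.df.index]
    if unknown:
        raise SignatureError(f"unknown signature names: {unknown}")
    merged = S.df.loc[group].mean(axis=0)
    rows = []
    inserted = False
    for name in S.names:
        if name in group:
            if not inserted:
                rows.append(pd.Series(merged, name=merged_name))
                inserted = True
            continue
        rows.append(S.df.loc[name])
    return SignatureSet(pd.DataFrame(rows))
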
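"""Record containers: microdata tables and equivalence classes.

A :class:`Microdata` wraps a pandas DataFrame whose columns are the dimension
(quasi-identifier) attributes plus one categorical *informative* attribute
(e.g. the disease code) with a declared, ordered domain.  All cells are held
as strings so generalized labels like ``"[10-19]"`` and the suppression mark
``"*"`` live in the same columns as raw values and survive CSV round-trips
verbatim.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .taxonomy import SUPPRESSED

__all__ = ["Record", "Microdata", "EquivalentClass"]


@dataclass(frozen=True)
class Record:
    """One individual's row: dimension values plus the informative value."""

    dim_values: tuple
    inf_value: str
    is_counterfeit: bool = False
    is_suppressed: bool = False


@dataclass
class Microdata:
    """A microdata table with a declared schema.

    Attributes
    ----------
    df:
        String-typed DataFrame with one column per dimension attribute plus
        the informative attribute.
    dim_attrs:
        Ordered dimension attribute names.
    inf_attr:
        Name of the informative attribute (never generalized).
    inf_domain:
        Ordered informative domain; a superset of the observed values.
    """

    df: pd.DataFrame
    dim_attrs: tuple[str, ...]
    inf_attr: str
    inf_domain: tuple[str, ...]

    @classmethod
    def build(
        cls,
        df: pd.DataFrame,
        dim_attrs: Sequence[str],
        inf_attr: str,
        inf_domain: Sequence[str] | None = None,
    ) -> "Microdata":
        dim_attrs = tuple(str(a) for a in dim_attrs)
        inf_attr = str(inf_attr)
        missing = [c for c in (*dim_attrs, inf_attr) if c not in df.columns]
        if missing:
            raise ValueError(f"microdata missing columns {missing}")
        if inf_attr in dim_attrs:
            raise ValueError(f"informative attribute {inf_attr!r} cannot also be a dimension")
        out = df.loc[:, list(dim_attrs) + [inf_attr]].astype(str).reset_index(drop=True)
        observed = set(out[inf_attr]) if len(out) else set()
        if inf_domain is None:
            inf_domain = tuple(sorted(observed))
        else:
            inf_domain = tuple(str(v) for v in inf_domain)
            extra = observed - set(inf_domain)
            if extra:
                raise ValueError(f"informative values outside declared domain: {sorted(extra)}")
        return cls(out, dim_attrs, inf_attr, inf_domain)

    @classmethod
    def from_records(
        cls,
        records: Sequence[Record | tuple],
        dim_attrs: Sequence[str],
        inf_attr: str,
        inf_domain: Sequence[str] | None = None,
    ) -> "Microdata":
        rows = []
        for r in records:
            if isinstance(r, Record):
                rows.append((*r.dim_values, r.inf_value))
            else:
                rows.append(tuple(r))
        df = pd.DataFrame(rows, columns=list(dim_attrs) + [inf_attr])
        return cls.build(df, dim_attrs, inf_attr, inf_domain)

    def __len__(self) -> int:
        return len(self.df)

    def inf_distribution(self) -> np.ndarray:
        """Empirical distribution of the informative attribute over inf_domain."""
        if len(self.df) == 0:
            return np.zeros(len(self.inf_domain))
        counts = self.df[self.inf_attr].value_counts()
        vec = np.array([counts.get(v, 0) for v in self.inf_domain], dtype=float)
        return vec / vec.sum()

    def to_csv_text(self) -> str:
        """Deterministic CSV rendering (header + rows, UTF-8, comma)."""
        return self.df.to_csv(index=False)


@dataclass
class EquivalentClass:
    """Records sharing one generalized dimension tuple.

    ``members`` carries the dimension columns, the informative column, and an
    ``is_counterfeit`` flag column; the histogram and support are derived.
    """

    key: tuple[str, ...]
    members: pd.DataFrame
    inf_attr: str

    def __post_init__(self):
        self.key = tuple(str(k) for k in self.key)
        if "is_counterfeit" not in self.members.columns:
            self.members = self.members.assign(is_counterfeit=False)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def counterfeit_count(self) -> int:
        return int(self.members["is_counterfeit"].sum())

    @property
    def inf_histogram(self) -> Counter:
        return Counter(self.members[self.inf_attr])

    @property
    def present_inf(self) -> frozenset:
        return frozenset(self.members[self.inf_attr])

    def is_fully_suppressed(self) -> bool:
        return all(k == SUPPRESSED for k in self.key)
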
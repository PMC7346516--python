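"""Aggregation-query evaluation on original and anonymized microdata.

Supports the style of utility study used for released health data: group-by
counts and group-by means of an integer attribute, with equality filters
(e.g. *count of stroke patients by 5-year age band among men*).

On anonymized data a record may carry a generalized interval or ``"*"``.  Its
unit of count mass is split across the query buckets proportionally to the
number of raw values the label shares with each bucket (uniform over the
label's extent), filters match when the filter value falls inside the
released label's extent, and means use the interval midpoint as the value
surrogate.  On ungeneralized data these rules reduce exactly to the raw
answers.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping

from .microdata import Microdata
from .taxonomy import TaxonomyTree

__all__ = ["AggregationQuery", "answer_on_original", "answer_on_anonymized", "utility_gap"]


@dataclass(frozen=True)
class AggregationQuery:
    """A filtered group-by count or mean over one integer attribute.

    ``group_by`` buckets the attribute into ``[0, w), [w, 2w), ...`` bands of
    width ``bucket_width``; ``aggregate`` is ``"count"`` or ``"mean"`` (the
    latter averages the integer attribute named ``target``).
    """

    group_by: str
    bucket_width: int
    aggregate: str = "count"
    target: str | None = None
    filters: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.bucket_width < 1:
            raise ValueError("bucket width must be >= 1")
        if self.aggregate not in ("count", "mean"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.aggregate == "mean" and not self.target:
            raise ValueError("mean queries need a target attribute")
        object.__setattr__(
            self, "filters", tuple((str(a), str(v)) for a, v in self.filters)
        )

    @classmethod
    def from_dict(cls, doc: dict) -> "AggregationQuery":
        return cls(
            group_by=doc["group_by"],
            bucket_width=int(doc["bucket_width"]),
            aggregate=doc.get("aggregate", "count"),
            target=doc.get("target"),
            filters=tuple((a, v) for a, v in doc.get("filters", [])),
        )


def answer_on_original(data: Microdata, q: AggregationQuery) -> dict[int, float]:
    """Exact filtered group-by answer on raw microdata."""
    df = data.df
    for attr, val in q.filters:
        if attr not in df.columns:
            raise ValueError(f"unknown filter attribute {attr!r}")
        df = df[df[attr] == val]
    if q.group_by not in data.df.columns:
        raise ValueError(f"unknown group-by attribute {q.group_by!r}")
    if df.empty:
        return {}
    buckets = (df[q.group_by].astype(int) // q.bucket_width) * q.bucket_width
    if q.aggregate == "count":
        return {int(b): float(c) for b, c in buckets.value_counts().items()}
    target = df[q.target].astype(int)
    out = target.groupby(buckets).mean()
    return {int(b): float(m) for b, m in out.items()}


def _extent(trees: Mapping[str, TaxonomyTree], attr: str, label: str):
    tree = trees[attr]
    return tree.extent(label)


def _int_extent(trees, attr, label) -> tuple[int, int]:
    ext = _extent(trees, attr, label)
    if not isinstance(ext, tuple):
        raise ValueError(
            f"attribute {attr!r} is not integer-valued; cannot bucket or average it"
        )
    return ext


def answer_on_anonymized(
    released: Microdata, trees: Mapping[str, TaxonomyTree], q: AggregationQuery
) -> dict[int, float]:
    """Group-by answer on (possibly generalized) released microdata.

    Count mass of a record whose group-by label spans several buckets is
    split proportionally to the leaf overlap with each bucket; ``"*"`` spans
    the whole attribute domain.  Means use the midpoint of the target label's
    extent as the per-record value.
    """
    df = released.df
    for attr, val in q.filters:
        if attr not in df.columns:
            raise ValueError(f"unknown filter attribute {attr!r}")
        if attr == released.inf_attr or attr not in trees:
            df = df[df[attr] == val]
        else:
            matches = {}
            for label in df[attr].unique():
                ext = _extent(trees, attr, label)
                if isinstance(ext, tuple):
                    matches[label] = ext[0] <= int(val) <= ext[1]
                else:
                    matches[label] = val in ext
            df = df[df[attr].map(matches)]
    if df.empty:
        return {}

    w = q.bucket_width
    group_cols = [q.group_by] + ([q.target] if q.aggregate == "mean" else [])
    num: dict[int, float] = defaultdict(float)
    den: dict[int, float] = defaultdict(float)
    for key, cnt in df.groupby(group_cols, sort=False).size().items():
        if not isinstance(key, tuple):
            key = (key,)
        glo, ghi = _int_extent(trees, q.group_by, key[0])
        size = ghi - glo + 1
        if q.aggregate == "mean":
            tlo, thi = _int_extent(trees, q.target, key[1])
            value = (tlo + thi) / 2.0
        b0 = (glo // w) * w
        for b in range(b0, ghi + 1, w):
            overlap = min(ghi, b + w - 1) - max(glo, b) + 1
            if overlap <= 0:
                continue
            mass = cnt * overlap / size
            den[b] += mass
            if q.aggregate == "mean":
                num[b] += mass * value
    if q.aggregate == "count":
        return {b: m for b, m in sorted(den.items())}
    return {b: num[b] / den[b] for b in sorted(den)}


def utility_gap(orig_answers: Mapping[int, float], anon_answers: Mapping[int, float]) -> float:
    """Mean absolute difference across buckets (missing buckets count as 0)."""
    keys = set(orig_answers) | set(anon_answers)
    if not keys:
        return 0.0
    return sum(
        abs(float(orig_answers.get(k, 0.0)) - float(anon_answers.get(k, 0.0))) for k in keys
    ) / len(keys)
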
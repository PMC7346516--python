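"""CSV/JSON readers and writers.

The CSV dialect is fixed — comma separator, required header, UTF-8, fields
kept as strings — so generalized labels like ``"[10-19]"`` and the
suppression mark ``"*"`` round-trip verbatim and writes are byte-stable for
identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .microdata import Microdata

__all__ = ["read_microdata", "write_microdata", "write_json_report", "read_query"]


def read_microdata(
    path,
    dim_attrs: Sequence[str],
    inf_attr: str,
    inf_domain: Sequence[str] | None = None,
) -> Microdata:
    """Read a CSV with a header row into a Microdata table.

    All cells are read as strings (no NA coercion), so values written by
    :func:`write_microdata` are recovered exactly.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Microdata.build(df, dim_attrs, inf_attr, inf_domain)


def write_microdata(data: Microdata, path) -> None:
    """Write a Microdata table as CSV (deterministic column and row order)."""
    Path(path).write_text(data.to_csv_text(), encoding="utf-8")


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_query(path):
    """Read an aggregation-query document (JSON) into an AggregationQuery."""
    from .queries import AggregationQuery

    return AggregationQuery.from_dict(json.loads(Path(path).read_text()))
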
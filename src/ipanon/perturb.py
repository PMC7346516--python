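"""Data perturbation at one lattice node: generalize, suppress, insert.

The pipeline for a single candidate is:

1. *Generalize* every dimension attribute to the node's taxonomy level; the
   informative attribute is never touched.  Records sharing a generalized
   tuple form an equivalence class.
2. *Suppress* small classes.  One noisy threshold ``t + Lap((t-1)/eps)`` is
   drawn per candidate; every class of size <= threshold is removed and its
   records re-emitted with all dimension values set to ``"*"`` (informative
   value preserved).
3. *Insert counterfeits*.  Each kept class receives ``round(Lap(1/eps))``
   extra records (negative draws delete uniformly chosen real records,
   floored at an empty class).  Each counterfeit's informative value is
   chosen by the exponential mechanism over the full informative domain,
   scored by the class's pre-insertion value frequencies, so inserted values
   track the class's real composition.

Released rows are ordered canonically (classes by key, records by
informative value, suppressed bucket last) so the output cannot leak
insertion order.

Draw contract (reproducibility): per candidate, the ``"suppression"`` child
stream yields the single threshold draw; the ``"insertion"`` child yields one
Laplace draw per kept class in sorted key order; the ``"deletion"`` child
yields one permutation per negative-delta class in that same order; the
``"value"`` child yields one uniform per inserted counterfeit, classes in key
order.  Changing one stage never shifts another stage's draws.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mechanisms import PrivacyBudget, RandomSource, exponential_choice, sample_laplace
from .microdata import EquivalentClass, Microdata
from .taxonomy import SUPPRESSED, TaxonomyTree

__all__ = [
    "PerturbOverrides",
    "PerturbedCandidate",
    "generalize_dataset",
    "noisy_threshold",
    "apply_suppression",
    "counterfeit_delta",
    "informative_score",
    "sample_informative_value",
    "perturb_candidate",
    "round_half_away",
]

#: Sensitivity bound used for the informative-value exponential mechanism;
#: the frequency scores lie in (0, 1).
SCORE_SENSITIVITY = 1.0


def round_half_away(x):
    """Round to nearest integer, ties away from zero (reproducible rule)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class PerturbOverrides:
    """Deterministic test-mode knobs for :func:`perturb_candidate`.

    ``threshold`` fixes the suppression threshold (no Laplace draw);
    ``deltas`` maps class keys to forced counterfeit deltas (missing keys
    default to 0); ``forced_values`` maps class keys to the informative
    values of forced insertions.
    """

    threshold: float | None = None
    deltas: Mapping[tuple, int] | None = None
    forced_values: Mapping[tuple, Sequence[str]] | None = None


@dataclass
class PerturbedCandidate:
    """Output of the perturbation pipeline at one lattice node.

    The released rows live in one canonically ordered frame; kept classes are
    contiguous runs of ``class_sizes`` rows (aligned with ``class_keys``),
    followed by ``n_bucket`` suppressed rows.  ``classes`` materializes
    per-class views on demand.
    """

    node: tuple[int, ...]
    dim_attrs: tuple[str, ...]
    inf_attr: str
    released: pd.DataFrame
    class_keys: list[tuple]
    class_sizes: np.ndarray
    class_counterfeits: np.ndarray
    n_bucket: int
    noisy_threshold: float
    n_suppressed_classes: int = 0
    n_inserted: int = 0
    n_deleted: int = 0
    loss: "object | None" = None  # InfoLossReport, filled by the scorer

    @property
    def released_size(self) -> int:
        return len(self.released)

    @property
    def suppressed(self) -> pd.DataFrame:
        """The starred bucket rows (always the tail of the released frame)."""
        return self.released.iloc[len(self.released) - self.n_bucket :]

    @property
    def classes(self) -> list[EquivalentClass]:
        out = []
        start = 0
        for key, size in zip(self.class_keys, self.class_sizes):
            members = self.released.iloc[start : start + int(size)].reset_index(drop=True)
            out.append(EquivalentClass(key, members, self.inf_attr))
            start += int(size)
        return out

    def to_frame(self, public: bool = True) -> pd.DataFrame:
        """Released rows; ``public=True`` strips the counterfeit flag (the
        flagged frame is retained only for private audit)."""
        out = self.released.reset_index(drop=True)
        return out.drop(columns=["is_counterfeit"]) if public else out

    def to_microdata(self, inf_domain: Sequence[str]) -> Microdata:
        return Microdata.build(self.to_frame(public=True), self.dim_attrs, self.inf_attr, inf_domain)


def build_candidate(
    node,
    dim_attrs: Sequence[str],
    inf_attr: str,
    kept_rows: pd.DataFrame,
    bucket: pd.DataFrame,
    noisy_thr: float = float("nan"),
    **counts,
) -> PerturbedCandidate:
    """Assemble a candidate from kept rows and a starred bucket.

    Sorts kept rows into canonical order and derives the per-class index
    (sizes and counterfeit counts) in one vectorized pass.
    """
    dims = list(dim_attrs)
    cols = dims + [inf_attr, "is_counterfeit"]
    kept_rows = kept_rows.loc[:, cols]
    bucket = bucket.loc[:, cols] if len(bucket) else bucket.reindex(columns=cols)
    keys, sizes, cfs = [], [], []
    if len(kept_rows):
        kept_rows = kept_rows.sort_values(dims + [inf_attr], kind="mergesort")
        grp = kept_rows.groupby(dims, sort=True)
        agg = grp["is_counterfeit"].agg(["size", "sum"])
        keys = [k if isinstance(k, tuple) else (k,) for k in agg.index]
        sizes = agg["size"].to_numpy()
        cfs = agg["sum"].to_numpy()
    if len(bucket):
        bucket = bucket.sort_values(inf_attr, kind="mergesort")
    released = pd.concat([kept_rows, bucket], ignore_index=True)
    # classes emptied by deletion keep a zero-size slot
    empty = counts.pop("empty_keys", [])
    if empty:
        keys = list(keys) + list(empty)
        sizes = np.concatenate([np.asarray(sizes, dtype=int), np.zeros(len(empty), dtype=int)])
        cfs = np.concatenate([np.asarray(cfs, dtype=int), np.zeros(len(empty), dtype=int)])
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        keys = [keys[i] for i in order]  # key order must match the row order
        sizes, cfs = sizes[order], cfs[order]
    return PerturbedCandidate(
        node=tuple(node),
        dim_attrs=tuple(dim_attrs),
        inf_attr=inf_attr,
        released=released,
        class_keys=list(keys),
        class_sizes=np.asarray(sizes, dtype=int),
        class_counterfeits=np.asarray(cfs, dtype=int),
        n_bucket=int(len(bucket)),
        noisy_threshold=noisy_thr,
        **counts,
    )


def _generalize_frame(data: Microdata, node, trees: Mapping[str, TaxonomyTree]) -> pd.DataFrame:
    """Generalized copy of the dimension+informative columns (no grouping)."""
    if len(node) != len(data.dim_attrs):
        raise ValueError(f"node {node} does not match {len(data.dim_attrs)} dimensions")
    gdf = data.df.loc[:, list(data.dim_attrs) + [data.inf_attr]].copy()
    for attr, level in zip(data.dim_attrs, node):
        if level == 0:
            continue
        tree = trees[attr]
        col = gdf[attr]
        mapping = {u: str(tree.generalize(u, level)) for u in col.unique()}
        gdf[attr] = col.map(mapping)
    return gdf


def generalize_dataset(
    data: Microdata, node, trees: Mapping[str, TaxonomyTree]
) -> list[EquivalentClass]:
    """Group the node-generalized dataset into equivalence classes.

    Classes are returned sorted by key; informative values are unchanged.
    """
    gdf = _generalize_frame(data, node, trees)
    gdf["is_counterfeit"] = False
    dims = list(data.dim_attrs)
    out = []
    for key, sub in gdf.groupby(dims, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        out.append(EquivalentClass(key, sub.reset_index(drop=True), data.inf_attr))
    return out


def noisy_threshold(t: int, eps_suppression: float, rng: RandomSource) -> float:
    """Suppression threshold ``t + Lap((t-1)/eps)``, drawn once per candidate.

    The threshold's sensitivity is t-1, hence t >= 2: at t = 1 the noise
    scale degenerates to zero and the threshold would leak.
    """
    t = int(t)
    if t < 2:
        raise ValueError(f"suppression threshold t must be >= 2, got {t}")
    if eps_suppression <= 0:
        raise ValueError("eps_suppression must be positive")
    return t + sample_laplace((t - 1) / eps_suppression, rng)


def apply_suppression(
    classes: Sequence[EquivalentClass], threshold: float
) -> tuple[list[EquivalentClass], pd.DataFrame]:
    """Split classes into kept ones and a suppressed bucket.

    Classes of size <= threshold are dissolved: their records keep the
    informative value but every dimension value becomes ``"*"``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    kept, dropped = [], []
    for ec in classes:
        (kept if ec.size > threshold else dropped).append(ec)
    if dropped:
        bucket = pd.concat([ec.members for ec in dropped], ignore_index=True)
        dims = [c for c in bucket.columns if c not in (dropped[0].inf_attr, "is_counterfeit")]
        bucket[dims] = SUPPRESSED
    else:
        cols = classes[0].members.columns if classes else []
        bucket = pd.DataFrame(columns=list(cols))
    return kept, bucket.reset_index(drop=True)


def counterfeit_delta(n: int, eps_insertion: float, rng: RandomSource) -> int:
    """Noisy change to a class size: ``round(Lap(1/eps))``, ties away from 0.

    Positive deltas insert counterfeits; negative deltas delete real records
    (the caller floors deletions at an empty class).  Only non-empty,
    non-suppressed classes receive a draw.
    """
    if int(n) < 1:
        raise ValueError("counterfeit noise applies only to non-empty kept classes")
    if eps_insertion <= 0:
        raise ValueError("eps_insertion must be positive")
    return int(round_half_away(sample_laplace(1.0 / eps_insertion, rng)))


def informative_score(ec: EquivalentClass, v: str, inf_domain: Sequence[str]) -> float:
    """Frequency score of informative value v in a class (pre-insertion).

    ``count(v)/(n+1)`` when v occurs in the class; otherwise the leftover
    mass ``1/((n+1)(|Inf|-|Inf_i|))`` shared uniformly by the absent values.
    """
    v = str(v)
    if v not in set(map(str, inf_domain)):
        raise ValueError(f"value {v!r} outside the informative domain")
    hist = ec.inf_histogram
    n = ec.size
    if hist.get(v, 0) > 0:
        return hist[v] / (n + 1)
    absent = len(inf_domain) - len(ec.present_inf)
    assert absent > 0, "a value absent from the class implies |Inf| > |Inf_i|"
    return 1.0 / ((n + 1) * absent)


def _score_vector(hist: Counter, n: int, inf_domain: Sequence[str]) -> np.ndarray:
    counts = np.array([hist.get(v, 0) for v in inf_domain], dtype=float)
    absent = len(inf_domain) - int((counts > 0).sum())
    scores = counts / (n + 1)
    if absent:
        scores[counts == 0] = 1.0 / ((n + 1) * absent)
    return scores


def sample_informative_value(
    ec: EquivalentClass, inf_domain: Sequence[str], eps_value: float, rng: RandomSource
) -> str:
    """Exponential-mechanism draw of one counterfeit's informative value."""
    domain = [str(v) for v in inf_domain]
    scores = [informative_score(ec, v, domain) for v in domain]
    return exponential_choice(domain, scores, eps_value, SCORE_SENSITIVITY, rng)


def _draw_values(
    hist: Counter, n: int, inf_domain, eps_value: float, count: int, rng: RandomSource
) -> list[str]:
    """Vectorized equivalent of ``count`` sequential exponential-mechanism
    draws (same per-draw distribution, one uniform per counterfeit)."""
    if eps_value <= 0:
        raise ValueError("eps_value must be positive")
    logw = (eps_value / (2.0 * SCORE_SENSITIVITY)) * _score_vector(hist, n, inf_domain)
    w = np.exp(logw - logw.max())
    cum = np.cumsum(w / w.sum())
    idx = np.minimum(np.searchsorted(cum, rng.uniform(count), side="right"), len(cum) - 1)
    return [inf_domain[i] for i in idx]


def perturb_candidate(
    data: Microdata,
    node,
    trees: Mapping[str, TaxonomyTree],
    budget: PrivacyBudget,
    t: int,
    rng: RandomSource,
    mode: str = "symmetric",
    overrides: PerturbOverrides | None = None,
    threshold_per_class: bool = False,
) -> PerturbedCandidate:
    """Run generalize -> suppress -> insert for one lattice node.

    Parameters
    ----------
    mode:
        ``"symmetric"`` (default) lets negative deltas delete records, which
        preserves the two-sided noisy-count distribution; ``"clamp"`` floors
        deltas at 0 (insertion-only, a strictly weaker noise argument).
    overrides:
        Deterministic test-mode knobs; see :class:`PerturbOverrides`.
    threshold_per_class:
        Draw a fresh noisy threshold per class instead of once per candidate.
        Off by default: the single-draw reading treats the threshold as one
        protected quantity of sensitivity t-1.
    """
    if mode not in ("symmetric", "clamp"):
        raise ValueError(f"unknown mode {mode!r}")
    dims = list(data.dim_attrs)
    inf = data.inf_attr
    gdf = _generalize_frame(data, node, trees)

    fixed_thr = overrides.threshold if overrides is not None else None
    if fixed_thr is not None:
        thr = float(fixed_thr)
    else:
        thr = noisy_threshold(t, budget.eps_suppression, rng.child("suppression"))

    keys = list(zip(*(gdf[a] for a in dims))) if len(gdf) else []
    sizes = Counter(keys)

    if fixed_thr is None and threshold_per_class:
        srng = rng.child("suppression", "per-class")
        thr_of = {k: noisy_threshold(t, budget.eps_suppression, srng) for k in sorted(sizes)}
    else:
        thr_of = {k: thr for k in sizes}
    supp_keys = {k for k, s in sizes.items() if s <= thr_of[k]}
    supp_mask = np.fromiter((k in supp_keys for k in keys), dtype=bool, count=len(keys))

    bucket = gdf.loc[supp_mask].copy()
    if len(bucket):
        bucket[dims] = SUPPRESSED
    bucket["is_counterfeit"] = False

    kept = gdf.loc[~supp_mask].copy()
    kept["is_counterfeit"] = False
    kept = kept.sort_values(dims, kind="mergesort")
    kept_keys = sorted(k for k in sizes if k not in supp_keys)
    bounds = np.cumsum([0] + [sizes[k] for k in kept_keys])
    inf_values = kept[inf].to_numpy()

    ins_rng = rng.child("insertion")
    del_rng = rng.child("deletion")
    val_rng = rng.child("value")

    drop_pos: list[np.ndarray] = []
    new_rows: list[tuple] = []  # (*key, value)
    empty_keys: list[tuple] = []
    n_ins = n_del = 0
    for j, key in enumerate(kept_keys):
        lo, hi = bounds[j], bounds[j + 1]
        n = hi - lo
        if overrides is not None and overrides.deltas is not None:
            delta = int(overrides.deltas.get(key, 0))
        else:
            delta = counterfeit_delta(n, budget.eps_insertion, ins_rng)
        if mode == "clamp" and delta < 0:
            delta = 0
        if delta > 0:
            forced = None
            if overrides is not None and overrides.forced_values is not None:
                forced = overrides.forced_values.get(key)
            if forced is not None:
                values = [str(v) for v in forced]
                if len(values) != delta:
                    raise ValueError(f"class {key}: {delta} insertions but {len(values)} values")
            else:
                hist = Counter(inf_values[lo:hi])
                values = _draw_values(hist, n, data.inf_domain, budget.eps_value, delta, val_rng)
            new_rows.extend(key + (v,) for v in values)
            n_ins += delta
        elif delta < 0:
            n_drop = min(-delta, n)
            order = del_rng.permutation(n)
            drop_pos.append(lo + order[:n_drop])
            n_del += n_drop
            if n_drop == n:
                empty_keys.append(key)

    if drop_pos:
        mask = np.ones(len(kept), dtype=bool)
        mask[np.concatenate(drop_pos)] = False
        kept = kept.iloc[mask]
    if new_rows:
        inserts = pd.DataFrame(new_rows, columns=dims + [inf])
        inserts["is_counterfeit"] = True
        kept = pd.concat([kept, inserts], ignore_index=True)

    return build_candidate(
        node,
        data.dim_attrs,
        inf,
        kept,
        bucket,
        noisy_thr=thr,
        empty_keys=empty_keys,
        n_suppressed_classes=len(supp_keys),
        n_inserted=n_ins,
        n_deleted=n_del,
    )
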
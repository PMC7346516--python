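"""Empirical sensitivity audits by exhaustive neighbor enumeration.

These utilities verify, by brute force on small random datasets, the two
sensitivity constants the release mechanisms rely on: the class-size count
query changes by at most 1, and the total information loss changes by at
most 3, when one record is added to or removed from the data.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .loss import score_candidate
from .mechanisms import RandomSource
from .microdata import Microdata
from .perturb import PerturbOverrides, _generalize_frame, perturb_candidate
from .taxonomy import TaxonomyTree, build_lattice

__all__ = ["neighbor_datasets", "class_count_sensitivity", "il_sensitivity"]


def _random_dataset(
    rng: RandomSource,
    n: int,
    dim_domains: Mapping[str, Sequence[str]],
    inf_attr: str,
    inf_domain: Sequence[str],
) -> Microdata:
    cols = {
        a: rng.choice([str(v) for v in dom], size=n) for a, dom in dim_domains.items()
    }
    cols[inf_attr] = rng.choice([str(v) for v in inf_domain], size=n)
    return Microdata.build(
        pd.DataFrame(cols), tuple(dim_domains), inf_attr, tuple(inf_domain)
    )


def neighbor_datasets(
    data: Microdata, dim_domains: Mapping[str, Sequence[str]]
) -> list[Microdata]:
    """All datasets at distance one: each single-record removal, and each
    single-record addition over the full attribute cross-product."""
    out = []
    for i in range(len(data)):
        out.append(
            Microdata.build(
                data.df.drop(index=i), data.dim_attrs, data.inf_attr, data.inf_domain
            )
        )
    domains = [list(map(str, dim_domains[a])) for a in data.dim_attrs]
    for combo in itertools.product(*domains, data.inf_domain):
        row = pd.DataFrame([combo], columns=list(data.dim_attrs) + [data.inf_attr])
        out.append(
            Microdata.build(
                pd.concat([data.df, row], ignore_index=True),
                data.dim_attrs,
                data.inf_attr,
                data.inf_domain,
            )
        )
    return out


def _class_counts(data: Microdata, node, trees) -> Counter:
    gdf = _generalize_frame(data, node, trees)
    return Counter(zip(*(gdf[a] for a in data.dim_attrs))) if len(gdf) else Counter()


def class_count_sensitivity(
    trees: Mapping[str, TaxonomyTree],
    dim_domains: Mapping[str, Sequence[str]],
    inf_domain: Sequence[str],
    n_records: int = 5,
    n_datasets: int = 20,
    seed: int = 0,
) -> tuple[float, int]:
    """Max change of any equivalence-class size over all one-record neighbors.

    Returns ``(max_change, n_pairs)`` where ``n_pairs`` counts the evaluated
    dataset/neighbor pairs across every lattice node.
    """
    rng = RandomSource(seed).child("class-count-sensitivity")
    lattice = build_lattice([trees[a] for a in dim_domains])
    worst, n_pairs = 0.0, 0
    for i in range(n_datasets):
        data = _random_dataset(rng.child(i), n_records, dim_domains, "Inf", inf_domain)
        for node in lattice:
            base = _class_counts(data, node, trees)
            for nb in neighbor_datasets(data, dim_domains):
                other = _class_counts(nb, node, trees)
                keys = set(base) | set(other)
                diff = max(abs(base.get(k, 0) - other.get(k, 0)) for k in keys)
                worst = max(worst, float(diff))
                n_pairs += 1
    return worst, n_pairs


def il_sensitivity(
    trees: Mapping[str, TaxonomyTree],
    dim_domains: Mapping[str, Sequence[str]],
    inf_domain: Sequence[str],
    n_records: int = 6,
    n_datasets: int = 10,
    t: int = 2,
    seed: int = 0,
) -> tuple[float, int]:
    """Max change of the total information loss over one-record neighbors.

    Each dataset is perturbed with the noise-free deterministic pipeline
    (fixed threshold t, no insertions) at every lattice node, and the loss of
    the resulting candidate is compared with the loss the same pipeline
    yields on each neighbor.  Returns ``(max_change, n_pairs)``.
    """
    from .mechanisms import PrivacyBudget

    rng = RandomSource(seed).child("il-sensitivity")
    budget = PrivacyBudget(1.0, 1.0, 1.0, 1.0)  # unused: the pipeline is noise-free
    overrides = PerturbOverrides(threshold=float(t), deltas={})
    lattice = build_lattice([trees[a] for a in dim_domains])

    def il_at(data: Microdata, node) -> float:
        cand = perturb_candidate(
            data, node, trees, budget, t, rng, overrides=overrides
        )
        return score_candidate(data, cand, trees).il

    worst, n_pairs = 0.0, 0
    for i in range(n_datasets):
        data = _random_dataset(rng.child(i), n_records, dim_domains, "Inf", inf_domain)
        neighbors = neighbor_datasets(data, dim_domains)
        for node in lattice:
            base = il_at(data, node)
            for nb in neighbors:
                worst = max(worst, abs(base - il_at(nb, node)))
                n_pairs += 1
    return worst, n_pairs
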
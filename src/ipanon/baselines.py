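"""Comparison methods: full-domain k-anonymization and the DP contingency table.

The k-anonymity baseline searches the same generalization lattice, suppresses
classes smaller than k (common full-domain practice; a strict no-suppression
mode is available), and deterministically returns the minimum-information-loss
node — no privacy budget is spent, which is exactly the weakness the
differentially private method addresses.

The contingency baseline materializes the full cross-product of the
generalized attribute domains (informative attribute included), adds
Laplace(1/eps) to every cell — present or not — and rounds/clamps the noisy
counts to non-negative integers, mirroring the classic noisy-histogram
release.  Its node is chosen as the minimum-loss node by exhaustive search
with no budget charged for the choice, which favors the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .anonymize import anonymize
from .loss import InfoLossReport, ncp_value, emd, score_candidate
from .mechanisms import PrivacyBudget, RandomSource, sample_laplace
from .microdata import Microdata
from .perturb import PerturbedCandidate, _generalize_frame, build_candidate, round_half_away
from .taxonomy import SUPPRESSED, TaxonomyTree, build_lattice

__all__ = [
    "KAnonResult",
    "ContingencyTable",
    "ContingencyResult",
    "k_anonymize",
    "dp_contingency",
    "contingency_loss",
    "reconstruct_candidate",
    "best_contingency",
    "compare_methods",
]

DEFAULT_CELL_CAP = 2_000_000


@dataclass
class KAnonResult:
    released: Microdata
    loss: InfoLossReport
    node: tuple[int, ...]
    n_suppressed_records: int
    k: int


def _node_sizes(data, node, trees):
    gdf = _generalize_frame(data, node, trees)
    dims = list(data.dim_attrs)
    keys = list(zip(*(gdf[a] for a in dims))) if len(gdf) else []
    from collections import Counter

    return gdf, Counter(keys)


def k_anonymize(
    data: Microdata, trees: Mapping[str, TaxonomyTree], k: int, suppress: bool = True
) -> KAnonResult:
    """Minimum-loss full-domain k-anonymization (deterministic, no DP).

    With ``suppress=True`` classes smaller than k are suppressed before the
    feasibility test, so every node is feasible and the search minimizes the
    loss of generalization plus suppression.  With ``suppress=False`` a node
    is feasible only if every class already has >= k records; if none is
    feasible even at the top, everything is suppressed as a fallback.
    """
    k = int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    q = len(data.dim_attrs)
    n = len(data)
    lattice = build_lattice([trees[a] for a in data.dim_attrs])

    best_node, best_ncp = None, math.inf
    for node in lattice:
        _, sizes = _node_sizes(data, node, trees)
        small = sum(s for s in sizes.values() if s < k)
        if not suppress and small > 0:
            continue
        # EMD and Rate vanish for k-anonymization (all informative values are
        # kept, nothing is inserted), so the loss reduces to NCP.
        if n == 0:
            ncp = 0.0
        else:
            label_cost = {
                a: {lbl: ncp_value(trees[a], lbl) for lbl in trees[a].labels_at_level(lvl)}
                for a, lvl in zip(data.dim_attrs, node)
            }
            total = 0.0
            for key, s in sizes.items():
                if s < k and suppress:
                    total += q * s
                else:
                    total += s * sum(
                        label_cost[a][lbl] for a, lbl in zip(data.dim_attrs, key)
                    )
            ncp = total / (n * q)
        if ncp < best_ncp - 1e-15:
            best_node, best_ncp = node, ncp

    if best_node is None:  # strict mode, nothing feasible: full suppression
        best_node = lattice.top

    # Materialize the winning node through the shared class machinery.
    gdf, sizes = _node_sizes(data, best_node, trees)
    dims = list(data.dim_attrs)
    keys = list(zip(*(gdf[a] for a in dims))) if len(gdf) else []
    feasible = all(s >= k for s in sizes.values())
    if not suppress and not feasible:
        supp_mask = np.ones(len(gdf), dtype=bool)
    else:
        supp_mask = np.fromiter((sizes[key] < k for key in keys), dtype=bool, count=len(keys))
    bucket = gdf.loc[supp_mask].copy()
    if len(bucket):
        bucket[dims] = SUPPRESSED
    bucket["is_counterfeit"] = False
    kept = gdf.loc[~supp_mask].copy()
    kept["is_counterfeit"] = False
    cand = build_candidate(
        best_node,
        data.dim_attrs,
        data.inf_attr,
        kept,
        bucket,
        n_suppressed_classes=sum(1 for s in sizes.values() if s < k),
    )
    loss = score_candidate(data, cand, trees)
    return KAnonResult(cand.to_microdata(data.inf_domain), loss, best_node, int(len(bucket)), k)


@dataclass
class ContingencyTable:
    """Noisy generalized contingency table over a full domain cross-product.

    ``cells`` has one row per combination of generalized dimension labels and
    informative value, with the exact count (``true``) and the rounded,
    clamped noisy count (``noisy``).
    """

    node: tuple[int, ...]
    cells: pd.DataFrame
    dim_attrs: tuple[str, ...]
    inf_attr: str

    def nonzero(self) -> pd.DataFrame:
        return self.cells[self.cells["noisy"] > 0].reset_index(drop=True)


@dataclass
class ContingencyResult:
    table: ContingencyTable
    loss: InfoLossReport
    node: tuple[int, ...]


def _n_cells(data, node, trees) -> int:
    n = len(data.inf_domain)
    for a, lvl in zip(data.dim_attrs, node):
        n *= len(trees[a].labels_at_level(lvl))
    return n


def dp_contingency(
    data: Microdata,
    trees: Mapping[str, TaxonomyTree],
    node,
    epsilon: float,
    rng: RandomSource,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> ContingencyTable:
    """Laplace-noised contingency table at one generalization node.

    Every combination of the generalized domain values (including combinations
    absent from the data) gets an independent Laplace(1/eps) perturbation;
    noisy counts are rounded to the nearest integer and clamped at 0.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    node = tuple(node)
    n_cells = _n_cells(data, node, trees)
    if n_cells > cell_cap:
        raise ValueError(
            f"domain cross-product has {n_cells} cells, exceeding the cap {cell_cap}"
        )
    dims = list(data.dim_attrs)
    label_lists = [trees[a].labels_at_level(lvl) for a, lvl in zip(dims, node)]
    idx = pd.MultiIndex.from_product(
        label_lists + [list(data.inf_domain)], names=dims + [data.inf_attr]
    )
    gdf = _generalize_frame(data, node, trees)
    if len(gdf):
        true = gdf.groupby(dims + [data.inf_attr]).size().reindex(idx, fill_value=0).to_numpy()
    else:
        true = np.zeros(n_cells, dtype=int)
    noise = sample_laplace(1.0 / epsilon, rng, size=n_cells)
    noisy = np.clip(round_half_away(true + noise), 0, None).astype(int)
    cells = idx.to_frame(index=False)
    cells["true"] = true
    cells["noisy"] = noisy
    return ContingencyTable(node, cells, data.dim_attrs, data.inf_attr)


def contingency_loss(
    ct: ContingencyTable, original: Microdata, trees: Mapping[str, TaxonomyTree]
) -> InfoLossReport:
    """Information loss of the microdata implied by a noisy contingency table.

    The implied microdata repeats each cell's rounded count; cell excess over
    the exact count is counterfeit mass.  Computed directly from the cell
    counts (equivalent to scoring the materialized reconstruction).
    """
    cells = ct.cells
    noisy = cells["noisy"].to_numpy()
    n_released = int(noisy.sum())
    if n_released == 0:
        return InfoLossReport(0.0, 0.0, 0.0)
    q = len(ct.dim_attrs)
    per_row = np.zeros(len(cells))
    for a in ct.dim_attrs:
        col = cells[a]
        cost = {lbl: ncp_value(trees[a], lbl) for lbl in col.unique()}
        per_row += col.map(cost).to_numpy()
    ncp = float((noisy * per_row).sum()) / (n_released * q)

    inf_counts = cells.assign(noisy=noisy).groupby(ct.inf_attr)["noisy"].sum()
    q_vec = np.array([inf_counts.get(v, 0) for v in original.inf_domain], dtype=float)
    emd_val = emd(original.inf_distribution(), q_vec / q_vec.sum()) if len(original) else 0.0

    counterfeit = np.maximum(0, noisy - cells["true"].to_numpy())
    grp = cells.assign(noisy=noisy, cf=counterfeit).groupby(list(ct.dim_attrs))
    sizes = grp["noisy"].sum()
    cfs = grp["cf"].sum()
    mask = sizes > 0
    rate = float((cfs[mask] / sizes[mask]).mean()) if mask.any() else 0.0
    return InfoLossReport(ncp=ncp, emd=emd_val, rate=rate)


def reconstruct_candidate(ct: ContingencyTable, original: Microdata) -> PerturbedCandidate:
    """Materialize the microdata implied by a noisy contingency table.

    Each cell emits ``noisy`` rows; rows beyond the exact count are flagged
    counterfeit.  Intended for small tables and cross-checks.
    """
    cells = ct.cells[ct.cells["noisy"] > 0]
    dims = list(ct.dim_attrs)
    rows = cells.loc[cells.index.repeat(cells["noisy"])].reset_index(drop=True)
    cf_flags = np.concatenate(
        [
            np.arange(c) >= t
            for c, t in zip(cells["noisy"], cells["true"])
        ]
    ) if len(cells) else np.array([], dtype=bool)
    rows = rows.drop(columns=["true", "noisy"])
    rows["is_counterfeit"] = cf_flags
    return build_candidate(
        ct.node,
        ct.dim_attrs,
        ct.inf_attr,
        rows,
        rows.iloc[0:0],
        n_inserted=int(cf_flags.sum()),
    )


def best_contingency(
    data: Microdata,
    trees: Mapping[str, TaxonomyTree],
    epsilon: float,
    rng: RandomSource,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> ContingencyResult:
    """Minimum-loss noisy contingency table over all lattice nodes under the cap."""
    lattice = build_lattice([trees[a] for a in data.dim_attrs])
    best = None
    for node in lattice:
        if _n_cells(data, node, trees) > cell_cap:
            continue
        ct = dp_contingency(data, trees, node, epsilon, rng.child("cells", node), cell_cap)
        loss = contingency_loss(ct, data, trees)
        if best is None or loss.il < best.loss.il:
            best = ContingencyResult(ct, loss, node)
    if best is None:
        raise ValueError("no lattice node fits under the contingency cell cap")
    return best


def compare_methods(
    data: Microdata,
    trees: Mapping[str, TaxonomyTree],
    epsilon: float,
    k: int,
    t: int,
    seed: int,
    shares=(0.1, 0.3, 0.3, 0.3),
    cell_cap: int = DEFAULT_CELL_CAP,
) -> dict:
    """Run the DP release, k-anonymization and the noisy contingency table on
    the same data and report the loss components of each."""
    budget = PrivacyBudget.from_total(epsilon, shares)
    ipa = anonymize(data, trees, budget, t, seed)
    kan = k_anonymize(data, trees, k)
    cont = best_contingency(data, trees, epsilon, RandomSource(seed).child("contingency"), cell_cap)
    return {
        "epsilon": epsilon,
        "k": k,
        "t": t,
        "seed": seed,
        "ipa": {"node": list(ipa.report["chosen_node"]), **{m: ipa.report[m] for m in ("ncp", "emd", "rate", "il", "u")}},
        "kanon": {"node": list(kan.node), **kan.loss.as_dict()},
        "contingency": {"node": list(cont.node), **cont.loss.as_dict()},
    }
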
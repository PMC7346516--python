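"""Information-loss scoring of perturbed candidates.

Three components, each in [0, 1], are summed into the total loss IL:

* **NCP** (normalized certainty penalty) — generalization loss.  A value
  generalized to a label covering ``|v|`` of the attribute's ``|L|`` leaves
  costs ``|v|/|L|`` (0 for raw leaves, 1 for ``"*"``); the dataset NCP is the
  mean per released record *and* per dimension attribute, so a fully
  suppressed dataset scores exactly 1.
* **EMD** — distortion of the informative-value distribution, measured as half
  the L1 distance between the original and released dataset-level
  distributions over the shared ordered domain (the categorical
  earth-mover's distance; at most 1, attained on disjoint supports).
* **Rate** — counterfeit contamination: the unweighted mean over kept,
  non-empty classes of (counterfeits in class) / (released class size).

IL = NCP + EMD + Rate lies in [0, 3]; the utility score is u = 3 - IL.  Each
component changes by at most 1 when one record is added or removed, so the
sensitivity of IL (and of u) is 3 — the constant the candidate-selection
exponential mechanism divides by.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .microdata import EquivalentClass, Microdata
from .perturb import PerturbedCandidate
from .taxonomy import SUPPRESSED, TaxonomyTree

__all__ = [
    "InfoLossReport",
    "ncp_value",
    "ncp_dataset",
    "emd",
    "rate_class",
    "rate_dataset",
    "score_candidate",
    "NCP_SENSITIVITY",
    "EMD_SENSITIVITY",
    "RATE_SENSITIVITY",
    "IL_SENSITIVITY",
    "UTILITY_SENSITIVITY",
]

NCP_SENSITIVITY = 1.0
EMD_SENSITIVITY = 1.0
RATE_SENSITIVITY = 1.0
IL_SENSITIVITY = 3.0
#: Sensitivity of the utility score u = 3 - IL, used by candidate selection.
UTILITY_SENSITIVITY = 3.0


@dataclass(frozen=True)
class InfoLossReport:
    """The three loss components, their sum, and the utility score."""

    ncp: float
    emd: float
    rate: float

    @property
    def il(self) -> float:
        return self.ncp + self.emd + self.rate

    @property
    def u(self) -> float:
        return 3.0 - self.il

    def as_dict(self) -> dict:
        return {
            "ncp": self.ncp,
            "emd": self.emd,
            "rate": self.rate,
            "il": self.il,
            "u": self.u,
        }


def ncp_value(tree: TaxonomyTree, label) -> float:
    """Per-value generalization penalty: 0 for leaves, |v|/|L| otherwise."""
    if str(label) == SUPPRESSED:
        return 1.0
    if tree.level_of(label) == 0:
        return 0.0
    return tree.leaf_count(label) / tree.n_leaves


def ncp_dataset(candidate: PerturbedCandidate, trees: Mapping[str, TaxonomyTree]) -> float:
    """Mean NCP over released records and dimension attributes, in [0, 1].

    Suppressed records contribute 1 per attribute; counterfeit records are
    released rows and count like any other.  An empty candidate scores 0.
    """
    q = len(candidate.dim_attrs)
    n = candidate.released_size
    if n == 0 or q == 0:
        return 0.0
    total = 0.0
    cost_cache: dict[tuple[str, str], float] = {}
    for key, size in zip(candidate.class_keys, candidate.class_sizes):
        if size == 0:
            continue
        per_record = 0.0
        for a, lbl in zip(candidate.dim_attrs, key):
            c = cost_cache.get((a, lbl))
            if c is None:
                c = cost_cache[(a, lbl)] = ncp_value(trees[a], lbl)
            per_record += c
        total += per_record * int(size)
    total += q * candidate.n_bucket
    return total / (n * q)


def emd(p, q) -> float:
    """Half the L1 distance between two aligned probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"distributions must be equal-length vectors, got {p.shape} and {q.shape}")
    for name, vec in (("p", p), ("q", q)):
        if abs(vec.sum() - 1.0) > 1e-9 or (vec < -1e-12).any():
            raise ValueError(f"{name} is not a probability vector (sum {vec.sum()!r})")
    return 0.5 * float(np.abs(p - q).sum())


def rate_class(ec: EquivalentClass) -> float:
    """Counterfeit fraction of a released class (post-insertion size)."""
    if ec.size == 0:
        raise ValueError("empty class has no counterfeit rate")
    return ec.counterfeit_count / ec.size


def rate_dataset(candidate: PerturbedCandidate) -> float:
    """Unweighted mean of class rates over kept non-empty classes.

    The suppressed bucket never receives counterfeits and is excluded; a
    candidate with no kept classes scores 0 by convention.
    """
    sizes = np.asarray(candidate.class_sizes, dtype=float)
    cfs = np.asarray(candidate.class_counterfeits, dtype=float)
    mask = sizes > 0
    return float((cfs[mask] / sizes[mask]).mean()) if mask.any() else 0.0


def _released_inf_distribution(candidate: PerturbedCandidate, inf_domain) -> np.ndarray:
    if candidate.released_size == 0:
        return np.zeros(len(inf_domain))
    counts = candidate.released[candidate.inf_attr].value_counts()
    vec = np.array([counts.get(v, 0) for v in inf_domain], dtype=float)
    return vec / vec.sum()


def score_candidate(
    original: Microdata,
    candidate: PerturbedCandidate,
    trees: Mapping[str, TaxonomyTree],
) -> InfoLossReport:
    """Compute NCP, EMD and Rate of a candidate against its original dataset.

    The EMD compares the informative-value distributions of the two datasets
    over the original's ordered domain.  The report is also attached to
    ``candidate.loss``.
    """
    ncp = ncp_dataset(candidate, trees)
    if candidate.released_size == 0 or len(original) == 0:
        emd_val = 0.0
    else:
        emd_val = emd(
            original.inf_distribution(),
            _released_inf_distribution(candidate, original.inf_domain),
        )
    report = InfoLossReport(ncp=ncp, emd=emd_val, rate=rate_dataset(candidate))
    candidate.loss = report
    return report
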
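"""Core differential-privacy primitives: Laplace noise, the exponential
mechanism, the privacy-budget accountant, and seeded randomness.

The release pipeline spends four separate budgets — on the suppression
threshold, on noisy class sizes (counterfeit insertion), on the informative
value of each counterfeit, and on the final candidate-dataset choice — and
reports their sum as the total guarantee under sequential composition.

All randomness flows through :class:`RandomSource`, which supports
deterministic derivation of independent child streams.  Laplace variates are
generated by inverse-CDF transform of exactly one uniform per draw, so the
number of uniforms consumed by any pipeline stage is a fixed function of the
data — two runs with the same seed are bit-identical, and changing one stage
cannot shift the draws of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RandomSource",
    "PrivacyBudget",
    "sample_laplace",
    "exponential_choice",
    "total_budget",
]

_MAX_SEED = 2**31


class RandomSource:
    """A seeded random stream with reproducible child derivation.

    ``child(*keys)`` hashes ``(seed, *keys)`` into a fresh seed, independent of
    how many draws the parent has consumed.  Stages of the release pipeline
    each take a named child (``"suppression"``, ``"insertion"``, ``"value"``,
    ``"candidates"``, per-node and per-class keys), so the outcome of one stage
    does not depend on the draw count of unrelated stages.
    """

    def __init__(self, seed: int):
        self.seed = int(seed) % _MAX_SEED
        self._gen = np.random.Generator(np.random.PCG64(self.seed))

    def child(self, *keys) -> "RandomSource":
        digest = hashlib.sha256(repr((self.seed,) + keys).encode()).digest()
        return RandomSource(int.from_bytes(digest[:4], "big") % _MAX_SEED)

    def uniform(self, size=None):
        """Uniform draw(s) on [0, 1)."""
        return self._gen.random(size)

    def integers(self, low, high, size=None):
        """Integer draw(s) on [low, high) — numpy half-open convention."""
        return self._gen.integers(low, high, size=size)

    def choice(self, a, size=None, p=None, replace=True):
        return self._gen.choice(a, size=size, p=p, replace=replace)

    def permutation(self, n: int) -> np.ndarray:
        return self._gen.permutation(n)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomSource(seed={self.seed})"


@dataclass(frozen=True)
class PrivacyBudget:
    """The four positive budget components spent by one release.

    Attributes
    ----------
    eps_suppression:
        Budget of the noisy suppression threshold.
    eps_insertion:
        Budget of the noisy per-class counterfeit counts.
    eps_value:
        Budget of the exponential mechanism choosing each counterfeit's
        informative value.
    eps_candidates:
        Budget of the exponential mechanism choosing the released dataset.
    """

    eps_suppression: float
    eps_insertion: float
    eps_value: float
    eps_candidates: float

    def __post_init__(self):
        for name in ("eps_suppression", "eps_insertion", "eps_value", "eps_candidates"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")

    def total(self) -> float:
        """Total guarantee under sequential composition."""
        return self.eps_suppression + self.eps_insertion + self.eps_value + self.eps_candidates

    @classmethod
    def from_total(
        cls, total: float, shares: Sequence[float] = (0.1, 0.3, 0.3, 0.3)
    ) -> "PrivacyBudget":
        """Split a total budget into the four components.

        The default shares (0.1, 0.3, 0.3, 0.3) give the standard split used
        for evaluation at total budget 1.
        """
        if total <= 0:
            raise ValueError("total budget must be positive")
        if len(shares) != 4 or any(s <= 0 for s in shares):
            raise ValueError("shares must be four positive reals")
        s = float(sum(shares))
        return cls(*(total * x / s for x in shares))


def total_budget(budget: PrivacyBudget) -> float:
    """Sum of the four budget components (sequential composition)."""
    return budget.total()


def sample_laplace(scale: float, rng: RandomSource, size=None):
    """Draw from Laplace(0, scale) by inverse-CDF of one uniform per variate.

    Parameters
    ----------
    scale:
        The Laplace scale b > 0; the variance is 2 b**2.
    size:
        None for a scalar float, else an array shape.
    """
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"Laplace scale must be positive, got {scale!r}")
    u = np.asarray(rng.uniform(size))
    centered = u - 0.5
    # Clip the log argument away from 0 so u == 0 cannot produce inf.
    arg = np.clip(1.0 - 2.0 * np.abs(centered), 1e-300, None)
    x = -scale * np.sign(centered) * np.log(arg)
    return float(x) if size is None else x


def exponential_choice(items, scores, epsilon: float, sensitivity: float, rng: RandomSource):
    """Select one item with probability proportional to exp(eps*score/(2*Delta)).

    Scores are shifted by their maximum before exponentiation so the
    normalization is numerically stable for any epsilon.
    """
    items = list(items)
    scores = np.asarray(list(scores), dtype=float)
    if len(items) == 0:
        raise ValueError("exponential_choice needs at least one item")
    if len(items) != len(scores):
        raise ValueError(f"{len(items)} items but {len(scores)} scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not np.isfinite(epsilon) or epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon!r}")
    if not np.isfinite(sensitivity) or sensitivity <= 0:
        raise ValueError(f"sensitivity must be positive, got {sensitivity!r}")

    logw = (epsilon / (2.0 * sensitivity)) * scores
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    r = float(rng.uniform())
    idx = int(np.searchsorted(np.cumsum(probs), r, side="right"))
    return items[min(idx, len(items) - 1)]
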
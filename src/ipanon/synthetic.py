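"""Synthetic electronic-health-record generator.

Emulates the schema of a national insurance claims sample: Age (0-99), Sex,
a 5-digit Zipcode-like region code, an integer length-of-stay, a surgery
flag, and a skewed large-domain Disease code used as the informative
attribute.  Dimension attributes are drawn uniformly over their declared
domains; the disease follows a power-law (Zipf-like) frequency profile, with
an optional age-disease association that rotates the frequency ranking by
the patient's age decade.

The zip-like code is drawn from a small set of region-representative codes
(``n_zip_codes`` values spread evenly over the 5-digit range) rather than
from all 90,000 codes: location codes in claims data identify regions or
facilities, a domain of tens of values, and this keeps the records-per-class
density of a desk-scale sample in the same regime as a multi-million-record
national sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mechanisms import RandomSource
from .microdata import Microdata
from .taxonomy import CategoricalTaxonomy, IntervalTaxonomy, TaxonomyTree

__all__ = ["SyntheticConfig", "generate_synthetic", "disease_domain", "default_trees"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults define the standard study conditions."""

    n_records: int = 10_000
    age_range: tuple[int, int] = (0, 99)
    sexes: tuple[str, ...] = ("F", "M")
    zip_range: tuple[int, int] = (10000, 99999)
    n_zip_codes: int = 18
    los_range: tuple[int, int] = (1, 30)
    surgery: tuple[str, ...] = ("N", "Y")
    n_diseases: int = 50
    disease_skew: float = 1.0
    age_disease_assoc: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if self.n_diseases < 1:
            raise ValueError("disease domain must be non-empty")
        if self.disease_skew < 0:
            raise ValueError("disease_skew must be >= 0")
        if not 0.0 <= self.age_disease_assoc <= 1.0:
            raise ValueError("age_disease_assoc must be in [0, 1]")
        if self.n_zip_codes < 1:
            raise ValueError("n_zip_codes must be >= 1")
        for name in ("age_range", "zip_range", "los_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty")


def disease_domain(n: int) -> tuple[str, ...]:
    """Ordered disease codes D01..Dnn (zero-padded)."""
    width = max(2, len(str(n)))
    return tuple(f"D{i:0{width}d}" for i in range(1, n + 1))


def generate_synthetic(cfg: SyntheticConfig) -> Microdata:
    """Draw a reproducible synthetic microdata table from the config."""
    rng = RandomSource(cfg.seed).child("synthetic")
    n = cfg.n_records
    domain = disease_domain(cfg.n_diseases)

    ranks = np.arange(1, cfg.n_diseases + 1, dtype=float)
    base = ranks ** (-cfg.disease_skew)
    base /= base.sum()

    ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)
    diseases = np.empty(n, dtype=object)
    if cfg.age_disease_assoc > 0 and n:
        use_assoc = rng.uniform(size=n) < cfg.age_disease_assoc
        decades = ages // 10
        for d in np.unique(decades):
            sel = use_assoc & (decades == d)
            if sel.any():
                # Shift the frequency ranking with age so each decade favors
                # a different slice of the disease domain.
                probs = np.roll(base, int(d))
                diseases[sel] = rng.choice(np.array(domain, dtype=object), size=int(sel.sum()), p=probs)
        rest = ~use_assoc
    else:
        rest = np.ones(n, dtype=bool)
    if rest.any():
        diseases[rest] = rng.choice(np.array(domain, dtype=object), size=int(rest.sum()), p=base)

    lo, hi = cfg.zip_range
    zip_codes = np.linspace(lo, hi, cfg.n_zip_codes + 2)[1:-1].astype(int)
    df = pd.DataFrame(
        {
            "Age": ages.astype(str),
            "Sex": rng.choice(np.array(cfg.sexes, dtype=object), size=n),
            "Zipcode": rng.choice(zip_codes, size=n).astype(str),
            "LengthOfStay": rng.integers(cfg.los_range[0], cfg.los_range[1] + 1, size=n).astype(str),
            "Surgery": rng.choice(np.array(cfg.surgery, dtype=object), size=n),
            "Disease": diseases,
        }
    )
    return Microdata.build(
        df,
        dim_attrs=("Age", "Sex", "Zipcode", "LengthOfStay", "Surgery"),
        inf_attr="Disease",
        inf_domain=domain,
    )


def default_trees(cfg: SyntheticConfig = SyntheticConfig()) -> dict[str, TaxonomyTree]:
    """Taxonomy trees matching the synthetic schema's domains."""
    return {
        "Age": IntervalTaxonomy("Age", *cfg.age_range, widths=[10]),
        "Sex": CategoricalTaxonomy("Sex", cfg.sexes, [[["*", list(cfg.sexes)]]]),
        "Zipcode": IntervalTaxonomy("Zipcode", *cfg.zip_range, widths=[10000]),
        "LengthOfStay": IntervalTaxonomy("LengthOfStay", *cfg.los_range, widths=[10]),
        "Surgery": CategoricalTaxonomy("Surgery", cfg.surgery, [[["*", list(cfg.surgery)]]]),
    }
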
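"""Worked-example tables used throughout the docs and tests.

Two tiny reference tables ship with the package: a five-record Age/Gender/
Disease table (``table1``) illustrating the noisy contingency baseline, and a
seven-record Age/Gender/Zipcode/Disease table (``table5``) whose
generalization, suppression and insertion steps are fully worked by hand.
The matching taxonomy trees use decade bands for Age and 10,000-wide bands
for the 5-digit Zipcode.
"""

from __future__ import annotations

from .microdata import Microdata
from .taxonomy import CategoricalTaxonomy, IntervalTaxonomy, TaxonomyTree

__all__ = ["load_fixture", "fixture_trees"]

_TABLE1 = [
    ("10", "M", "Anemia"),
    ("14", "F", "Gastritis"),
    ("19", "F", "Pneumonia"),
    ("12", "F", "Anemia"),
    ("15", "M", "Pneumonia"),
]

_TABLE5 = [
    ("17", "M", "28912", "Gastritis"),
    ("16", "M", "23512", "Pneumonia"),
    ("13", "M", "24231", "Pneumonia"),
    ("24", "F", "31891", "Anemia"),
    ("29", "F", "34225", "Anemia"),
    ("25", "F", "37756", "Diabetes"),
    ("67", "M", "80061", "Stroke"),
]


def load_fixture(name: str) -> Microdata:
    """Return one of the worked-example tables (``"table1"`` or ``"table5"``)."""
    if name == "table1":
        return Microdata.from_records(_TABLE1, ("Age", "Gender"), "Disease")
    if name == "table5":
        return Microdata.from_records(_TABLE5, ("Age", "Gender", "Zipcode"), "Disease")
    raise ValueError(f"unknown fixture {name!r}")


def fixture_trees(name: str) -> dict[str, TaxonomyTree]:
    """Taxonomy trees for a fixture's dimension attributes."""
    age = IntervalTaxonomy("Age", 0, 99, widths=[10])
    gender = CategoricalTaxonomy("Gender", ["M", "F"], [[["*", ["M", "F"]]]])
    if name == "table1":
        return {"Age": age, "Gender": gender}
    if name == "table5":
        return {
            "Age": age,
            "Gender": gender,
            "Zipcode": IntervalTaxonomy("Zipcode", 10000, 99999, widths=[10000]),
        }
    raise ValueError(f"unknown fixture {name!r}")
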
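"""Per-attribute generalization hierarchies and the full-domain lattice.

A *taxonomy tree* maps raw attribute values (leaves, level 0) to increasingly
general labels, up to the root ``"*"`` which covers the whole domain.  A node
vector of per-attribute levels identifies one full-domain generalization; the
set of all level combinations forms the generalization lattice searched by the
anonymizer.

Two concrete tree types are provided:

* :class:`CategoricalTaxonomy` — every level's grouping enumerated explicitly.
* :class:`IntervalTaxonomy` — a regular interval hierarchy over a finite
  integer domain (width-w bands rendered as ``"[lo-hi]"`` with inclusive
  bounds), stored implicitly so large domains (e.g. 5-digit zip codes) cost
  nothing to hold.
"""

from __future__ import annotations

import abc
import itertools
import json
import re
from pathlib import Path
from typing import Sequence

__all__ = [
    "TaxonomyTree",
    "CategoricalTaxonomy",
    "IntervalTaxonomy",
    "GeneralizationLattice",
    "load_taxonomy",
    "load_taxonomies",
    "build_lattice",
    "SUPPRESSED",
]

#: Label reserved for the root of every tree and for suppressed cells.
SUPPRESSED = "*"

_INTERVAL_RE = re.compile(r"^\[(\d+)-(\d+)\]$")


class TaxonomyTree(abc.ABC):
    """Common interface of generalization hierarchies."""

    attribute: str

    @property
    @abc.abstractmethod
    def height(self) -> int:
        """Level index of the root; leaves sit at level 0."""

    @property
    @abc.abstractmethod
    def n_leaves(self) -> int:
        """Total number of raw domain values |L|."""

    @abc.abstractmethod
    def generalize(self, value, level: int):
        """Unique ancestor label of a raw leaf value at the given level."""

    @abc.abstractmethod
    def leaf_count(self, label) -> int:
        """Number of leaves covered by a label, |v|."""

    @abc.abstractmethod
    def level_of(self, label) -> int:
        """Level at which a label lives; raises on unknown labels."""

    @abc.abstractmethod
    def labels_at_level(self, level: int) -> list:
        """All labels of one level, in canonical order."""

    @abc.abstractmethod
    def extent(self, label):
        """Set of leaves under a label: an inclusive ``(lo, hi)`` integer pair
        for interval trees, a ``frozenset`` for categorical trees."""

    def _check_level(self, level: int) -> None:
        if not 0 <= level <= self.height:
            raise ValueError(
                f"{self.attribute}: level {level} out of range 0..{self.height}"
            )


class CategoricalTaxonomy(TaxonomyTree):
    """Explicitly enumerated hierarchy.

    Parameters
    ----------
    attribute:
        Attribute name.
    leaves:
        Ordered raw domain values (coerced to str).
    levels:
        One entry per level above the leaves; each entry is a list of
        ``(label, members)`` groups whose members are labels of the level
        below.  Every level must partition the level below (no overlap, no
        orphan) and the final level must be the single root ``"*"``.
    """

    def __init__(self, attribute: str, leaves: Sequence, levels: Sequence):
        self.attribute = str(attribute)
        leaf_labels = [str(v) for v in leaves]
        if not leaf_labels:
            raise ValueError(f"{attribute}: empty leaf set")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise ValueError(f"{attribute}: duplicate leaves")
        self._leaves = leaf_labels
        self._level_of = {lf: 0 for lf in leaf_labels}
        self._parent: dict[str, str] = {}
        self._leaf_count = {lf: 1 for lf in leaf_labels}
        self._extent = {lf: frozenset([lf]) for lf in leaf_labels}
        self._labels_by_level: list[list[str]] = [list(leaf_labels)]

        prev = list(leaf_labels)
        for lvl, groups in enumerate(levels, start=1):
            seen_members: set[str] = set()
            level_labels: list[str] = []
            for label, members in groups:
                label = str(label)
                if label in self._level_of:
                    raise ValueError(f"{attribute}: duplicate label {label!r}")
                members = [str(m) for m in members]
                if not members:
                    raise ValueError(f"{attribute}: empty group {label!r} at level {lvl}")
                ext: set[str] = set()
                for m in members:
                    if m not in {p for p in prev}:
                        raise ValueError(
                            f"{attribute}: group {label!r} at level {lvl} references "
                            f"unknown member {m!r}"
                        )
                    if m in seen_members:
                        raise ValueError(
                            f"{attribute}: overlapping extents at level {lvl}: "
                            f"{m!r} grouped twice"
                        )
                    seen_members.add(m)
                    self._parent[m] = label
                    ext |= self._extent[m]
                self._level_of[label] = lvl
                self._leaf_count[label] = len(ext)
                self._extent[label] = frozenset(ext)
                level_labels.append(label)
            missing = set(prev) - seen_members
            if missing:
                raise ValueError(
                    f"{attribute}: level {lvl} leaves {sorted(missing)!r} orphaned "
                    "(value missing from every group)"
                )
            self._labels_by_level.append(level_labels)
            prev = level_labels

        if len(prev) != 1 or prev[0] != SUPPRESSED:
            raise ValueError(
                f"{attribute}: top level must be the single root {SUPPRESSED!r}, got {prev!r}"
            )
        # Ancestor lookup per level: anc[level][leaf] -> label.
        self._anc: list[dict[str, str]] = [{lf: lf for lf in leaf_labels}]
        for lvl in range(1, self.height + 1):
            self._anc.append({lf: self._parent[self._anc[lvl - 1][lf]] for lf in leaf_labels})

    @property
    def height(self) -> int:
        return len(self._labels_by_level) - 1

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def leaves(self) -> list[str]:
        return list(self._leaves)

    @property
    def parent_of(self) -> dict[str, str]:
        return dict(self._parent)

    @property
    def label_leaf_count(self) -> dict[str, int]:
        return dict(self._leaf_count)

    def generalize(self, value, level: int):
        self._check_level(level)
        key = str(value)
        if key not in self._level_of or self._level_of[key] != 0:
            raise ValueError(f"{self.attribute}: unknown value {value!r}")
        return value if level == 0 else self._anc[level][key]

    def leaf_count(self, label) -> int:
        try:
            return self._leaf_count[str(label)]
        except KeyError:
            raise ValueError(f"{self.attribute}: unknown label {label!r}") from None

    def level_of(self, label) -> int:
        try:
            return self._level_of[str(label)]
        except KeyError:
            raise ValueError(f"{self.attribute}: unknown label {label!r}") from None

    def labels_at_level(self, level: int) -> list:
        self._check_level(level)
        return list(self._labels_by_level[level])

    def extent(self, label):
        try:
            return self._extent[str(label)]
        except KeyError:
            raise ValueError(f"{self.attribute}: unknown label {label!r}") from None


class IntervalTaxonomy(TaxonomyTree):
    """Regular interval hierarchy over an inclusive integer range.

    Level k (1-based) groups the domain into aligned bands of ``widths[k-1]``
    values labelled ``"[lo-hi]"``; the top level is the root ``"*"``.  Widths
    must be strictly increasing, each band width must divide the next, and
    every width must divide the domain span so each level partitions the
    leaves exactly.
    """

    def __init__(self, attribute: str, lo: int, hi: int, widths: Sequence[int]):
        self.attribute = str(attribute)
        lo, hi = int(lo), int(hi)
        if hi < lo:
            raise ValueError(f"{attribute}: empty integer domain [{lo}, {hi}]")
        if lo < 0:
            raise ValueError(f"{attribute}: negative domains not supported")
        span = hi - lo + 1
        widths = [int(w) for w in widths]
        if not widths:
            raise ValueError(f"{attribute}: at least one band width required")
        prev = 1
        for w in widths:
            if w <= prev:
                raise ValueError(f"{attribute}: widths must be strictly increasing, got {widths}")
            if w % prev != 0:
                raise ValueError(f"{attribute}: width {w} does not nest in {prev}")
            if span % w != 0 or w >= span:
                raise ValueError(
                    f"{attribute}: width {w} does not partition domain of span {span}"
                )
            prev = w
        self.lo, self.hi = lo, hi
        self.widths = tuple(widths)

    @property
    def height(self) -> int:
        return len(self.widths) + 1

    @property
    def n_leaves(self) -> int:
        return self.hi - self.lo + 1

    def _as_int(self, value) -> int:
        try:
            v = int(value)
        except (TypeError, ValueError):
            raise ValueError(f"{self.attribute}: unknown value {value!r}") from None
        if not self.lo <= v <= self.hi:
            raise ValueError(f"{self.attribute}: value {value!r} outside [{self.lo}, {self.hi}]")
        return v

    def generalize(self, value, level: int):
        self._check_level(level)
        v = self._as_int(value)
        if level == 0:
            return value
        if level == self.height:
            return SUPPRESSED
        w = self.widths[level - 1]
        start = self.lo + ((v - self.lo) // w) * w
        return f"[{start}-{start + w - 1}]"

    def _parse(self, label) -> tuple[int, int, int]:
        """Return (lo, hi, level) for any valid label of this tree."""
        s = str(label)
        if s == SUPPRESSED:
            return self.lo, self.hi, self.height
        m = _INTERVAL_RE.match(s)
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            w = b - a + 1
            if w in self.widths and self.lo <= a <= b <= self.hi and (a - self.lo) % w == 0:
                return a, b, self.widths.index(w) + 1
            raise ValueError(f"{self.attribute}: unknown label {label!r}")
        return (lambda v: (v, v, 0))(self._as_int(s))

    def leaf_count(self, label) -> int:
        a, b, _ = self._parse(label)
        return b - a + 1

    def level_of(self, label) -> int:
        return self._parse(label)[2]

    def labels_at_level(self, level: int) -> list:
        self._check_level(level)
        if level == 0:
            return [str(v) for v in range(self.lo, self.hi + 1)]
        if level == self.height:
            return [SUPPRESSED]
        w = self.widths[level - 1]
        return [f"[{s}-{s + w - 1}]" for s in range(self.lo, self.hi + 1, w)]

    def extent(self, label) -> tuple[int, int]:
        a, b, _ = self._parse(label)
        return a, b


class GeneralizationLattice:
    """All per-attribute level combinations, ordered componentwise.

    Nodes are tuples of levels aligned with the tree order; iteration yields
    nodes in lexicographic order (bottom = all zeros first).
    """

    def __init__(self, trees: Sequence[TaxonomyTree]):
        trees = list(trees)
        if not trees:
            raise ValueError("lattice needs at least one taxonomy tree")
        self.trees = trees
        self.heights = tuple(t.height for t in trees)
        self.nodes = [tuple(n) for n in itertools.product(*(range(h + 1) for h in self.heights))]

    @classmethod
    def from_heights(cls, heights: Sequence[int]) -> "GeneralizationLattice":
        """Enumeration-only lattice built from bare heights (no trees)."""
        obj = cls.__new__(cls)
        obj.trees = []
        obj.heights = tuple(int(h) for h in heights)
        if not obj.heights:
            raise ValueError("lattice needs at least one height")
        obj.nodes = [tuple(n) for n in itertools.product(*(range(h + 1) for h in obj.heights))]
        return obj

    @property
    def bottom(self) -> tuple:
        return tuple(0 for _ in self.heights)

    @property
    def top(self) -> tuple:
        return self.heights

    @staticmethod
    def dominates(a: tuple, b: tuple) -> bool:
        """Componentwise partial order: a >= b in every coordinate."""
        return all(x >= y for x, y in zip(a, b))

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)


def build_lattice(trees: Sequence[TaxonomyTree]) -> GeneralizationLattice:
    """Combine per-attribute taxonomy trees into the full-domain lattice."""
    return GeneralizationLattice(trees)


def load_taxonomy(doc) -> TaxonomyTree:
    """Build a taxonomy tree from a configuration document.

    ``doc`` may be a dict, or a path to a JSON/YAML file holding one.  Two
    forms are accepted::

        {"attribute": "Age", "type": "integer", "range": [0, 99], "widths": [10]}
        {"attribute": "Sex", "type": "categorical", "leaves": ["M", "F"],
         "levels": [[["*", ["M", "F"]]]]}

    An integer document may also enumerate explicit ``levels`` over its range,
    in which case it is treated as a categorical tree with numeric leaf labels.
    """
    if isinstance(doc, (str, Path)):
        doc = _read_structured(Path(doc))
    if not isinstance(doc, dict):
        raise ValueError(f"taxonomy document must be a mapping, got {type(doc).__name__}")
    try:
        attribute = doc["attribute"]
        kind = doc["type"]
    except KeyError as e:
        raise ValueError(f"taxonomy document missing key {e.args[0]!r}") from None

    if kind == "integer":
        if "range" not in doc:
            raise ValueError(f"{attribute}: integer taxonomy needs a 'range'")
        lo, hi = doc["range"]
        if "widths" in doc:
            return IntervalTaxonomy(attribute, lo, hi, doc["widths"])
        if "levels" in doc:
            leaves = [str(v) for v in range(int(lo), int(hi) + 1)]
            return CategoricalTaxonomy(attribute, leaves, doc["levels"])
        raise ValueError(f"{attribute}: integer taxonomy needs 'widths' or 'levels'")
    if kind == "categorical":
        if "leaves" not in doc or "levels" not in doc:
            raise ValueError(f"{attribute}: categorical taxonomy needs 'leaves' and 'levels'")
        return CategoricalTaxonomy(attribute, doc["leaves"], doc["levels"])
    raise ValueError(f"{attribute}: unknown taxonomy type {kind!r}")


def load_taxonomies(path) -> dict[str, TaxonomyTree]:
    """Load a file holding a list of taxonomy documents; returns name -> tree."""
    docs = _read_structured(Path(path))
    if isinstance(docs, dict) and "attributes" in docs:
        docs = docs["attributes"]
    if not isinstance(docs, list):
        raise ValueError("taxonomy file must hold a list of documents")
    trees = [load_taxonomy(d) for d in docs]
    return {t.attribute: t for t in trees}


def _read_structured(path: Path):
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
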
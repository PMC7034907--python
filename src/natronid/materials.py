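"""Chemical compositions, materials and the bundled material registry.

A :class:`Composition` is an element→count map parsed from a conventional
chemical formula (``"NaCl"``, ``"Ca10(PO4)6(OH)2"``, hydrate notation
``"Na2CO3.10H2O"``).  A :class:`Material` pairs a composition with a bulk
density, which is all the attenuation engine needs.  Minerals that occur as a
hydration series with strongly hydration-dependent density (sodium carbonate,
sodium sulphate) are represented by :class:`HydrationSeries`, which exposes its
anhydrous and decahydrate endpoints as ordinary materials; intermediate
hydrates require a user-supplied density because real hydrate densities are
not linear in the water count.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterator, List, Tuple, Union

from .errors import FormulaError

__all__ = [
    "ATOMIC_MASS",
    "Composition",
    "Material",
    "HydrationSeries",
    "parse_formula",
    "Registry",
    "default_registry",
]


def _load_atomic_masses() -> Dict[str, float]:
    with resources.files("natronid.data").joinpath("atomic_weights.csv").open() as f:
        return {r["element"]: float(r["atomic_mass_g_mol"]) for r in csv.DictReader(f)}


#: Standard atomic weights (g/mol) for every element in the bundled tables.
ATOMIC_MASS: Dict[str, float] = _load_atomic_masses()

_TOKEN = re.compile(r"([A-Z][a-z]?)|(\d+)|([().])|(\S)")


@dataclass(frozen=True)
class Composition:
    """Element symbol → atom count (positive, possibly non-integer)."""

    counts: Tuple[Tuple[str, float], ...]

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "Composition":
        return cls(tuple(sorted((el, float(n)) for el, n in d.items() if n)))

    def as_dict(self) -> Dict[str, float]:
        return dict(self.counts)

    def items(self) -> Iterator[Tuple[str, float]]:
        return iter(self.counts)

    @property
    def molar_mass(self) -> float:
        """Formula mass in g/mol."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.counts)

    def mass_fractions(self) -> Dict[str, float]:
        """Per-element mass fractions; sum to 1 by construction."""
        m = self.molar_mass
        return {el: ATOMIC_MASS[el] * n / m for el, n in self.counts}

    def combine(self, other: "Composition", n: float = 1.0) -> "Composition":
        """Return this composition plus ``n`` formula units of ``other``."""
        d = self.as_dict()
        for el, cnt in other.items():
            d[el] = d.get(el, 0.0) + n * cnt
        return Composition.from_dict(d)


def _parse_group(tokens: List[str], pos: int, formula: str) -> Tuple[Dict[str, float], int]:
    counts: Dict[str, float] = {}
    saw_item = False
    while pos < len(tokens):
        tok = tokens[pos]
        if tok == ")":
            break
        if tok == "(":
            inner, pos = _parse_group(tokens, pos + 1, formula)
            if pos >= len(tokens) or tokens[pos] != ")":
                raise FormulaError(f"unbalanced '(' in {formula!r}")
            pos += 1
            mult = 1.0
            if pos < len(tokens) and tokens[pos].isdigit():
                mult = float(tokens[pos])
                pos += 1
            for el, n in inner.items():
                counts[el] = counts.get(el, 0.0) + mult * n
            saw_item = True
        elif re.fullmatch(r"[A-Z][a-z]?", tok):
            if tok not in ATOMIC_MASS:
                raise FormulaError(f"unknown element {tok!r} in {formula!r}")
            pos += 1
            n = 1.0
            if pos < len(tokens) and tokens[pos].isdigit():
                n = float(tokens[pos])
                pos += 1
            counts[tok] = counts.get(tok, 0.0) + n
            saw_item = True
        else:
            raise FormulaError(f"unexpected token {tok!r} in {formula!r}")
    if not saw_item:
        raise FormulaError(f"empty group in {formula!r}")
    return counts, pos


def parse_formula(formula: str) -> Composition:
    """Parse a chemical formula into a :class:`Composition`.

    Supports element symbols with integer counts, nested parentheses, and
    dot-separated hydrate/adduct parts with a leading multiplier
    (``"Na2CO3.10H2O"`` → Na₂CO₃ plus 10 H₂O; counts are additive across
    parts).  The mid-dot ``·`` is accepted as a synonym for ``.``.

    Raises
    ------
    FormulaError
        On an unknown element symbol or malformed nesting, naming the
        offending token.
    """
    total: Dict[str, float] = {}
    for part in formula.replace("·", ".").split("."):
        part = part.strip()
        if not part:
            raise FormulaError(f"empty formula part in {formula!r}")
        m = re.match(r"^(\d+)", part)
        mult = 1.0
        if m:
            mult = float(m.group(1))
            part = part[m.end():]
            if not part:
                raise FormulaError(f"dangling multiplier in {formula!r}")
        tokens = []
        for mt in _TOKEN.finditer(part):
            if mt.group(4):
                raise FormulaError(f"unexpected character {mt.group(4)!r} in {formula!r}")
            tokens.append(mt.group(0))
        counts, pos = _parse_group(tokens, 0, formula)
        if pos != len(tokens):
            raise FormulaError(f"unbalanced ')' in {formula!r}")
        for el, n in counts.items():
            total[el] = total.get(el, 0.0) + mult * n
    return Composition.from_dict(total)


@dataclass(frozen=True)
class Material:
    """A named composition with bulk density in g/cm³."""

    name: str
    composition: Composition
    density: float

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")

    def with_density(self, density: float) -> "Material":
        return Material(self.name, self.composition, density)


_WATER = parse_formula("H2O")


@dataclass(frozen=True)
class HydrationSeries:
    """A mineral hydrated from 0 to ``n_max`` waters, with endpoint densities.

    Only the endpoints carry bundled densities (the anhydrous and the
    decahydrate form); anything in between needs an explicit density.
    """

    name: str
    base: Composition
    density_anhydrous: float
    density_decahydrate: float
    n_max: int = 10

    def __post_init__(self):
        if self.density_anhydrous <= 0 or self.density_decahydrate <= 0:
            raise ValueError(f"series {self.name!r}: endpoint densities must be > 0")

    def hydrate_composition(self, n_water: int) -> Composition:
        if not 0 <= n_water <= self.n_max:
            raise ValueError(f"n_water must be in 0..{self.n_max}")
        return self.base.combine(_WATER, n_water)

    def endpoints(self) -> Tuple[Material, Material]:
        """(anhydrous, decahydrate) endpoint materials."""
        anh = Material(f"{self.name}_anhydrous", self.base, self.density_anhydrous)
        deca = Material(
            f"{self.name}_decahydrate",
            self.hydrate_composition(self.n_max),
            self.density_decahydrate,
        )
        return anh, deca


Candidate = Union[Material, HydrationSeries]


@dataclass
class Registry:
    """Bundled material table (mirrors the published natron-constituent table)."""

    _materials: Dict[str, Material] = field(default_factory=dict)
    _series: Dict[str, HydrationSeries] = field(default_factory=dict)
    _roles: Dict[str, str] = field(default_factory=dict)

    def names(self) -> List[str]:
        return sorted(set(self._materials) | set(self._series))

    def __contains__(self, name: str) -> bool:
        return name in self._materials or name in self._series

    def is_series(self, name: str) -> bool:
        return name in self._series

    def role(self, name: str) -> str:
        return self._roles[name]

    def get(self, name: str, density: float | None = None) -> Material:
        """Resolve a solid material, optionally overriding its density."""
        if name in self._materials:
            mat = self._materials[name]
            return mat.with_density(density) if density is not None else mat
        if name in self._series:
            raise KeyError(
                f"{name!r} is a hydration series; use get_series() or name an endpoint"
            )
        raise KeyError(f"unknown material {name!r}; known: {', '.join(self.names())}")

    def get_series(self, name: str) -> HydrationSeries:
        try:
            return self._series[name]
        except KeyError:
            raise KeyError(f"unknown hydration series {name!r}") from None

    def candidate(self, name: str) -> Candidate:
        if name in self._series:
            return self._series[name]
        return self.get(name)

    def natron_candidates(self) -> List[Candidate]:
        """The five natron constituents, in bundled-table order."""
        out: List[Candidate] = []
        for name, role in self._roles.items():
            if role == "candidate":
                out.append(self.candidate(name))
        return out


@lru_cache(maxsize=1)
def default_registry() -> Registry:
    reg = Registry()
    with resources.files("natronid.data").joinpath("materials.csv").open() as f:
        for row in csv.DictReader(f):
            name = row["name"]
            comp = parse_formula(row["formula"])
            reg._roles[name] = row["role"]
            if row["kind"] == "series":
                reg._series[name] = HydrationSeries(
                    name,
                    comp,
                    float(row["density_anhydrous_g_cm3"]),
                    float(row["density_decahydrate_g_cm3"]),
                )
            else:
                reg._materials[name] = Material(name, comp, float(row["density_g_cm3"]))
    return reg
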
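"""Pathway chemistry: compounds, elemental formulas, reaction topology.

The measured pathway runs from mevalonate (MEV) through mevalonate
5-phosphate (M5P) and mevalonate 5-pyrophosphate (M5PP) to the prenyl
pyrophosphates: isopentenyl / dimethylallyl pyrophosphate (IPP/DMAPP,
isobaric and chromatographically unresolved, treated as one merged pool),
geranyl- (GPP), farnesyl- (FPP) and geranylgeranyl pyrophosphate (GGPP).
This module provides the domain types (:class:`ElementalFormula`,
:class:`MetaboliteSpec`, :class:`PathwaySpec`) plus the two targeted-MS
bookkeeping operations: exact deprotonated ion masses for tSIM acquisition
and isotopologue accounting for an isotope labeling experiment (ILE).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "MetaboliteSpec",
    "Pool",
    "Reaction",
    "PathwaySpec",
    "IsotopologueCount",
    "exact_mz",
    "count_isotopologues",
    "default_pathway",
    "load_pathway",
]

#: Monoisotopic masses (Da) of the lightest stable isotope of each
#: supported element (CODATA/NIST values, >=6 decimals).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Mass of a proton (Da); the electron mass is accounted for, i.e. this is
#: m(1H) - m(e-), the mass removed when forming the [M-H]- anion.
PROTON_MASS = 1.007276466879

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition of a neutral molecule, e.g. ``C20H36O7P2``.

    Stored as a sorted tuple of ``(element, count)`` pairs so instances are
    hashable; construct from a Hill-style string with :meth:`from_string`.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for element, count in self.counts:
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise ValueError(f"element count must be a non-negative integer: {element}={count!r}")
            if element in seen:
                raise ValueError(f"duplicate element symbol: {element!r}")
            seen[element] = count
        if sum(c for _, c in self.counts) < 1:
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        """Parse ``'C6H12O4'`` style formulas (count 1 may be omitted)."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula")
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(tuple(sorted(counts.items())))

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(sorted((e, int(c)) for e, c in counts.items() if c)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def n_carbons(self) -> int:
        return self.as_dict().get("C", 0)

    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[e] * c for e, c in self.counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        d = self.as_dict()
        order = [e for e in ("C", "H") if e in d] + sorted(e for e in d if e not in ("C", "H"))
        return "".join(f"{e}{d[e] if d[e] != 1 else ''}" for e in order if d[e])


def exact_mz(formula: ElementalFormula | str, adduct: str = "[M-H]-") -> float:
    """Theoretical m/z of the given adduct of ``formula``.

    Only the deprotonated anion ``[M-H]-`` is supported (the acquisition
    mode used for these phosphorylated, acidic compounds); other adducts
    raise ``ValueError``.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.from_string(formula)
    if adduct != "[M-H]-":
        raise ValueError(f"unsupported adduct {adduct!r}; only '[M-H]-' is implemented")
    return formula.monoisotopic_mass() - PROTON_MASS


@dataclass(frozen=True)
class MetaboliteSpec:
    """A pathway compound as configured for targeted acquisition."""

    name: str
    formula: ElementalFormula
    cas: str = ""
    retention_time_min: float | None = None
    quantifiable_in_ile: bool = True
    n_carbons: int | None = None

    def __post_init__(self) -> None:
        if self.n_carbons is None:
            object.__setattr__(self, "n_carbons", self.formula.n_carbons)
        elif self.n_carbons != self.formula.n_carbons:
            raise ValueError(
                f"{self.name}: declared n_carbons={self.n_carbons} does not match "
                f"formula carbon count {self.formula.n_carbons}"
            )


@dataclass(frozen=True)
class Pool:
    """A kinetic pool / measured MS signal (isobaric members share one)."""

    name: str
    n_carbons: int
    members: tuple[str, ...]
    quantifiable_in_ile: bool = True

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise ValueError(f"pool {self.name}: negative carbon count")
        if not self.members:
            raise ValueError(f"pool {self.name}: no member metabolites")


@dataclass(frozen=True)
class Reaction:
    """One step of the pathway topology.

    kind is one of ``source_feed`` (n_units condensed units of
    unit_carbons carbons each enter from central metabolism),
    ``linear_step`` (carbon skeleton conserved), ``carbon_loss``
    (decarboxylation, one carbon lost) and ``condensation`` (two
    substrates condense, carbons add).
    """

    kind: str
    product: str
    substrates: tuple[str, ...] = ()
    unit_carbons: int = 0
    n_units: int = 0

    _KINDS = ("source_feed", "linear_step", "carbon_loss", "condensation")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        expected = {"source_feed": 0, "linear_step": 1, "carbon_loss": 1, "condensation": 2}
        if len(self.substrates) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} -> {self.product}: expected {expected[self.kind]} substrate(s), "
                f"got {len(self.substrates)}"
            )
        if self.kind == "source_feed" and (self.unit_carbons < 1 or self.n_units < 1):
            raise ValueError(f"source_feed -> {self.product}: unit_carbons and n_units must be >= 1")


@dataclass(frozen=True)
class PathwaySpec:
    """Compounds, pools and reactions of the measured pathway.

    Validation enforces carbon conservation for every reaction and an
    acyclic topology in which every pool is produced by exactly one
    reaction reachable from the source feed.
    """

    metabolites: tuple[MetaboliteSpec, ...]
    pools: tuple[Pool, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        met_by_name = {m.name: m for m in self.metabolites}
        if len(met_by_name) != len(self.metabolites):
            raise ValueError("duplicate metabolite names")
        pool_by_name = {p.name: p for p in self.pools}
        if len(pool_by_name) != len(self.pools):
            raise ValueError("duplicate pool names")
        for pool in self.pools:
            for member in pool.members:
                if member not in met_by_name:
                    raise ValueError(f"pool {pool.name}: unknown member metabolite {member!r}")
                if met_by_name[member].n_carbons != pool.n_carbons:
                    raise ValueError(
                        f"pool {pool.name}: member {member} has "
                        f"{met_by_name[member].n_carbons} carbons, pool declares {pool.n_carbons}"
                    )
        producers: dict[str, Reaction] = {}
        for rxn in self.reactions:
            for name in (rxn.product, *rxn.substrates):
                if name not in pool_by_name:
                    raise ValueError(f"reaction references unknown pool {name!r}")
            if rxn.product in producers:
                raise ValueError(f"pool {rxn.product} has more than one producing reaction")
            producers[rxn.product] = rxn
            n_prod = pool_by_name[rxn.product].n_carbons
            if rxn.kind == "source_feed":
                n_in = rxn.unit_carbons * rxn.n_units
            elif rxn.kind == "linear_step":
                n_in = pool_by_name[rxn.substrates[0]].n_carbons
            elif rxn.kind == "carbon_loss":
                n_in = pool_by_name[rxn.substrates[0]].n_carbons - 1
            else:  # condensation
                n_in = sum(pool_by_name[s].n_carbons for s in rxn.substrates)
            if n_in != n_prod:
                raise ValueError(
                    f"carbon conservation violated at {rxn.kind} -> {rxn.product}: "
                    f"{n_in} in vs {n_prod} out"
                )
        missing = [p.name for p in self.pools if p.name not in producers]
        if missing:
            raise ValueError(f"pools with no producing reaction: {missing}")
        # topological order (raises on cycles)
        object.__setattr__(self, "_producers", producers)
        object.__setattr__(self, "_topo_order", self._toposort(producers))

    def _toposort(self, producers: dict[str, Reaction]) -> tuple[str, ...]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(name: str) -> None:
            if state.get(name) == 1:
                return
            if state.get(name) == 0:
                raise ValueError(f"pathway topology contains a cycle through {name!r}")
            state[name] = 0
            for sub in producers[name].substrates:
                visit(sub)
            state[name] = 1
            order.append(name)

        for pool in self.pools:
            visit(pool.name)
        return tuple(order)

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self._topo_order  # type: ignore[attr-defined]

    def producer(self, pool_name: str) -> Reaction:
        return self._producers[pool_name]  # type: ignore[attr-defined]

    def pool(self, name: str) -> Pool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(name)

    def metabolite(self, name: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def quantifiable_pools(self) -> tuple[Pool, ...]:
        return tuple(p for p in self.pools if p.quantifiable_in_ile)


@dataclass(frozen=True)
class IsotopologueCount:
    """Isotopologue bookkeeping for an ILE over a set of timepoints."""

    per_signal: Mapping[str, int]
    n_timepoints: int

    @property
    def per_timepoint(self) -> int:
        return sum(self.per_signal.values())

    @property
    def total(self) -> int:
        return self.per_timepoint * self.n_timepoints


def count_isotopologues(pathway: PathwaySpec, timepoints: Sequence[float]) -> IsotopologueCount:
    """Count measured isotopologues: n+1 per quantifiable signal, summed
    over signals and multiplied by the number of sampling timepoints."""
    if len(timepoints) == 0:
        raise ValueError("empty timepoint list")
    per_signal = {p.name: p.n_carbons + 1 for p in pathway.quantifiable_pools}
    return IsotopologueCount(per_signal=per_signal, n_timepoints=len(timepoints))


def _pathway_from_mapping(doc: Mapping) -> PathwaySpec:
    metabolites = tuple(
        MetaboliteSpec(
            name=m["name"],
            formula=ElementalFormula.from_string(m["formula"]),
            cas=str(m.get("cas", "")),
            retention_time_min=m.get("retention_time_min"),
            quantifiable_in_ile=bool(m.get("quantifiable_in_ile", True)),
        )
        for m in doc["metabolites"]
    )
    pools = tuple(
        Pool(
            name=p["name"],
            n_carbons=int(p["n_carbons"]),
            members=tuple(p["members"]),
            quantifiable_in_ile=bool(p.get("quantifiable_in_ile", True)),
        )
        for p in doc["pools"]
    )
    reactions = []
    for r in doc["reactions"]:
        subs = r.get("substrates")
        if subs is None:
            subs = [r["substrate"]] if "substrate" in r else []
        reactions.append(
            Reaction(
                kind=r["kind"],
                product=r["product"],
                substrates=tuple(subs),
                unit_carbons=int(r.get("unit_carbons", 0)),
                n_units=int(r.get("n_units", 0)),
            )
        )
    return PathwaySpec(metabolites=metabolites, pools=pools, reactions=tuple(reactions))


def load_pathway(path: str | Path) -> PathwaySpec:
    """Load a pathway/compound configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _pathway_from_mapping(doc)


def default_pathway() -> PathwaySpec:
    """The shipped mevalonate / prenyl-pyrophosphate pathway configuration."""
    ref = resources.files("prenylflux") / "data" / "pathway.yaml"
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _pathway_from_mapping(doc)
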
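"""Exact fermentation stoichiometry and transformed reaction Gibbs energies.

A fermentation equation is represented as a signed stoichiometric map over
registered compounds (negative coefficients = consumed, positive = produced).
Unknown coefficients are solved by element and charge conservation in exact
rational arithmetic, so a reaction reported as balanced has literally zero
residuals in every element and in charge.

Transformed standard Gibbs energies of reaction (dG'0) are computed from a
packaged table of transformed standard formation energies of the pH-7
dominant species at ionic strength 0.25 M and 298.15 K.  Under the
transformed (Legendre) convention the proton carries a formation energy of
zero; protons nevertheless appear explicitly in the stoichiometry so that
charge balance holds for the equations as printed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional

__all__ = [
    "Compound",
    "CompoundRegistry",
    "Reaction",
    "ThermoResult",
    "RegistryError",
    "UnbalanceableError",
    "UnbalancedReactionError",
    "ThermoDataError",
    "parse_formula",
    "balance_fermentation",
    "check_balance",
    "delta_r_g_prime",
    "EQ1_FIXED",
    "EQ2_FIXED",
    "FREE_SPECIES",
    "eq1",
    "eq2",
]


class RegistryError(KeyError):
    """An operation referenced a compound id that is not registered."""


class UnbalanceableError(ValueError):
    """The element/charge system has no (unique) solution."""


class UnbalancedReactionError(ValueError):
    """A thermodynamic quantity was requested for an unbalanced reaction."""


class ThermoDataError(ValueError):
    """A compound lacks a transformed formation energy."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``C6H11O2``) into counts."""
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        n = int(m.group(2)) if m.group(2) else 1
        if n < 0:
            raise ValueError("negative element count")
        counts[m.group(1)] = counts.get(m.group(1), 0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Compound:
    """A chemical species in its pH-7 dominant protonation state.

    ``dfg_prime`` is the transformed standard formation energy (kJ/mol) at
    pH 7.0, ionic strength 0.25 M, 298.15 K; ``None`` when unavailable.
    """

    id: str
    name: str
    formula: Mapping[str, int]
    charge: int
    dfg_prime: Optional[float] = None
    dfg_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.formula.values()):
            raise ValueError(f"{self.id}: negative element count")
        if self.dfg_uncertainty < 0:
            raise ValueError(f"{self.id}: negative uncertainty")


class CompoundRegistry:
    """Unique-id registry of compounds, usually loaded from the packaged TSV."""

    def __init__(self, compounds: Iterable[Compound] = ()) -> None:
        self._by_id: Dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.id in self._by_id:
            raise RegistryError(f"duplicate compound id {compound.id!r}")
        self._by_id[compound.id] = compound

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    def __getitem__(self, cid: str) -> Compound:
        try:
            return self._by_id[cid]
        except KeyError:
            raise RegistryError(f"unknown compound id {cid!r}") from None

    def ids(self) -> List[str]:
        return list(self._by_id)

    @classmethod
    def from_tsv(cls, path) -> "CompoundRegistry":
        reg = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                reg.add(
                    Compound(
                        id=row["id"],
                        name=row["name"],
                        formula=parse_formula(row["formula"]),
                        charge=int(row["charge"]),
                        dfg_prime=float(row["dfg_prime"]) if row["dfg_prime"] else None,
                        dfg_uncertainty=float(row.get("dfg_uncertainty") or 0.0),
                    )
                )
        return reg

    @classmethod
    def default(cls) -> "CompoundRegistry":
        """The packaged registry (pH 7.0, I = 0.25 M, 298.15 K)."""
        with resources.as_file(
            resources.files("caproflux").joinpath("data/compounds.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass
class Reaction:
    """Signed stoichiometric map; zero coefficients are never stored."""

    stoich: Dict[str, Fraction]
    basis: Optional[str] = None

    def __post_init__(self) -> None:
        self.stoich = {
            cid: Fraction(c) for cid, c in self.stoich.items() if Fraction(c) != 0
        }

    def scaled(self, k: Fraction) -> "Reaction":
        k = Fraction(k)
        if k == 0:
            raise ValueError("scale factor must be nonzero")
        return Reaction({c: v * k for c, v in self.stoich.items()}, basis=self.basis)

    def reversed(self) -> "Reaction":
        return self.scaled(Fraction(-1))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Reaction) and self.stoich == other.stoich


@dataclass(frozen=True)
class ThermoResult:
    """dG'0 per mole of the basis compound, with a root-sum-square uncertainty."""

    drg_prime: float
    uncertainty: float
    basis: str


def _elements_of(rxn_ids: Iterable[str], registry: CompoundRegistry) -> List[str]:
    elems: List[str] = []
    for cid in rxn_ids:
        for e in registry[cid].formula:
            if e not in elems:
                elems.append(e)
    return sorted(elems)


def check_balance(rxn: Reaction, registry: CompoundRegistry) -> Dict[str, Fraction]:
    """Per-element and charge residuals; an all-zero map means balanced."""
    if not rxn.stoich:
        return {}
    residuals: Dict[str, Fraction] = {}
    for e in _elements_of(rxn.stoich, registry):
        residuals[e] = sum(
            (coeff * registry[cid].formula.get(e, 0) for cid, coeff in rxn.stoich.items()),
            Fraction(0),
        )
    residuals["charge"] = sum(
        (coeff * registry[cid].charge for cid, coeff in rxn.stoich.items()),
        Fraction(0),
    )
    return residuals


def balance_fermentation(
    fixed: Mapping[str, Fraction],
    free: Iterable[str],
    registry: Optional[CompoundRegistry] = None,
) -> Reaction:
    """Solve free coefficients so the reaction balances in every element and charge.

    ``fixed`` maps compound ids to known signed coefficients (measured
    substrate consumption and product formation); ``free`` lists the species
    whose coefficients are solved from one conservation equation per element
    plus one for charge.  Arithmetic is exact: the returned reaction passes
    :func:`check_balance` with all-zero residuals or an
    :class:`UnbalanceableError` is raised naming the offending element.
    """
    registry = registry or CompoundRegistry.default()
    free = list(free)
    fixed = {cid: Fraction(v) for cid, v in fixed.items()}
    overlap = set(fixed) & set(free)
    if overlap:
        raise ValueError(f"fixed and free overlap: {sorted(overlap)}")
    for cid in list(fixed) + free:
        registry[cid]  # raises RegistryError for unknown ids

    labels = _elements_of(list(fixed) + free, registry) + ["charge"]

    def row_count(cid: str, label: str) -> Fraction:
        comp = registry[cid]
        if label == "charge":
            return Fraction(comp.charge)
        return Fraction(comp.formula.get(label, 0))

    n = len(free)
    a = [[row_count(cid, lab) for cid in free] for lab in labels]
    b = [
        -sum((coeff * row_count(cid, lab) for cid, coeff in fixed.items()), Fraction(0))
        for lab in labels
    ]
    a_orig = [row[:] for row in a]
    b_orig = b[:]

    # Gauss-Jordan elimination over the rationals.
    rank = 0
    pivot_cols: List[int] = []
    m = len(labels)
    for col in range(n):
        piv = next((i for i in range(rank, m) if a[i][col] != 0), None)
        if piv is None:
            continue
        a[rank], a[piv] = a[piv], a[rank]
        b[rank], b[piv] = b[piv], b[rank]
        inv = 1 / a[rank][col]
        a[rank] = [v * inv for v in a[rank]]
        b[rank] *= inv
        for i in range(m):
            if i != rank and a[i][col] != 0:
                f = a[i][col]
                a[i] = [vi - f * vr for vi, vr in zip(a[i], a[rank])]
                b[i] -= f * b[rank]
        pivot_cols.append(col)
        rank += 1
    if rank < n:
        missing = [free[c] for c in range(n) if c not in pivot_cols]
        raise UnbalanceableError(
            f"underdetermined system: coefficients of {missing} are not fixed "
            "by element/charge conservation"
        )
    x = [Fraction(0)] * n
    for r, col in enumerate(pivot_cols):
        x[col] = b[r]
    # Verify against every original equation so inconsistencies name the element.
    for lab, row, rhs in zip(labels, a_orig, b_orig):
        if sum((c * xi for c, xi in zip(row, x)), Fraction(0)) != rhs:
            raise UnbalanceableError(f"unbalanceable: no solution satisfies {lab}")

    stoich = dict(fixed)
    for cid, coeff in zip(free, x):
        stoich[cid] = stoich.get(cid, Fraction(0)) + coeff
    return Reaction(stoich)


def delta_r_g_prime(
    rxn: Reaction,
    basis: str,
    registry: Optional[CompoundRegistry] = None,
) -> ThermoResult:
    """Transformed standard reaction Gibbs energy per mole of ``basis``.

    drg = sum(coeff * dfg_prime) / |coeff(basis)|, with the uncertainty
    combined as the root-sum-square of coefficient-weighted per-compound
    standard errors (an approximation: covariances are not tracked).
    Refuses unbalanced reactions and compounds without thermodynamic data.
    """
    registry = registry or CompoundRegistry.default()
    if not rxn.stoich:
        raise ValueError("empty reaction")
    if basis not in rxn.stoich:
        raise ValueError(f"basis {basis!r} not in reaction")
    residuals = check_balance(rxn, registry)
    bad = {k: v for k, v in residuals.items() if v != 0}
    if bad:
        raise UnbalancedReactionError(f"reaction is not balanced: residuals {bad}")
    total = 0.0
    var = 0.0
    for cid, coeff in rxn.stoich.items():
        comp = registry[cid]
        if comp.dfg_prime is None:
            raise ThermoDataError(f"no thermodynamic data for {cid!r}")
        total += float(coeff) * comp.dfg_prime
        var += (float(coeff) * comp.dfg_uncertainty) ** 2
    scale = abs(float(rxn.stoich[basis]))
    return ThermoResult(total / scale, math.sqrt(var) / scale, basis)


# Built-in fixtures: the measured caproate fermentations on glucose (eq1)
# and on lactate (eq2), at a reducing-substrate:acetate ratio of ~5-10:1.
EQ1_FIXED: Dict[str, Fraction] = {
    "glucose": Fraction(-6),
    "acetate": Fraction(-2),
    "caproate": Fraction(4),
    "butyrate": Fraction(1),
}
EQ2_FIXED: Dict[str, Fraction] = {
    "lactate": Fraction(-21),
    "acetate": Fraction(-2),
    "caproate": Fraction(7),
    "butyrate": Fraction(1),
}
FREE_SPECIES = ["H+", "H2O", "CO2", "H2"]


def eq1(registry: Optional[CompoundRegistry] = None) -> Reaction:
    """Glucose fermentation: 6 glucose + 2 acetate -> 4 caproate + 1 butyrate + ..."""
    rxn = balance_fermentation(EQ1_FIXED, FREE_SPECIES, registry)
    rxn.basis = "glucose"
    return rxn


def eq2(registry: Optional[CompoundRegistry] = None) -> Reaction:
    """Lactate fermentation: 21 lactate + 2 acetate + 15 H+ -> 7 caproate + ..."""
    rxn = balance_fermentation(EQ2_FIXED, FREE_SPECIES, registry)
    rxn.basis = "lactate"
    return rxn
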
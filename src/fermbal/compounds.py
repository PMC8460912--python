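"""Chemical species registry, unit conversion, and exact reaction balancing.

Every other stage leans on this module: the degree of reduction (gamma, the
available-electron count per mole) is the currency of the electron ledger,
and the stoichiometric coefficients of the reaction set drive both the
reactor simulator and the H2 attribution rules.

Conventions
-----------
* Carboxylates are carried as neutral free acids (lactic, acetic, ...) for
  molar mass and gamma; protonation state is ignored, which is how g/L and
  mM are used interchangeably throughout.
* gamma = 4*C + H - 2*O - 3*N (ammonia-N reference), so CO2 and H2O score 0
  and O2 scores -4 (a pure electron acceptor).
* Gas volumes convert at 22.414 mL/mmol (0 degC, 101.325 kPa).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterator, Mapping, Optional

from .errors import BalancingError, RegistryError

ATOMIC_WEIGHTS: Dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "He": 4.0026,
}

#: Elements participating in conservation equations (He handled separately).
ELEMENTS = ("C", "H", "O", "N")

#: Degree-of-reduction weights, per atom.
GAMMA_WEIGHTS = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0}

#: Ideal-gas molar volume at the declared reference state, mL/mmol.
MOLAR_VOLUME_ML = 22.414


def formula_mass(formula: Mapping[str, float]) -> float:
    """Molar mass in g/mol from element counts (fractional counts allowed)."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class Compound:
    """A chemical species with its elemental formula and bookkeeping role.

    ``formula`` maps element symbols (C, H, O, N, He) to counts; counts may
    be fractional for lumped species such as biomass. ``role`` is one of
    substrate / product / tracer / inhibitor / contaminant and is purely
    descriptive. ``molar_mass`` defaults to the formula mass.
    """

    name: str
    formula: Mapping[str, float]
    phase_default: str = "liquid"
    role: str = "product"
    molar_mass: Optional[float] = None

    def __post_init__(self) -> None:
        counts = dict(self.formula)
        if any(n < 0 for n in counts.values()) or not any(counts.values()):
            raise RegistryError(
                f"{self.name}: element counts must be >= 0 and not all zero"
            )
        object.__setattr__(self, "formula", counts)
        mass = formula_mass(counts)
        if self.molar_mass is None:
            object.__setattr__(self, "molar_mass", mass)
        else:
            if self.molar_mass <= 0:
                raise RegistryError(f"{self.name}: molar_mass must be > 0")
            if abs(self.molar_mass - mass) > 0.01 * mass:
                raise RegistryError(
                    f"{self.name}: molar_mass {self.molar_mass} inconsistent "
                    f"with formula mass {mass:.3f} (>1%)"
                )

    def count(self, element: str) -> float:
        return self.formula.get(element, 0.0)

    @property
    def gamma(self) -> float:
        return degree_of_reduction(self)


def degree_of_reduction(compound: Compound) -> float:
    """Available electron equivalents per mole: 4C + H - 2O - 3N.

    Total on any valid compound. Examples: lactic acid (C3H6O3) -> 12,
    CH4 -> 8, O2 -> -4, biomass CH1.8O0.5N0.2 -> 4.2.
    """
    return sum(GAMMA_WEIGHTS[el] * compound.count(el) for el in ELEMENTS)


class CompoundRegistry:
    """Name-keyed collection of compounds, JSON round-trippable."""

    def __init__(self, compounds: Optional[Mapping[str, Compound]] = None):
        self._compounds: Dict[str, Compound] = dict(compounds or {})

    def add(self, compound: Compound) -> None:
        self._compounds[compound.name] = compound

    def get(self, name: str) -> Compound:
        try:
            return self._compounds[name]
        except KeyError:
            raise RegistryError(f"unknown compound: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._compounds

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds.values())

    def names(self) -> list[str]:
        return list(self._compounds)

    def to_json(self) -> str:
        payload = [
            {
                "name": c.name,
                "formula": c.formula,
                "phase_default": c.phase_default,
                "role": c.role,
                "molar_mass": c.molar_mass,
            }
            for c in self
        ]
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CompoundRegistry":
        reg = cls()
        for item in json.loads(text):
            reg.add(Compound(**item))
        return reg


def _acid(name: str, c: int, h: int, o: int, role: str = "product") -> Compound:
    return Compound(name, {"C": c, "H": h, "O": o}, "liquid", role)


def default_registry() -> CompoundRegistry:
    """All species monitored in the liquid and gas phases, plus water and a
    lumped biomass (CH1.8O0.5N0.2, excluded from ledgers by default)."""
    reg = CompoundRegistry()
    for comp in [
        _acid("formate", 1, 2, 2),
        _acid("acetate", 2, 4, 2, "substrate"),
        _acid("lactate", 3, 6, 3, "substrate"),
        _acid("propionate", 3, 6, 2),
        _acid("n-butyrate", 4, 8, 2),
        _acid("i-butyrate", 4, 8, 2),
        _acid("n-valerate", 5, 10, 2),
        _acid("i-valerate", 5, 10, 2),
        _acid("n-caproate", 6, 12, 2),
        _acid("i-caproate", 6, 12, 2),
        _acid("n-heptanoate", 7, 14, 2),
        _acid("n-caprylate", 8, 16, 2),
        Compound("ethanol", {"C": 2, "H": 6, "O": 1}),
        Compound("n-propanol", {"C": 3, "H": 8, "O": 1}),
        Compound("n-butanol", {"C": 4, "H": 10, "O": 1}),
        Compound("n-pentanol", {"C": 5, "H": 12, "O": 1}),
        Compound("n-hexanol", {"C": 6, "H": 14, "O": 1}),
        Compound("h2o", {"H": 2, "O": 1}),
        Compound("h2", {"H": 2}, "gas", "substrate"),
        Compound("co2", {"C": 1, "O": 2}, "gas", "substrate"),
        Compound("ch4", {"C": 1, "H": 4}, "gas", "product"),
        Compound("he", {"He": 1}, "gas", "tracer"),
        Compound("o2", {"O": 2}, "gas", "contaminant"),
        Compound("n2", {"N": 2}, "gas", "contaminant"),
        Compound("ethylene", {"C": 2, "H": 4}, "gas", "inhibitor"),
        Compound("biomass", {"C": 1, "H": 1.8, "O": 0.5, "N": 0.2},
                 "liquid", "product"),
    ]:
        reg.add(comp)
    return reg


DEFAULT_REGISTRY = default_registry()


def mass_to_molar(conc_g_per_l: float, compound: str | Compound,
                  registry: Optional[CompoundRegistry] = None) -> float:
    """g/L -> mM using the free-acid molar mass. 12 g/L lactic acid -> 133.2."""
    comp = _resolve(compound, registry)
    return 1000.0 * conc_g_per_l / comp.molar_mass


def molar_to_mass(conc_mM: float, compound: str | Compound,
                  registry: Optional[CompoundRegistry] = None) -> float:
    """mM -> g/L; exact inverse of :func:`mass_to_molar`."""
    comp = _resolve(compound, registry)
    return conc_mM * comp.molar_mass / 1000.0


def _resolve(compound: str | Compound,
             registry: Optional[CompoundRegistry]) -> Compound:
    if isinstance(compound, Compound):
        return compound
    return (registry or DEFAULT_REGISTRY).get(compound)


@dataclass(frozen=True)
class ReactionSpec:
    """Signed stoichiometry over compound names (negative = consumed).

    A coefficient of ``None`` marks an unknown to be solved by
    :func:`balance_reaction`; at least one known coefficient must remain to
    anchor the scale.
    """

    name: str
    stoichiometry: Mapping[str, Optional[Fraction]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def unknowns(self) -> list[str]:
        return [n for n, c in self.stoichiometry.items() if c is None]

    def coefficients(self) -> Dict[str, Fraction]:
        if self.unknowns:
            raise BalancingError(f"{self.name}: unresolved coefficients")
        return {n: Fraction(c) for n, c in self.stoichiometry.items()}

    def element_residuals(self, registry: Optional[CompoundRegistry] = None
                          ) -> Dict[str, float]:
        reg = registry or DEFAULT_REGISTRY
        res = {}
        for el in (*ELEMENTS, "He"):
            res[el] = sum(float(c) * reg.get(n).count(el)
                          for n, c in self.coefficients().items())
        return res

    def electron_residual(self, registry: Optional[CompoundRegistry] = None
                          ) -> float:
        reg = registry or DEFAULT_REGISTRY
        return sum(float(c) * degree_of_reduction(reg.get(n))
                   for n, c in self.coefficients().items())

    def is_balanced(self, registry: Optional[CompoundRegistry] = None,
                    tol: float = 1e-9) -> bool:
        res = self.element_residuals(registry)
        ok = all(abs(v) <= tol for v in res.values())
        return ok and abs(self.electron_residual(registry)) <= tol

    def validate(self, registry: Optional[CompoundRegistry] = None) -> None:
        coeffs = self.coefficients()
        if not any(c < 0 for c in coeffs.values()) or \
                not any(c > 0 for c in coeffs.values()):
            raise BalancingError(
                f"{self.name}: needs at least one reactant and one product")
        if not self.is_balanced(registry):
            bad = {el: v for el, v in
                   self.element_residuals(registry).items() if abs(v) > 1e-9}
            raise BalancingError(f"{self.name}: element residuals {bad}")


def _row_reduce(A: list[list[Fraction]], b: list[Fraction]
                ) -> tuple[list[int], list[list[Fraction]], list[Fraction]]:
    """In-place exact Gauss-Jordan; returns pivot column per pivot row."""
    rows, cols = len(A), len(A[0]) if A else 0
    piv_cols: list[int] = []
    r = 0
    for c in range(cols):
        piv = next((i for i in range(r, rows) if A[i][c] != 0), None)
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        b[r], b[piv] = b[piv], b[r]
        inv = A[r][c]
        A[r] = [v / inv for v in A[r]]
        b[r] = b[r] / inv
        for i in range(rows):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [vi - f * vr for vi, vr in zip(A[i], A[r])]
                b[i] = b[i] - f * b[r]
        piv_cols.append(c)
        r += 1
        if r == rows:
            break
    return piv_cols, A, b


def balance_reaction(template: ReactionSpec,
                     registry: Optional[CompoundRegistry] = None
                     ) -> ReactionSpec:
    """Solve unknown coefficients from C/H/O/N (and He) conservation.

    The anchored known coefficients set the scale. When the element
    equations leave exactly one degree of freedom (which happens for
    reaction families that contain an internal redox-balanced blend, e.g.
    lactate -> propionate/acetate/CO2/H2O), the canonical solution is the
    one in which every template species participates with a nonzero,
    small-integer coefficient; if that choice is not unique the template is
    rejected as underdetermined. The returned spec has exactly zero element
    residuals and zero electron residual (the latter follows from the
    former because gamma is linear in the element counts, but both are
    verified).
    """
    reg = registry or DEFAULT_REGISTRY
    unknowns = template.unknowns
    known = {n: Fraction(c) for n, c in template.stoichiometry.items()
             if c is not None}
    if not unknowns:
        template.validate(reg)
        return template
    if not known:
        raise BalancingError(
            f"{template.name}: at least one coefficient must anchor the scale")

    elements = [el for el in (*ELEMENTS, "He")
                if any(reg.get(n).count(el) for n in template.stoichiometry)]
    A = [[Fraction(reg.get(u).count(el)).limit_denominator(10 ** 6)
          for u in unknowns] for el in elements]
    b = [-sum(c * Fraction(reg.get(n).count(el)).limit_denominator(10 ** 6)
              for n, c in known.items()) for el in elements]
    piv_cols, A, b = _row_reduce([row[:] for row in A], b[:])

    # Inconsistent rows: 0 = nonzero after reduction -> name the elements.
    bad = [elements[i] for i in range(len(A))
           if all(v == 0 for v in A[i]) and b[i] != 0]
    if bad:
        raise BalancingError(
            f"{template.name}: no solution; deficient elements: {bad}")

    free_cols = [c for c in range(len(unknowns)) if c not in piv_cols]
    x0 = [Fraction(0)] * len(unknowns)
    for r, c in enumerate(piv_cols):
        x0[c] = b[r]

    if len(free_cols) == 0:
        solution = x0
    elif len(free_cols) == 1:
        solution = _canonical_one_dof(A, piv_cols, free_cols[0], x0,
                                      template.name)
    else:
        raise BalancingError(
            f"{template.name}: underdetermined "
            f"({len(free_cols)} degrees of freedom)")

    coeffs = dict(known)
    coeffs.update(dict(zip(unknowns, solution)))
    if any(c == 0 for c in solution):
        raise BalancingError(
            f"{template.name}: a template species dropped out (zero "
            "coefficient); remove it or fix its coefficient")
    spec = ReactionSpec(template.name, coeffs)
    spec.validate(reg)
    return spec


def _canonical_one_dof(A: list[list[Fraction]], piv_cols: list[int],
                       free_col: int, x0: list[Fraction], name: str
                       ) -> list[Fraction]:
    """Pick the minimal all-integer, all-nonzero point on a solution line."""
    n_unk = len(x0)
    null = [Fraction(0)] * n_unk
    null[free_col] = Fraction(1)
    for r, c in enumerate(piv_cols):
        null[c] = -A[r][free_col]
    # Primitive integer direction.
    lcm = math.lcm(*(f.denominator for f in null))
    ints = [int(f * lcm) for f in null]
    g = math.gcd(*(abs(i) for i in ints if i)) or 1
    direction = [Fraction(i, g) for i in ints]

    denom = math.lcm(*(f.denominator for f in x0), 1)
    span = 4 * max(1, max(abs(int(f)) + 1 for f in x0))
    candidates = []
    for k in range(-span * denom, span * denom + 1):
        t = Fraction(k, denom)
        x = [xi + t * di for xi, di in zip(x0, direction)]
        if any(v == 0 for v in x):
            continue
        if all(v.denominator == 1 for v in x):
            candidates.append((sum(abs(v) for v in x), abs(t), x))
    if not candidates:
        raise BalancingError(
            f"{name}: underdetermined (no canonical integer solution)")
    candidates.sort(key=lambda item: (item[0], item[1]))
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0] \
            and candidates[0][1] == candidates[1][1]:
        raise BalancingError(f"{name}: underdetermined (tied solutions)")
    return candidates[0][2]


def default_reactions() -> Dict[str, ReactionSpec]:
    """The shipped reaction set, every member element- and electron-balanced.

    Covers lactate fermentation to propionate (2:1:1 propionate:acetate:CO2),
    H2 oxidation by O2 (the anaerobic scavenging sink), homopropionate
    fermentation (lactate + H2), homoacetogenesis (4 H2 + 2 CO2 -> acetate),
    hydrogenotrophic methanogenesis (4 H2 + CO2 -> CH4), n-butyrate
    formation from lactate, and lactate/acetate chain elongation to
    n-caproate.
    """
    f = Fraction
    specs = {
        "propionate_fermentation": {"lactate": f(-3), "propionate": f(2),
                                    "acetate": f(1), "co2": f(1), "h2o": f(1)},
        "h2_oxidation": {"h2": f(-2), "o2": f(-1), "h2o": f(2)},
        "homopropionate": {"lactate": f(-1), "h2": f(-1),
                           "propionate": f(1), "h2o": f(1)},
        "homoacetogenesis": {"h2": f(-4), "co2": f(-2),
                             "acetate": f(1), "h2o": f(2)},
        "methanogenesis": {"h2": f(-4), "co2": f(-1), "ch4": f(1), "h2o": f(2)},
        "butyrate_from_lactate": {"lactate": f(-2), "n-butyrate": f(1),
                                  "co2": f(2), "h2": f(2)},
        "chain_elongation": {"lactate": f(-2), "acetate": f(-1),
                             "n-caproate": f(1), "co2": f(2), "h2o": f(2)},
    }
    out = {}
    for name, st in specs.items():
        spec = ReactionSpec(name, st)
        spec.validate()
        out[name] = spec
    return out


DEFAULT_REACTIONS = default_reactions()
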
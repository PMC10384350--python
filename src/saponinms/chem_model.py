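"""Structural data model and mass bookkeeping for sea-cucumber triterpene glycosides.

Triterpene glycosides (saponins) of sea cucumbers are lanostane-type aglycons
glycosylated at C-3 with a short oligosaccharide (1-6 units drawn from Xyl, Qui,
Glc, MeGlc, MeXyl) that may carry up to four sulfate half-ester groups.  This
module provides elemental-formula arithmetic, residue masses, the glycoside
data model (aglycon + glycan tree + sulfation), negative-mode adduct math for
[M-H]-, [M-Na]- and [M-nNa]n- ions, and a plain-text structure file format.

Two mass modes are used throughout the package:

``"mono"``
    Monoisotopic masses; the working mode for measured data.
``"nominal"``
    Integer residue and neutral-loss masses (Xyl 132, Qui/MeXyl 146, Glc 162,
    MeGlc 176, SO3 80, H2O 18, CO2 44, ...), which reproduce the truncated
    integer m/z values conventionally quoted for CID ladders of this compound
    class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Formula",
    "formula_mass",
    "GlycanUnit",
    "GlycanTree",
    "AglyconSpec",
    "Glycoside",
    "precursor_mz",
    "residue_mass",
    "residue_nominal_mass",
    "parse_structures",
    "load_structures",
    "format_structure",
    "write_structures",
    "MONOSACCHARIDES",
    "RESIDUE_FORMULAS",
    "PROTON",
    "NA_ION",
    "MASS",
    "NOMINAL",
]

# Monoisotopic atomic masses (CODATA/IUPAC), restricted to the elements that
# occur in this compound class.
_ELEMENTS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "Na": 22.98976928,
}

#: mass of the charge carriers; electron mass is neglected (its effect is far
#: below every matching tolerance used here).
PROTON = 1.007276
NA_ION = 22.989770

MODES = ("mono", "nominal")


class Formula:
    """Elemental formula over {C, H, N, O, S, Na} with non-negative counts."""

    __slots__ = ("counts",)

    def __init__(self, counts: dict[str, int] | str | None = None):
        if isinstance(counts, str):
            counts = _parse_formula_string(counts)
        self.counts: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            if sym not in _ELEMENTS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n:
                self.counts[sym] = int(n)

    @property
    def mass(self) -> float:
        return sum(_ELEMENTS[sym] * n for sym, n in self.counts.items())

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged)

    def __eq__(self, other) -> bool:
        return isinstance(other, Formula) and self.counts == other.counts

    def __hash__(self):
        return hash(frozenset(self.counts.items()))

    def __repr__(self):
        return f"Formula({self!s})"

    def __str__(self):
        order = ["C", "H", "N", "O", "S", "Na"]
        return "".join(
            f"{sym}{self.counts[sym] if self.counts[sym] != 1 else ''}"
            for sym in order
            if sym in self.counts
        ) or "(empty)"


def _parse_formula_string(s: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", s):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {s!r} at position {pos}")
        if not m.group(0):
            break
        sym, num = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise ValueError(f"unknown element symbol: {sym!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"cannot parse formula {s!r} at position {pos}")
    return counts


def formula_mass(f: Formula | str | dict) -> float:
    """Monoisotopic mass in Da of an elemental formula; empty formula -> 0."""
    if not isinstance(f, Formula):
        f = Formula(f)
    return f.mass


# --- monosaccharide residues -------------------------------------------------

#: residue (anhydro) formulas: monosaccharide minus water, the increment
#: exchanged at a glycosidic cleavage.  Qui and MeXyl are isobaric; mass alone
#: can never distinguish them and downstream code must keep the ambiguity.
RESIDUE_FORMULAS: dict[str, Formula] = {
    "Xyl": Formula("C5H8O4"),
    "Qui": Formula("C6H10O4"),
    "MeXyl": Formula("C6H10O4"),
    "Glc": Formula("C6H10O5"),
    "MeGlc": Formula("C7H12O5"),
}

MONOSACCHARIDES = tuple(RESIDUE_FORMULAS)

#: methylated units: terminal-only under the biosynthetic grammar.
METHYLATED = ("MeGlc", "MeXyl")

#: integer residue masses as conventionally quoted in fragment ladders.
_RESIDUE_NOMINAL = {"Xyl": 132, "Qui": 146, "MeXyl": 146, "Glc": 162, "MeGlc": 176}

# Neutral-piece monoisotopic masses used across the package.
MASS = {
    "SO3": Formula("SO3").mass,              # 79.9568
    "H2O": Formula("H2O").mass,              # 18.0106
    "CO2": Formula("CO2").mass,              # 43.9898
    "AcOH": Formula("C2H4O2").mass,          # 60.0211
    "AcOH_CO2": Formula("C3H4O4").mass,      # 104.0110
    "C2H2O2": Formula("C2H2O2").mass,        # 58.0055
    "C5H10": Formula("C5H10").mass,          # 70.0783
    # HSO4- anion m/z = H2SO4 - proton (96.9601): the sulfate diagnostic ion.
    "HSO4": Formula("H2SO4").mass - PROTON,
    "Na_minus_H": _ELEMENTS["Na"] - _ELEMENTS["H"],
    "H": _ELEMENTS["H"],
    "proton": PROTON,
    "Na": NA_ION,
}

#: nominal (integer) counterparts of :data:`MASS`.
NOMINAL = {
    "SO3": 80,
    "H2O": 18,
    "CO2": 44,
    "AcOH": 60,
    "AcOH_CO2": 104,
    "C2H2O2": 58,
    "C5H10": 70,
    "HSO4": 97,
    "Na_minus_H": 22,
    "H": 1,
    "proton": 1,
    "Na": 23,
}


def piece(name: str, mode: str = "mono") -> float:
    """Mass of a named neutral piece / charge carrier in the given mode."""
    _check_mode(mode)
    table = MASS if mode == "mono" else NOMINAL
    return table[name]


def residue_mass(code: str, mode: str = "mono") -> float:
    """Residue mass of a monosaccharide code in the given mode."""
    _check_mode(mode)
    if code not in RESIDUE_FORMULAS:
        raise ValueError(f"unknown monosaccharide code: {code!r}")
    if mode == "nominal":
        return float(_RESIDUE_NOMINAL[code])
    return RESIDUE_FORMULAS[code].mass


def residue_nominal_mass(code: str) -> int:
    """Integer residue mass (MeGlc 176, Glc 162, Qui/MeXyl 146, Xyl 132)."""
    if code not in RESIDUE_FORMULAS:
        raise ValueError(f"unknown monosaccharide code: {code!r}")
    return _RESIDUE_NOMINAL[code]


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


# --- glycan tree -------------------------------------------------------------


@dataclass(frozen=True)
class GlycanUnit:
    """One monosaccharide node of the glycan, optionally sulfated."""

    code: str
    sulfated: bool = False

    def __post_init__(self):
        if self.code not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown monosaccharide code: {self.code!r}")

    def __str__(self):
        return f"{self.code}(S)" if self.sulfated else self.code


class GlycanTree:
    """Rooted glycan: a main chain (root = unit bound to aglycon C-3) plus
    optional linear branches attached to main-chain units.

    Parameters
    ----------
    main : sequence of GlycanUnit
        Root-to-terminus chain; the root is the unit attached to the aglycon.
    branches : sequence of (int, sequence of GlycanUnit)
        Each branch attaches at the given 1-based main-chain position.
    """

    def __init__(self, main, branches=()):
        self.main: tuple[GlycanUnit, ...] = tuple(main)
        self.branches: tuple[tuple[int, tuple[GlycanUnit, ...]], ...] = tuple(
            (int(pos), tuple(chain)) for pos, chain in branches
        )
        if not self.main:
            raise ValueError("glycan must contain at least one unit")
        for pos, chain in self.branches:
            if not 1 <= pos <= len(self.main):
                raise ValueError(f"branch position {pos} outside main chain")
            if not chain:
                raise ValueError("empty branch chain")
        # flattened node arrays: main chain first, then branches in order
        self.units: list[GlycanUnit] = list(self.main)
        self.parents: list[int] = [-1] + list(range(len(self.main) - 1))
        self.labels: list[str] = [f"m{i + 1}" for i in range(len(self.main))]
        for b, (pos, chain) in enumerate(self.branches):
            attach = pos - 1
            for j, unit in enumerate(chain):
                self.units.append(unit)
                self.parents.append(attach)
                self.labels.append(f"b{b + 1}.{j + 1}")
                attach = len(self.units) - 1

    # -- basic structure queries

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_sulfates(self) -> int:
        return sum(u.sulfated for u in self.units)

    def children(self, i: int) -> list[int]:
        return [j for j, p in enumerate(self.parents) if p == i]

    def is_leaf(self, i: int) -> bool:
        return not self.children(i)

    def subtree(self, i: int) -> frozenset[int]:
        """Indices of node ``i`` and all its descendants (a non-reducing-end
        subtree, i.e. a B/C-ion candidate when cleaved at its root bond)."""
        out = {i}
        stack = [i]
        while stack:
            for c in self.children(stack.pop()):
                out.add(c)
                stack.append(c)
        return frozenset(out)

    def removal_sets(self) -> list[frozenset[int]]:
        """All non-empty descendant-closed node sets: the sugar sets that a
        Y-type (aglycon-retaining) cleavage or combination of cleavages can
        remove.  Removing the root removes everything (the bare-aglycon Y0)."""
        n = self.n_units
        out = []
        for mask in range(1, 1 << n):
            members = {i for i in range(n) if mask >> i & 1}
            if all(set(self.children(i)) <= members for i in members):
                out.append(frozenset(members))
        return out

    def validate(self, grammar: bool = True) -> None:
        """Check tree invariants; with ``grammar=True`` also enforce the
        biosynthetic grammar (root Xyl, methylated units terminal, <=6 units,
        <=4 sulfates, branching at unit 1 or 2)."""
        if not 1 <= self.n_units <= 6:
            raise ValueError(f"glycan must have 1-6 units, has {self.n_units}")
        if self.n_sulfates > 4:
            raise ValueError(f"at most 4 sulfates allowed, has {self.n_sulfates}")
        if grammar:
            if self.units[0].code != "Xyl":
                raise ValueError("grammar: the first (root) unit must be Xyl")
            for i, u in enumerate(self.units):
                if u.code in METHYLATED and not self.is_leaf(i):
                    raise ValueError(
                        f"grammar: methylated unit {u.code} must be terminal"
                    )
            for pos, _ in self.branches:
                if pos not in (1, 2):
                    raise ValueError(
                        "grammar: branching occurs at the first or second unit"
                    )

    def residues_mass(self, mode: str = "mono") -> float:
        return sum(residue_mass(u.code, mode) for u in self.units)

    def __eq__(self, other):
        return (
            isinstance(other, GlycanTree)
            and self.main == other.main
            and self.branches == other.branches
        )

    def __repr__(self):
        return f"GlycanTree({format_glycan(self)!r})"


# --- aglycon and glycoside ---------------------------------------------------

LACTONES = ("18(20)", "18(16)")


@dataclass(frozen=True)
class AglyconSpec:
    """Aglycon description.

    The aglycon may be given by an elemental formula or, since formulas of
    isolated compounds are often unpublished, by its bare neutral monoisotopic
    mass (of the free aglycon as it sits in the glycoside, i.e. glycoside minus
    glycan residues and sulfates).  ``lactone`` is ``"18(20)"``, ``"18(16)"``
    or ``None``; ``side_chain_class`` names a row of the side-chain
    neutral-loss table in :mod:`saponinms.fragmenter` (or ``None`` if unknown).
    """

    neutral_mass: float | None = None
    formula: Formula | None = None
    lactone: str | None = None
    n_acetoxy: int = 0
    side_chain_class: str | None = None

    def __post_init__(self):
        if self.neutral_mass is None and self.formula is None:
            raise ValueError("aglycon needs a neutral_mass or a formula")
        if self.lactone is not None and self.lactone not in LACTONES:
            raise ValueError(f"lactone must be one of {LACTONES} or None")
        if self.n_acetoxy < 0:
            raise ValueError("n_acetoxy must be >= 0")

    def mass(self, mode: str = "mono") -> float:
        _check_mode(mode)
        m = self.formula.mass if self.formula is not None else self.neutral_mass
        return float(round(m)) if mode == "nominal" else m


@dataclass(frozen=True)
class Glycoside:
    """A named triterpene glycoside: aglycon + glycan tree + provenance."""

    name: str
    aglycon: AglyconSpec
    glycan: GlycanTree
    provenance: dict = field(default_factory=dict)

    @property
    def n_sulfates(self) -> int:
        return self.glycan.n_sulfates

    def neutral_mass(self, mode: str = "mono") -> float:
        """Mass of the free-acid form (sulfates as -OSO3H)."""
        return (
            self.aglycon.mass(mode)
            + self.glycan.residues_mass(mode)
            + self.n_sulfates * piece("SO3", mode)
        )

    def salt_mass(self, mode: str = "mono") -> float:
        """Mass of the sodium salt (one Na per sulfate), the species M in the
        [M-nNa]n- adduct notation for sulfated glycosides."""
        return self.neutral_mass(mode) + self.n_sulfates * piece("Na_minus_H", mode)

    def precursor_mz(
        self, n_charges: int | None = None, mode: str = "mono"
    ) -> tuple[float, str]:
        """Negative-mode precursor m/z and adduct label.

        Non-sulfated compounds ionize as [M-H]-; sulfated compounds (sodium
        salts) lose n sodium cations giving [M-nNa]n-, with n bounded by the
        sulfate count.  Returns ``(mz, label)``.
        """
        _check_mode(mode)
        if n_charges is None:
            n_charges = max(1, self.n_sulfates)
        if n_charges < 1:
            raise ValueError("n_charges must be >= 1")
        if n_charges > max(1, self.n_sulfates):
            raise ValueError(
                f"n_charges={n_charges} exceeds the sulfate count "
                f"({self.n_sulfates}); multiply-charged [M-nNa]n- ions require "
                "one sulfate per charge"
            )
        if self.n_sulfates == 0:
            mz = self.neutral_mass(mode) - piece("proton", mode)
            return mz, "[M-H]-"
        n = n_charges
        mz = (self.salt_mass(mode) - n * piece("Na", mode)) / n
        label = "[M-Na]-" if n == 1 else f"[M-{n}Na]{n}-"
        return mz, label

    def with_glycan(self, glycan: GlycanTree) -> "Glycoside":
        return replace(self, glycan=glycan)


def precursor_mz(
    g: Glycoside, n_charges: int | None = None, mode: str = "mono"
) -> tuple[float, str]:
    """Functional wrapper around :meth:`Glycoside.precursor_mz`."""
    return g.precursor_mz(n_charges=n_charges, mode=mode)


# --- structure file format ---------------------------------------------------
#
# One glycoside per record, records separated by blank lines:
#
#   name: psolusoside E
#   species: Psolus fabricii
#   aglycon_mass: 467.0
#   lactone: 18(20)
#   acetoxy: 0
#   side_chain: -
#   glycan: Xyl-Qui-Glc(S)-MeGlc
#   branch@2: Xyl
#
# "(S)" marks a sulfated unit; branch@N attaches a linear branch at the N-th
# main-chain unit (branch@<code> is accepted on input and resolves to the
# first main-chain unit with that code).


def _parse_chain(text: str) -> list[GlycanUnit]:
    units = []
    for token in text.strip().split("-"):
        token = token.strip()
        m = re.fullmatch(r"([A-Za-z]+)(\(S\))?", token)
        if not m:
            raise ValueError(f"cannot parse glycan unit {token!r}")
        units.append(GlycanUnit(m.group(1), sulfated=bool(m.group(2))))
    return units


def format_glycan(tree: GlycanTree) -> str:
    return "-".join(str(u) for u in tree.main)


def parse_structures(text: str) -> list[Glycoside]:
    """Parse the plain-text structure format into glycosides."""
    records: list[dict] = []
    current: dict[str, str] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            if current:
                records.append(current)
                current, order = {}, []
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'key: value', got {line!r}")
        key, value = line.split(":", 1)
        key = key.strip()
        if key in current and not key.startswith("branch@"):
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        current[key] = value.strip()
        order.append(key)
    if current:
        records.append(current)

    out = []
    for rec in records:
        if "name" not in rec or "glycan" not in rec:
            raise ValueError("each record needs 'name' and 'glycan' keys")
        if "aglycon_formula" in rec:
            agl_formula, agl_mass = Formula(rec["aglycon_formula"]), None
        elif "aglycon_mass" in rec:
            agl_formula, agl_mass = None, float(rec["aglycon_mass"])
        else:
            raise ValueError(f"record {rec['name']!r}: needs aglycon_mass or aglycon_formula")
        lactone = rec.get("lactone", "none")
        lactone = None if lactone in ("none", "-") else lactone
        side_chain = rec.get("side_chain", "-")
        side_chain = None if side_chain in ("-", "none", "") else side_chain
        aglycon = AglyconSpec(
            neutral_mass=agl_mass,
            formula=agl_formula,
            lactone=lactone,
            n_acetoxy=int(rec.get("acetoxy", "0")),
            side_chain_class=side_chain,
        )
        main = _parse_chain(rec["glycan"])
        branches = []
        for key, value in rec.items():
            if not key.startswith("branch@"):
                continue
            anchor = key[len("branch@"):]
            if anchor.isdigit():
                pos = int(anchor)
            else:
                codes = [u.code for u in main]
                if anchor not in codes:
                    raise ValueError(
                        f"record {rec['name']!r}: branch anchor {anchor!r} not on main chain"
                    )
                pos = codes.index(anchor) + 1
            branches.append((pos, _parse_chain(value)))
        provenance = {
            k: rec[k] for k in ("species", "family") if k in rec
        }
        out.append(
            Glycoside(
                name=rec["name"],
                aglycon=aglycon,
                glycan=GlycanTree(main, branches),
                provenance=provenance,
            )
        )
    return out


def format_structure(g: Glycoside) -> str:
    """Serialize one glycoside to the structure file format (normalized)."""
    lines = [f"name: {g.name}"]
    for k in ("species", "family"):
        if g.provenance.get(k):
            lines.append(f"{k}: {g.provenance[k]}")
    if g.aglycon.formula is not None:
        lines.append(f"aglycon_formula: {g.aglycon.formula}")
    else:
        lines.append(f"aglycon_mass: {g.aglycon.neutral_mass:.4f}")
    lines.append(f"lactone: {g.aglycon.lactone or 'none'}")
    lines.append(f"acetoxy: {g.aglycon.n_acetoxy}")
    lines.append(f"side_chain: {g.aglycon.side_chain_class or '-'}")
    lines.append(f"glycan: {format_glycan(g.glycan)}")
    for pos, chain in g.glycan.branches:
        lines.append(f"branch@{pos}: " + "-".join(str(u) for u in chain))
    return "\n".join(lines) + "\n"


def write_structures(glycosides, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(format_structure(g) for g in glycosides))


def load_structures(path) -> list[Glycoside]:
    with open(path) as fh:
        return parse_structures(fh.read())
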
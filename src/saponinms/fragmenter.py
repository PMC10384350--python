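"""Theoretical negative-mode CID fragment generation for triterpene glycosides.

Generates the glycosidic-bond ladder (Y/B/C/Z ions in the Domon-Costello
nomenclature), aglycon-related secondary losses (CO2 from the lactone, AcOH
from acetoxy groups, water), sulfate chemistry (HSO4- charge reduction,
neutral SO3 loss, sulfate diagnostics) and the side-chain neutral-loss
signatures of monosulfated holostane glycosides.

Ion chemistry conventions (validated against published fragment ladders of
psolusosides A, C1 and E):

* Non-sulfated glycosides ionize as [M-H]-; all fragments are singly charged.
* Sulfated glycosides are sodium salts M; the precursor is [M-nNa]n- and a
  fragment may carry charge z' <= min(n, retained sulfate count).
* B-type ions (non-reducing end, sulfate retains the charge):
  m/z = (sum residues + n_SO3 * 79.9568 - z * 1.00783) / z.
* Y-type ions (aglycon-retaining); a cleaved sulfated unit departs with its
  sodium counter-ion:
  m/z = (M_salt - sum residues - s_c*SO3 - (z'+s_c)*Na + s_c*H) / z'.
* C = B + H2O, Z = Y - H2O
* HSO4- loss from a multiply-charged ion reduces the charge:
  m/z' = (z*m/z - 96.9601) / (z-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .chem_model import (
    AglyconSpec,
    Glycoside,
    piece,
    residue_mass,
)

__all__ = [
    "FragmentAnnotation",
    "FragmentationConfig",
    "SideChainClass",
    "SIDE_CHAIN_CLASSES",
    "glycosidic_ladder",
    "secondary_losses",
    "sulfate_losses",
    "side_chain_losses",
    "theoretical_spectrum",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentAnnotation:
    """One theoretical fragment ion.

    ``core`` is the bracket content of the conventional label (the label of
    ``core='M-H-MeGlc'`` at charge 1 is ``[M-H-MeGlc]-``); ``cleaved_units``
    are flat glycan node indices removed relative to the precursor (Y-side)
    or retained (B-side); ``parent`` is the label of the fragment a secondary
    loss was applied to.
    """

    core: str
    ion_type: str
    charge: int
    mz: float
    cleaved_units: tuple[int, ...] = ()
    parent: str | None = None

    @property
    def label(self) -> str:
        suffix = "-" if self.charge == 1 else f"{self.charge}-"
        return f"[{self.core}]{suffix}"

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"fragment m/z must be positive, got {self.mz}")
        if self.charge < 1:
            raise ValueError("fragment charge must be >= 1")


@dataclass(frozen=True)
class FragmentationConfig:
    """Switches for :func:`theoretical_spectrum`.

    ``mode`` selects nominal (integer) or monoisotopic mass arithmetic;
    ``n_charges`` defaults to the adduct rule (1, or the sulfate count);
    ``cross_ring`` enables the single 0,2-type cross-ring variant (+C2H2O2 on
    B ions); ``include_z`` gates the rarely observed Z series.
    """

    mode: str = "mono"
    n_charges: int | None = None
    include_bc: bool = True
    include_z: bool = False
    cross_ring: bool = False
    water_loss: bool = True
    secondary: bool = True
    sulfate: bool = True
    side_chain: bool = True


def _unit_str(unit) -> str:
    return f"{unit.code}SO3" if unit.sulfated else unit.code


def glycosidic_ladder(
    g: Glycoside,
    n_charges: int | None = None,
    mode: str = "mono",
    include_bc: bool = True,
    include_z: bool = False,
) -> list[FragmentAnnotation]:
    """Y/B/C/Z glycosidic-bond fragments of a glycoside, precursor included.

    Y-type ions are generated for every descendant-closed set of removable
    units (all single and combined cleavages across branches, down to the
    bare-aglycon Y0); B/C-type ions for every non-reducing-end subtree that
    can hold the charge (>=1 sulfate in sulfated chemistry; any non-root
    subtree by deprotonation in [M-H]- chemistry).
    """
    tree = g.glycan
    if tree.n_units < 1:
        raise ValueError("glycan is empty")
    sulfated = g.n_sulfates > 0
    prec_mz, prec_label = g.precursor_mz(n_charges=n_charges, mode=mode)
    z_prec = n_charges if n_charges is not None else max(1, g.n_sulfates)

    H = piece("H", mode)
    NA = piece("Na", mode)
    SO3 = piece("SO3", mode)
    H2O = piece("H2O", mode)

    # strip the bracket/charge decoration from the adduct label to get a core
    frags: list[FragmentAnnotation] = [
        FragmentAnnotation(
            core=prec_label.split("]")[0][1:],
            ion_type="precursor",
            charge=z_prec,
            mz=prec_mz,
        )
    ]

    total_s = g.n_sulfates
    salt = g.salt_mass(mode) if sulfated else g.neutral_mass(mode)

    # --- Y series: remove every descendant-closed unit set
    for removal in tree.removal_sets():
        res = sum(residue_mass(tree.units[i].code, mode) for i in removal)
        s_c = sum(tree.units[i].sulfated for i in removal)
        units_part = "-".join(
            _unit_str(tree.units[i]) for i in sorted(removal, reverse=True)
        )
        if not sulfated:
            mz = g.neutral_mass(mode) - res - piece("proton", mode)
            frags.append(
                FragmentAnnotation(
                    core=f"M-H-{units_part}",
                    ion_type="Y",
                    charge=1,
                    mz=mz,
                    cleaved_units=tuple(sorted(removal)),
                )
            )
        else:
            s_r = total_s - s_c
            for z in range(1, min(z_prec, max(s_r, 0)) + 1):
                n_na = z + s_c
                mz = (salt - res - s_c * SO3 - n_na * NA + s_c * H) / z
                na_part = "Na" if n_na == 1 else f"{n_na}Na"
                frags.append(
                    FragmentAnnotation(
                        core=f"M-{na_part}-{units_part}",
                        ion_type="Y",
                        charge=z,
                        mz=mz,
                        cleaved_units=tuple(sorted(removal)),
                    )
                )

    if include_z:
        for f in [f for f in frags if f.ion_type == "Y"]:
            frags.append(
                FragmentAnnotation(
                    core=f.core + "-H2O",
                    ion_type="Z",
                    charge=f.charge,
                    mz=f.mz - H2O / f.charge,
                    cleaved_units=f.cleaved_units,
                    parent=f.label,
                )
            )

    # --- B/C series: non-reducing-end subtrees
    if include_bc:
        for i in range(tree.n_units):
            subtree = tree.subtree(i)
            s_t = sum(tree.units[j].sulfated for j in subtree)
            if sulfated and s_t == 0:
                logger.debug(
                    "skipping B/C ion for sulfate-free subtree at node %d of %s",
                    i,
                    g.name,
                )
                continue
            if not sulfated and i == 0:
                # B of the entire glycan is not observed in [M-H]- chemistry
                continue
            res = sum(residue_mass(tree.units[j].code, mode) for j in subtree)
            units_part = "+".join(
                _unit_str(tree.units[j]) for j in sorted(subtree, reverse=True)
            )
            z_max = min(z_prec, s_t) if sulfated else 1
            for z in range(1, z_max + 1):
                mz = (res + s_t * SO3 - z * H) / z
                if sulfated:
                    na_part = "Na" if z == 1 else f"{z}Na"
                    core = f"{units_part}-{na_part}"
                else:
                    core = f"{units_part}-H"
                frags.append(
                    FragmentAnnotation(
                        core=core,
                        ion_type="B",
                        charge=z,
                        mz=mz,
                        cleaved_units=tuple(sorted(subtree)),
                    )
                )
                if sulfated:
                    c_core = f"{units_part}+H2O-{'Na' if z == 1 else f'{z}Na'}"
                else:
                    c_core = f"{units_part}+H2O-H"
                frags.append(
                    FragmentAnnotation(
                        core=c_core,
                        ion_type="C",
                        charge=z,
                        mz=mz + H2O / z,
                        cleaved_units=tuple(sorted(subtree)),
                    )
                )

    return _finalize(frags)


def _finalize(frags: list[FragmentAnnotation]) -> list[FragmentAnnotation]:
    """Deduplicate by (label, charge) and sort by m/z."""
    seen: dict[tuple[str, int], FragmentAnnotation] = {}
    for f in frags:
        seen.setdefault((f.label, f.charge), f)
    return sorted(seen.values(), key=lambda f: (f.mz, f.charge, f.label))


def secondary_losses(
    fragments: list[FragmentAnnotation],
    aglycon: AglyconSpec,
    mode: str = "mono",
    water_loss: bool = True,
) -> list[FragmentAnnotation]:
    """Expand aglycon-retaining fragments with lactone/acetoxy/water losses.

    Lactone-bearing aglycons lose CO2 (44) and CO2+H2O; acetoxy-bearing lose
    acetic acid (60); the combination of an acetoxy group with an
    18(20)-lactone additionally gives the diagnostic 104 (C2H4O2 + CO2) loss.
    """
    combos: list[tuple[str, tuple[str, ...], float]] = []
    if aglycon.lactone is not None:
        combos.append(("loss_CO2", ("CO2",), piece("CO2", mode)))
        combos.append(
            ("loss_CO2", ("CO2", "H2O"), piece("CO2", mode) + piece("H2O", mode))
        )
    if aglycon.n_acetoxy >= 1:
        combos.append(("loss_AcOH", ("AcOH",), piece("AcOH", mode)))
        if aglycon.lactone == "18(20)":
            combos.append(("loss_AcOH_CO2", ("AcOH", "CO2"), piece("AcOH_CO2", mode)))
    if water_loss:
        combos.append(("loss_H2O", ("H2O",), piece("H2O", mode)))

    out = list(fragments)
    for f in fragments:
        if f.ion_type not in ("precursor", "Y", "Z"):
            continue
        for ion_type, names, mass in combos:
            mz = f.mz - mass / f.charge
            if mz <= 0:
                continue
            out.append(
                FragmentAnnotation(
                    core=f.core + "-" + "-".join(names),
                    ion_type=ion_type,
                    charge=f.charge,
                    mz=mz,
                    cleaved_units=f.cleaved_units,
                    parent=f.label,
                )
            )
    return _finalize(out)


def sulfate_losses(
    fragments: list[FragmentAnnotation],
    g: Glycoside,
    mode: str = "mono",
) -> list[FragmentAnnotation]:
    """Sulfate chemistry: charge-reduced HSO4- losses, neutral SO3 losses and
    the sulfate diagnostic ions.

    Every multiply-charged fragment yields a charge-reduced variant by loss of
    the HSO4- anion (m/z' = (z*m/z - 96.9601)/(z-1)) and a same-charge variant
    by neutral SO3 loss.  Diagnostics always included for sulfated glycosides:
    HSO4- at m/z 96.9601 and the sulfated-monosaccharide anion of every
    sulfated unit (MeGlcSO3 255, GlcSO3 241, QuiSO3/MeXylSO3 225, XylSO3 211
    nominal).
    """
    if g.n_sulfates == 0:
        return list(fragments)
    H = piece("H", mode)
    SO3 = piece("SO3", mode)
    hso4_loss = piece("HSO4", mode)

    out = list(fragments)
    for f in fragments:
        if f.ion_type in ("diagnostic_HSO4", "diagnostic_sulfomonosaccharide"):
            continue
        if f.charge >= 2:
            z = f.charge
            mz_red = (z * f.mz - hso4_loss) / (z - 1)
            out.append(
                FragmentAnnotation(
                    core=f.core + "-HSO4",
                    ion_type="loss_HSO4",
                    charge=z - 1,
                    mz=mz_red,
                    cleaved_units=f.cleaved_units,
                    parent=f.label,
                )
            )
            out.append(
                FragmentAnnotation(
                    core=f.core + "-SO3",
                    ion_type="loss_SO3",
                    charge=z,
                    mz=f.mz - SO3 / z,
                    cleaved_units=f.cleaved_units,
                    parent=f.label,
                )
            )

    # diagnostic ions: the HSO4- anion keeps its accurate mass in every mode
    # (it is conventionally quoted as 96.9 even inside integer ladders)
    from .chem_model import MASS

    out.append(
        FragmentAnnotation(core="HSO4", ion_type="diagnostic_HSO4", charge=1, mz=MASS["HSO4"])
    )
    seen_codes = set()
    for unit in g.glycan.units:
        if unit.sulfated and unit.code not in seen_codes:
            seen_codes.add(unit.code)
            mz = residue_mass(unit.code, mode) + SO3 - H
            out.append(
                FragmentAnnotation(
                    core=f"{unit.code}SO3-Na",
                    ion_type="diagnostic_sulfomonosaccharide",
                    charge=1,
                    mz=mz,
                )
            )
    return _finalize(out)


# --- side-chain neutral-loss signatures --------------------------------------


@dataclass(frozen=True)
class SideChainClass:
    """One side-chain structural class of monosulfated holostane glycosides
    and its diagnostic neutral-loss signature (integer Da).

    ``r1..r4`` are the side-chain substituents (``'-'`` marks an absent
    position), ``double_bonds`` the unsaturation pattern.  ``losses`` maps
    fragment families (b1/b2 retro-Diels-Alder B-ring ions, the f-series from
    C-20--C-22 cleavage with co-eliminated pieces, and the h ion from
    C-22--C-23 cleavage, observed only for Delta-25 side chains) to the
    neutral-loss mass.
    """

    key: str
    r1: str
    r2: str
    r3: str
    r4: str
    double_bonds: str
    losses: dict[str, int] = field(hash=False)
    example: str = ""

    @property
    def saturated(self) -> bool:
        return self.double_bonds == "sat"

    @property
    def oxygenated(self) -> bool:
        """Oxygen-containing substituent on the side chain (OH/keto/OOH)."""
        return any(r in ("OH", "=O", "OOH") for r in (self.r1, self.r2, self.r3, self.r4))


LOSS_KEYS = ("b1", "b2", "f+C6H8O4", "f+C4H6O4", "f+C3H4O4", "f+CO2", "h")


def _scc(key, r1, r2, r3, r4, db, values, example):
    losses = {k: v for k, v in zip(LOSS_KEYS, values) if v is not None}
    return key, SideChainClass(key, r1, r2, r3, r4, db, losses, example)


#: the thirteen side-chain classes with published neutral-loss signatures.
SIDE_CHAIN_CLASSES: dict[str, SideChainClass] = dict(
    [
        _scc("OAc,H,H,H|sat", "OAc", "H", "H", "H", "sat",
             (374, 362, 230, 204, 190, 130, None), "Cucumarioside H7"),
        _scc("OAc,H,H,H|d24", "OAc", "H", "H", "H", "d24",
             (372, 360, 228, 202, 188, 128, None), "Lefevreoside B"),
        _scc("OAc,H,H,H|d22E24", "OAc", "H", "H", "H", "d22E24",
             (370, 358, 226, 200, None, None, None), "Typicoside A1"),
        _scc("OAc,H,H,H|d22Z24", "OAc", "H", "H", "H", "d22Z24",
             (370, 358, 226, 200, None, None, None), "Cucumarioside H5"),
        _scc("OAc,H,H,-|d25", "OAc", "H", "H", "-", "d25",
             (372, 360, 228, 202, 188, 128, 70), "Colochiroside A1"),
        _scc("=O,H,H,-|d25", "=O", "H", "H", "-", "d25",
             (328, 316, None, None, None, 128, 70), "Philinopside E"),
        _scc("H,H,H,-|d25", "H", "H", "H", "-", "d25",
             (314, 302, None, None, None, 128, 70), "Colochiroside A2"),
        _scc("H,H,H,H|d24", "H", "H", "H", "H", "d24",
             (314, 302, None, None, None, None, None), "Colochiroside A3"),
        _scc("OAc,H,OH,-|d25", "OAc", "H", "OH", "-", "d25",
             (388, 376, 244, 218, 204, 144, 86), "Colochiroside B1"),
        _scc("OAc,H,H,OH|d23", "OAc", "H", "H", "OH", "d23",
             (388, 376, 244, 218, None, None, None), "Colochiroside B2"),
        _scc("OAc,H,=O,-|d25", "OAc", "H", "=O", "-", "d25",
             (386, 374, 242, 216, 202, 142, 84), "Colochiroside B3"),
        _scc("OAc,=O,H,H|sat", "OAc", "=O", "H", "H", "sat",
             (388, 376, 244, 218, 204, 144, None), "Okhotoside A1-1"),
        _scc("OAc,OH,H,H|sat", "OAc", "OH", "H", "H", "sat",
             (390, 378, 246, 220, 206, None, None), "Frondoside D"),
    ]
)

_SC_ION_TYPE = {
    "b1": "sidechain_b1",
    "b2": "sidechain_b2",
    "f+C6H8O4": "sidechain_f_series",
    "f+C4H6O4": "sidechain_f_series",
    "f+C3H4O4": "sidechain_f_series",
    "f+CO2": "sidechain_f_series",
    "h": "sidechain_h",
}


def side_chain_losses(aglycon: AglyconSpec | str, mode: str = "nominal") -> dict[str, int]:
    """Neutral-loss signature of a side-chain class (integer Da).

    Accepts an :class:`AglyconSpec` or a class key.  The signatures are
    defined at integer precision in both mass modes.  Raises ``ValueError``
    listing the supported classes for an unknown key.
    """
    key = aglycon.side_chain_class if isinstance(aglycon, AglyconSpec) else aglycon
    if key not in SIDE_CHAIN_CLASSES:
        raise ValueError(
            f"unknown side-chain class {key!r}; supported classes: "
            + ", ".join(SIDE_CHAIN_CLASSES)
        )
    return dict(SIDE_CHAIN_CLASSES[key].losses)


def _side_chain_ions(
    precursor: FragmentAnnotation, aglycon: AglyconSpec
) -> list[FragmentAnnotation]:
    if aglycon.side_chain_class is None:
        return []
    losses = side_chain_losses(aglycon)
    out = []
    for name, loss in losses.items():
        mz = precursor.mz - loss / precursor.charge
        if mz <= 0:
            continue
        out.append(
            FragmentAnnotation(
                core=f"{precursor.core}-{name}({loss})",
                ion_type=_SC_ION_TYPE[name],
                charge=precursor.charge,
                mz=mz,
                parent=precursor.label,
            )
        )
    return out


def _cross_ring_ions(
    fragments: list[FragmentAnnotation], mode: str
) -> list[FragmentAnnotation]:
    """0,2-type cross-ring variants: +C2H2O2 (58) on B ions."""
    c2h2o2 = piece("C2H2O2", mode)
    out = []
    for f in fragments:
        if f.ion_type != "B":
            continue
        head, _, tail = f.core.rpartition("-")
        out.append(
            FragmentAnnotation(
                core=f"{head}+C2H2O2-{tail}",
                ion_type="A02",
                charge=f.charge,
                mz=f.mz + c2h2o2 / f.charge,
                cleaved_units=f.cleaved_units,
                parent=f.label,
            )
        )
    return out


def theoretical_spectrum(
    g: Glycoside, config: FragmentationConfig | None = None, **overrides
) -> list[FragmentAnnotation]:
    """Full theoretical fragment list for a glycoside: glycosidic ladder,
    secondary losses, sulfate chemistry, side-chain signature and (optionally)
    the 0,2-type cross-ring variant.  Deterministic, duplicate-free, sorted
    by m/z."""
    if config is None:
        config = FragmentationConfig()
    if overrides:
        from dataclasses import replace

        config = replace(config, **overrides)

    frags = glycosidic_ladder(
        g,
        n_charges=config.n_charges,
        mode=config.mode,
        include_bc=config.include_bc,
        include_z=config.include_z,
    )
    if config.cross_ring:
        frags = _finalize(frags + _cross_ring_ions(frags, config.mode))
    if config.secondary:
        frags = secondary_losses(
            frags, g.aglycon, mode=config.mode, water_loss=config.water_loss
        )
    if config.sulfate:
        frags = sulfate_losses(frags, g, mode=config.mode)
    if config.side_chain and g.aglycon.side_chain_class is not None:
        precursor = next(f for f in frags if f.ion_type == "precursor")
        frags = _finalize(frags + _side_chain_ions(precursor, g.aglycon))
    return frags
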
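"""Reference compounds and published mass tables used as worked examples.

The structures here are mass-level fixtures for well-characterized
psolusosides (Psolus fabricii) and cucumariosides (Eupentacta fraudatrix):
the glycan sequence and sulfation are the literature structures, while the
aglycon is given as a bare nominal mass back-computed from the published
precursor m/z (molecular formulas of these compounds are not republished
here, and the fragment-ladder arithmetic needs only the printed masses).
They are intended for nominal-mass mode.

``PRECURSOR_TABLE`` lists published calculated/measured precursor m/z pairs
(with the mass error in ppm as printed) for the 27 compounds identified in an
E. fraudatrix extract by combined spectral and retention-time matching; it
drives the ppm-arithmetic checks.
"""

from __future__ import annotations

from .chem_model import AglyconSpec, GlycanTree, GlycanUnit, Glycoside


def psolusoside_c1() -> Glycoside:
    """Non-sulfated glycoside, [M-H]- at nominal m/z 1407.

    Pentaosidic mass fixture: terminal MeGlc on the main chain and a Xyl
    branch, reproducing the published Y/secondary ladder (1363, 1231, 1213,
    1187, 1169, 1099, 1081, 1055, 1037).  Aglycon nominal mass 660
    back-computed from the precursor.
    """
    return Glycoside(
        name="psolusoside C1",
        aglycon=AglyconSpec(neutral_mass=660.0, lactone="18(20)"),
        glycan=GlycanTree(
            [GlycanUnit("Xyl"), GlycanUnit("Qui"), GlycanUnit("Glc"),
             GlycanUnit("MeGlc")],
            branches=[(2, [GlycanUnit("Xyl")])],
        ),
        provenance={"species": "Psolus fabricii"},
    )


def psolusoside_e() -> Glycoside:
    """Monosulfated tetraoside MeGlc-Glc(S)-Qui-Xyl, [M-Na]- at 1163.

    Reproduces the published B-series 695/563/417 (+475 with the cross-ring
    variant), Y 987 and the GlcSO3 (241) / HSO4 (96.9) diagnostics.
    """
    return Glycoside(
        name="psolusoside E",
        aglycon=AglyconSpec(neutral_mass=468.0, lactone="18(20)"),
        glycan=GlycanTree(
            [GlycanUnit("Xyl"), GlycanUnit("Qui"), GlycanUnit("Glc", sulfated=True),
             GlycanUnit("MeGlc")]
        ),
        provenance={"species": "Psolus fabricii"},
    )


def psolusoside_a() -> Glycoside:
    """Disulfated tetraoside MeGlc(S)-Glc(S)-Qui-Xyl, [M-2Na]2- at 621.

    Reproduces the published charge-reduction and sulfated-fragment ions
    1145, 987, 255, 248 (2-) and 96.9.
    """
    return Glycoside(
        name="psolusoside A",
        aglycon=AglyconSpec(neutral_mass=468.0, lactone="18(20)"),
        glycan=GlycanTree(
            [GlycanUnit("Xyl"), GlycanUnit("Qui"), GlycanUnit("Glc", sulfated=True),
             GlycanUnit("MeGlc", sulfated=True)]
        ),
        provenance={"species": "Psolus fabricii"},
    )


def cucumarioside_h6() -> Glycoside:
    """Monosulfated pentaoside with sulfated xylose as the first unit,
    [M-Na]- at nominal 1309; its Y1 ion (aglycon + XylSO3) sits at 723."""
    return Glycoside(
        name="cucumarioside H6",
        aglycon=AglyconSpec(
            neutral_mass=512.0, lactone="18(20)", n_acetoxy=1,
            side_chain_class="OAc,H,H,H|d24",
        ),
        glycan=GlycanTree(
            [GlycanUnit("Xyl", sulfated=True), GlycanUnit("Qui"),
             GlycanUnit("Glc"), GlycanUnit("MeXyl")],
            branches=[(2, [GlycanUnit("Xyl")])],
        ),
        provenance={"species": "Eupentacta fraudatrix"},
    )


def feature_639() -> Glycoside:
    """Annotated structural analog of cucumarioside H6 ([M-Na]- 1325): the
    terminal MeXyl replaced by Glc, so its Y3 ion is 1325 - 162 = 1163."""
    return Glycoside(
        name="feature 639",
        aglycon=AglyconSpec(
            neutral_mass=512.0, lactone="18(20)", n_acetoxy=1,
            side_chain_class="OAc,H,H,H|d24",
        ),
        glycan=GlycanTree(
            [GlycanUnit("Xyl", sulfated=True), GlycanUnit("Qui"),
             GlycanUnit("Glc"), GlycanUnit("Glc")],
            branches=[(2, [GlycanUnit("Xyl")])],
        ),
        provenance={"species": "Eupentacta fraudatrix"},
    )


#: published precursor pairs: (compound, calculated m/z, measured m/z,
#: mass error in ppm as printed).
PRECURSOR_TABLE = [
    ("Cucumarioside H8", 1281.5216, 1281.5135, 6.3),
    ("Cucumarioside I3", 702.2487, 702.2474, 1.7),
    ("Cucumarioside I4", 630.2093, 630.2104, -1.7),
    ("Cucumarioside H2", 1325.5478, 1325.5474, 0.3),
    ("Colochiroside B1", 1193.5055, 1193.4989, 5.6),
    ("Pacificusoside A", 1201.5284, 1201.5260, 2.0),
    ("Colochiroside B2", 1193.5055, 1193.5030, 2.1),
    ("Cucumarioside H3", 1181.4691, 1181.4680, 1.0),
    ("Quadrangularisoside A", 1209.5004, 1209.4946, 4.8),
    ("Cucumarioside A7", 1113.5487, 1113.5455, 2.9),
    ("Cucumarioside A11", 1113.5487, 1113.5454, 3.0),
    ("Pacificusoside J", 1131.5229, 1131.5194, 3.1),
    ("Pacificusoside B", 1101.5123, 1101.5099, 2.2),
    ("Magnumoside B3", 1135.5000, 1135.4929, 6.3),
    ("Cucumarioside H4", 1353.5791, 1353.5759, 2.3),
    ("Typicoside C2", 643.2354, 643.2363, -1.5),
    ("Cucumarioside H5", 1307.5372, 1307.5366, 0.5),
    ("Colochiroside A1", 1193.5051, 1193.5055, -0.3),
    ("Cucumarioside H6", 1309.5529, 1309.5569, -3.1),
    ("Typicoside A1", 1175.4950, 1175.4933, 1.4),
    ("Cucumarioside D", 1257.5910, 1257.5961, -4.1),
    ("Pacificusoside G", 1081.5225, 1081.5248, -2.1),
    ("Cucumarioside C1", 1227.5804, 1227.5812, -0.6),
    ("Pacificusoside E", 1081.5225, 1081.5195, 2.7),
    ("Cucumarioside C2", 1227.5804, 1227.5812, -0.6),
    ("Cucumarioside A1", 1097.5538, 1097.5474, 5.9),
    ("Cucumarioside A15", 1099.5694, 1099.5643, 4.7),
]
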
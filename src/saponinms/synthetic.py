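"""Synthetic structures, spectra and retention times for self-contained testing.

The generator draws glycosides obeying the biosynthetic grammar of sea-cucumber
triterpene glycosides (xylose as the first unit, methylated monosaccharides
terminal, 2-6 units, up to 4 sulfates, branching at the first or second unit)
with sulfation/lactone frequencies matching the composition of the reference
compound collection (61/55/43/23/9 per 191 for 0-4 sulfates).  Spectra are the
theoretical fragment set with an ion-type intensity model (Y-series most
intense, then B, then secondary losses), Gaussian m/z noise and a configurable
fraction of spurious peaks.  Retention times come from an additive structural
model whose coefficient signs encode the observed reversed-phase trends
(sulfates shorten RT, acetoxy groups and the 18(20)-lactone lengthen it,
side-chain oxygenation shortens it, extra monosaccharides shorten it slightly,
saturated side chains lengthen it); magnitudes are free parameters chosen to
keep predictions inside the observed 4.3-18.9 min elution window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_model import AglyconSpec, GlycanTree, GlycanUnit, Glycoside
from .fragmenter import SIDE_CHAIN_CLASSES, FragmentationConfig, theoretical_spectrum
from .speclib import LibraryRecord, Spectrum

__all__ = [
    "SimulationConfig",
    "RTModel",
    "DEFAULT_RT_MODEL",
    "generate_structure",
    "simulate_spectrum",
    "simulate_library",
    "predict_rt",
]

#: sulfation-count frequencies of the reference collection (0..4 sulfates).
SULFATE_WEIGHTS = np.array([61, 55, 43, 23, 9]) / 191.0
#: lactone frequencies: 18(20), 18(16), none.
LACTONE_WEIGHTS = np.array([150, 16, 25]) / 191.0


@dataclass(frozen=True)
class SimulationConfig:
    """Noise and intensity model for :func:`simulate_spectrum`.

    ``noise_sigma_mz`` is the per-peak Gaussian m/z error (Da);
    ``spurious_peak_fraction`` adds that fraction of uniform random peaks;
    intensities are per-ion-type base values with log-normal jitter of
    ``intensity_jitter_sigma`` (log-scale).  With all noise at zero the peak
    list equals the theoretical fragment set exactly.
    """

    noise_sigma_mz: float = 0.0
    spurious_peak_fraction: float = 0.0
    intensity_jitter_sigma: float = 0.3
    base_intensity: dict = field(
        default_factory=lambda: {
            "precursor": 900.0,
            "Y": 1000.0,
            "B": 550.0,
            "C": 250.0,
            "Z": 250.0,
            "A02": 200.0,
            "loss_CO2": 350.0,
            "loss_H2O": 300.0,
            "loss_AcOH": 320.0,
            "loss_AcOH_CO2": 320.0,
            "loss_SO3": 300.0,
            "loss_HSO4": 450.0,
            "diagnostic_HSO4": 700.0,
            "diagnostic_sulfomonosaccharide": 500.0,
            "sidechain_b1": 220.0,
            "sidechain_b2": 220.0,
            "sidechain_f_series": 180.0,
            "sidechain_h": 180.0,
        },
        hash=False,
    )
    rt_noise_sigma_min: float = 0.05
    tetrasulfated_rt_absent: bool = True
    mode: str = "mono"
    fragmentation: FragmentationConfig | None = None

    def __post_init__(self):
        if not 0.0 <= self.spurious_peak_fraction <= 1.0:
            raise ValueError("spurious_peak_fraction must be in [0, 1]")
        if self.noise_sigma_mz < 0:
            raise ValueError("noise_sigma_mz must be >= 0")


@dataclass(frozen=True)
class RTModel:
    """Additive retention-time model (minutes).

    Only the coefficient signs are structurally constrained; magnitudes are
    chosen so grammar-valid structures predict inside the observed
    ``rt_min``-``rt_max`` elution window (predictions are clipped there as a
    safeguard).
    """

    intercept: float = 12.5
    first_sulfate: float = -0.5
    per_extra_sulfate: float = -1.0        # per sulfate beyond the first
    per_acetoxy: float = 1.5
    lactone_18_20: float = 1.3
    lactone_18_16: float = 0.0
    side_chain_oxygenation: float = -3.0   # OH / keto / OOH on the side chain
    per_extra_unit: float = -0.4           # per monosaccharide beyond a bioside
    saturated_side_chain: float = 1.6
    rt_min: float = 4.3
    rt_max: float = 18.9

    def predict(self, g: Glycoside) -> float:
        rt = self.intercept
        s = g.n_sulfates
        if s >= 1:
            rt += self.first_sulfate + self.per_extra_sulfate * (s - 1)
        rt += self.per_acetoxy * g.aglycon.n_acetoxy
        if g.aglycon.lactone == "18(20)":
            rt += self.lactone_18_20
        elif g.aglycon.lactone == "18(16)":
            rt += self.lactone_18_16
        key = g.aglycon.side_chain_class
        if key is not None and key in SIDE_CHAIN_CLASSES:
            cls = SIDE_CHAIN_CLASSES[key]
            if cls.oxygenated:
                rt += self.side_chain_oxygenation
            if cls.saturated:
                rt += self.saturated_side_chain
        rt += self.per_extra_unit * max(0, g.glycan.n_units - 2)
        return float(min(max(rt, self.rt_min), self.rt_max))


DEFAULT_RT_MODEL = RTModel()


def predict_rt(g: Glycoside, model: RTModel = DEFAULT_RT_MODEL) -> float:
    """Predicted reversed-phase retention time in minutes (deterministic)."""
    return model.predict(g)


def generate_structure(
    rng: np.random.Generator, name: str | None = None, grammar: bool = True
) -> Glycoside:
    """Draw one grammar-valid glycoside.

    2-6 units rooted at Xyl, optional single branch at unit 1 or 2,
    methylated units only terminal, 0-4 sulfates at the collection
    frequencies, aglycon mass uniform on [450, 600] Da with random lactone,
    acetoxy count and side-chain class.
    """
    n_units = int(rng.integers(2, 7))
    branched = bool(n_units >= 4 and rng.random() < 0.35)
    n_branch = 1 if branched else 0
    n_main = n_units - n_branch

    inner_codes = ["Qui", "Glc", "Xyl"]
    terminal_codes = ["MeGlc", "MeXyl", "Qui", "Glc", "Xyl"]

    main_codes = ["Xyl"]
    for _ in range(n_main - 2):
        main_codes.append(str(rng.choice(inner_codes)))
    if n_main > 1:
        main_codes.append(str(rng.choice(terminal_codes)))

    branches = []
    if branched:
        pos = int(rng.integers(1, 3))  # attach at unit 1 or 2
        branches.append((pos, [GlycanUnit(str(rng.choice(terminal_codes)))]))

    n_sulf = min(int(rng.choice(5, p=SULFATE_WEIGHTS)), n_units)
    flat_positions = list(range(n_units))  # main first, then branch
    sulf_positions = set(
        int(i) for i in rng.choice(flat_positions, size=n_sulf, replace=False)
    ) if n_sulf else set()

    main_units = [
        GlycanUnit(code, sulfated=(i in sulf_positions))
        for i, code in enumerate(main_codes)
    ]
    if branched:
        pos, chain = branches[0]
        branches[0] = (
            pos,
            [GlycanUnit(chain[0].code, sulfated=(n_main in sulf_positions))],
        )
    tree = GlycanTree(main_units, branches)
    if grammar:
        tree.validate(grammar=True)

    lactone = [
        "18(20)", "18(16)", None
    ][int(rng.choice(3, p=LACTONE_WEIGHTS))]
    n_acetoxy = int(rng.choice([0, 1, 2], p=[0.5, 0.35, 0.15]))
    side_chain = str(rng.choice(list(SIDE_CHAIN_CLASSES)))
    aglycon = AglyconSpec(
        neutral_mass=float(rng.uniform(450.0, 600.0)),
        lactone=lactone,
        n_acetoxy=n_acetoxy,
        side_chain_class=side_chain,
    )
    if name is None:
        name = f"syn-{int(rng.integers(0, 10**9)):09d}"
    return Glycoside(name=name, aglycon=aglycon, glycan=tree, provenance={})


def simulate_spectrum(
    g: Glycoside,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    rt_model: RTModel = DEFAULT_RT_MODEL,
) -> Spectrum:
    """Simulate a negative-mode CID spectrum of a glycoside.

    Peak m/z values are the theoretical fragment set plus Gaussian error;
    intensities follow the per-ion-type base model with log-normal jitter;
    spurious uniform peaks are added at the configured fraction.  The
    precursor follows the adduct rules and RT comes from the additive RT
    model plus Gaussian noise (absent for tetrasulfated compounds by default,
    whose reversed-phase elution is not reproducible).
    """
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    frag_cfg = config.fragmentation or FragmentationConfig(mode=config.mode)
    frags = theoretical_spectrum(g, frag_cfg)

    mz = np.array([f.mz for f in frags])
    base = np.array(
        [config.base_intensity.get(f.ion_type, 200.0) for f in frags]
    )
    jitter = np.exp(rng.normal(0.0, config.intensity_jitter_sigma, size=mz.size))
    intensity = base * jitter
    # noise offsets are always drawn and scaled by sigma, so simulations that
    # differ only in sigma share the same unit-normal offsets (common random
    # numbers): a peak that survives the tolerance at a larger sigma also
    # survives at any smaller one
    mz = mz + config.noise_sigma_mz * rng.standard_normal(mz.size)

    prec_mz, _ = g.precursor_mz(mode=config.mode)
    n_charges = max(1, g.n_sulfates)
    if config.spurious_peak_fraction > 0:
        n_spurious = int(round(config.spurious_peak_fraction * mz.size))
        if n_spurious:
            sp_mz = rng.uniform(80.0, prec_mz, size=n_spurious)
            sp_int = 50.0 * np.exp(
                rng.normal(0.0, config.intensity_jitter_sigma, size=n_spurious)
            )
            mz = np.concatenate([mz, sp_mz])
            intensity = np.concatenate([intensity, sp_int])

    rt = None
    if not (g.n_sulfates == 4 and config.tetrasulfated_rt_absent):
        rt = predict_rt(g, rt_model) + float(rng.normal(0.0, config.rt_noise_sigma_min))
    return Spectrum(
        mz=mz,
        intensity=intensity,
        precursor_mz=prec_mz,
        charge=n_charges,
        negative=True,
        rt=rt,
        id=g.name,
        metadata={"name": g.name},
    )


def simulate_library(
    n: int,
    seed: int = 42,
    config: SimulationConfig | None = None,
) -> list[LibraryRecord]:
    """Generate ``n`` structures and their simulated spectra, fully
    deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        g = generate_structure(rng, name=f"syn-{i:04d}")
        spec = simulate_spectrum(g, config=config, rng=rng)
        records.append(LibraryRecord(spectrum=spec, glycoside=g))
    return records
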
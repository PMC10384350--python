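"""Rule-based structural inference from negative-mode CID spectra.

Infers, from a query spectrum alone, the evidence a saponin analyst reads off
a CID spectrum:

* sulfate count (precursor charge for multiply-charged [M-nNa]n- ions; the
  HSO4- and sulfo-monosaccharide diagnostics for singly charged ones),
* glycan sequence candidates from the Y-type neutral-loss ladder
  (residue steps 176/162/146/132, with the Qui/MeXyl isobar kept ambiguous),
* aglycon flags from the 60/104/44/18 Da neutral losses,
* side-chain class from the published neutral-loss signatures,
* analog hypotheses from characteristic precursor mass differences.

Neutral-loss differences are computed on singly-charged-equivalent masses so
multiply-charged ladders participate: an ion of charge z and m/z x maps to
z*x + (z-1)*m_Na (sodium-salt chemistry) before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_model import MASS, piece, residue_mass
from .fragmenter import SIDE_CHAIN_CLASSES
from .speclib import LibraryRecord, Spectrum

__all__ = [
    "Evidence",
    "SulfationEstimate",
    "GlycanCandidate",
    "AglyconFlags",
    "SideChainMatch",
    "AnalogHypothesis",
    "AnnotationReport",
    "infer_sulfation",
    "sequence_glycan",
    "infer_composition",
    "detect_aglycon_features",
    "classify_side_chain",
    "annotate_analogs",
    "annotate",
]

#: ranking order of residues for deterministic tie-breaking.
_RESIDUE_ORDER = ("MeGlc", "Glc", "Qui", "Xyl")

#: sulfate diagnostic ions (label -> monoisotopic m/z, nominal m/z).
_SULFATE_DIAGNOSTICS = {
    "HSO4-": (MASS["HSO4"], MASS["HSO4"]),
    "XylSO3-Na": (residue_mass("Xyl") + MASS["SO3"] - MASS["H"], 211),
    "QuiSO3-Na": (residue_mass("Qui") + MASS["SO3"] - MASS["H"], 225),
    "GlcSO3-Na": (residue_mass("Glc") + MASS["SO3"] - MASS["H"], 241),
    "MeGlcSO3-Na": (residue_mass("MeGlc") + MASS["SO3"] - MASS["H"], 255),
}


@dataclass(frozen=True)
class Evidence:
    """One evidence line: which peak, which mass-difference/diagnostic rule."""

    peak_index: int
    mz: float
    rule: str


@dataclass(frozen=True)
class SulfationEstimate:
    count: int
    lower_bound: bool
    evidence: tuple[Evidence, ...]


def _equivalent_mass(mz: float, z: int, sulfated_chem: bool, mode: str) -> float:
    """Singly-charged-equivalent mass of an ion (its m/z had it kept one
    charge): z*m/z plus (z-1) sodium (salt chemistry) or proton masses."""
    carrier = piece("Na", mode) if sulfated_chem else piece("proton", mode)
    return z * mz + (z - 1) * carrier


def infer_sulfation(s: Spectrum, tol: float = 0.05, mode: str = "mono") -> SulfationEstimate:
    """Estimate the sulfate count of the precursor.

    For precursor charge z >= 2 the adduct rule [M-nNa]n- fixes the count at
    z.  For z = 1 the estimate is a lower bound: >=1 if any sulfate diagnostic
    ion (HSO4- 96.96 or a sulfo-monosaccharide anion) is present, else 0.
    Diagnostic hits are reported as evidence in both cases.
    """
    if s.precursor_mz is None:
        raise ValueError("spectrum has no precursor m/z")
    evidence = []
    col = 0 if mode == "mono" else 1
    for name, masses in _SULFATE_DIAGNOSTICS.items():
        target = masses[col]
        hits = np.nonzero(np.abs(s.mz - target) <= tol)[0]
        for i in hits:
            evidence.append(
                Evidence(int(i), float(s.mz[i]), f"diagnostic ion {name} at {target:.4f}")
            )
    if s.charge >= 2:
        evidence.insert(
            0,
            Evidence(-1, s.precursor_mz, f"[M-nNa]n- adduct rule: charge {s.charge}"),
        )
        return SulfationEstimate(s.charge, False, tuple(evidence))
    if evidence:
        return SulfationEstimate(1, True, tuple(evidence))
    return SulfationEstimate(0, False, ())


# --- glycan sequencing -------------------------------------------------------


@dataclass(frozen=True)
class GlycanCandidate:
    """A Y-ladder reading: residue steps from the terminal unit inwards.

    Each step is a tuple of possible codes (the 146 Da step is always the
    ambiguous ``("Qui", "MeXyl")``), with ``sulfated=True`` when the step mass
    includes a departing sulfate (sodium-salt form).  ``score`` is the
    fraction of the longest observed ladder this candidate explains.
    """

    steps: tuple[tuple[str, ...], ...]
    sulfated_steps: tuple[bool, ...]
    peak_indices: tuple[int, ...]
    matched_intensity: float
    mass_deviation: float = 0.0
    score: float = 0.0

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def composition(self) -> tuple[str, ...]:
        """Sorted residue multiset with the isobaric pair kept ambiguous."""
        return tuple(
            sorted("Qui/MeXyl" if len(c) > 1 else c[0] for c in self.steps)
        )


def _step_table(mode: str, sulfated_chem: bool):
    steps = []
    for code in _RESIDUE_ORDER:
        codes = ("Qui", "MeXyl") if code == "Qui" else (code,)
        steps.append((codes, residue_mass(code, mode), False))
        if sulfated_chem:
            # a cleaved sulfated unit departs with SO3 and its Na counter-ion
            extra = piece("SO3", mode) + piece("Na", mode) - piece("H", mode)
            steps.append((codes, residue_mass(code, mode) + extra, True))
    return steps


def sequence_glycan(
    s: Spectrum,
    tol: float = 0.05,
    mode: str = "mono",
    max_candidates: int = 50,
) -> list[GlycanCandidate]:
    """Read glycan sequence candidates from the Y-type neutral-loss ladder.

    Depth-first search from the precursor over peak-to-peak differences
    matching the residue masses (and their sulfated variants in sodium-salt
    chemistry).  Maximal ladders are reported terminal-to-root, ranked by
    matched-step count, then cumulative mass deviation of the steps, then
    summed matched intensity, then lexicographic residue order.  Mass
    deviation outranks intensity so that a near-isobaric impostor step
    (e.g. Xyl + CO2 at 176.032 mimicking MeGlc at 176.069 inside a 0.05 Da
    tolerance) never displaces an exact-mass reading.  An empty list is a
    valid result.
    """
    if s.precursor_mz is None or s.n_peaks < 1:
        return []
    sulfated_chem = s.charge >= 2
    steps = _step_table(mode, sulfated_chem or True)
    # deconvolute every peak at every plausible charge
    nodes = []  # (equivalent mass, intensity, peak index)
    for i in range(s.n_peaks):
        for z in range(1, s.charge + 1):
            nodes.append(
                (_equivalent_mass(float(s.mz[i]), z, sulfated_chem, mode), float(s.intensity[i]), i)
            )
    start = _equivalent_mass(s.precursor_mz, s.charge, sulfated_chem, mode)
    masses = np.array([n[0] for n in nodes])

    results: list[GlycanCandidate] = []

    def extend(mass, path_steps, path_sulf, path_peaks, path_intensity, path_dev):
        extended = False
        for codes, delta, sulf in steps:
            target = mass - delta
            hits = np.nonzero(np.abs(masses - target) <= tol)[0]
            # at most one continuation per (step, peak): group identical peaks
            seen_peaks = set()
            for h in hits:
                eq, inten, idx = nodes[h]
                if idx in path_peaks or idx in seen_peaks:
                    continue
                seen_peaks.add(idx)
                extended = True
                extend(
                    eq,
                    path_steps + [codes],
                    path_sulf + [sulf],
                    path_peaks + [idx],
                    path_intensity + inten,
                    path_dev + abs((mass - eq) - delta),
                )
                if len(results) >= 20 * max_candidates:
                    return
        if not extended and path_steps:
            results.append(
                GlycanCandidate(
                    steps=tuple(path_steps),
                    sulfated_steps=tuple(path_sulf),
                    peak_indices=tuple(path_peaks),
                    matched_intensity=path_intensity,
                    mass_deviation=path_dev,
                )
            )

    extend(start, [], [], [], 0.0, 0.0)
    if not results:
        return []
    # deduplicate identical readings
    uniq = {(c.steps, c.sulfated_steps, c.peak_indices): c for c in results}
    results = list(uniq.values())

    def sort_key(c: GlycanCandidate):
        lex = tuple(_RESIDUE_ORDER.index(codes[0]) for codes in c.steps)
        return (-c.n_steps, round(c.mass_deviation, 6), -c.matched_intensity, lex)

    results.sort(key=sort_key)
    longest = results[0].n_steps
    results = [
        GlycanCandidate(
            c.steps, c.sulfated_steps, c.peak_indices, c.matched_intensity,
            mass_deviation=c.mass_deviation, score=c.n_steps / longest,
        )
        for c in results[:max_candidates]
    ]
    return results


def branch_hypotheses(candidates: list[GlycanCandidate]) -> list[tuple[int, int, int]]:
    """Pairs of ladder readings that diverge and later reconverge on a shared
    peak — the signature of a branched glycan, whose arms can be removed in
    either order.  A linear chain admits only one removal order, so its
    maximal ladders never reconverge after diverging.  Returns
    ``(candidate_i, candidate_j, divergence_step)`` tuples."""
    out = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            k = 0
            while (
                k < min(a.n_steps, b.n_steps)
                and a.peak_indices[k] == b.peak_indices[k]
            ):
                k += 1
            rest_a = set(a.peak_indices[k:])
            rest_b = set(b.peak_indices[k:])
            diverged = rest_a != rest_b or a.peak_indices[k:] != b.peak_indices[k:]
            if k < min(a.n_steps, b.n_steps) and diverged and (rest_a & rest_b):
                out.append((i, j, k))
    return out


# --- composition inference ---------------------------------------------------

#: residue mass classes; the 146 class is intrinsically ambiguous.
_CLASS_LABEL = {"Xyl": "Xyl", "Qui": "Qui/MeXyl", "MeXyl": "Qui/MeXyl",
                "Glc": "Glc", "MeGlc": "MeGlc"}
_CLASS_CODES = ("Xyl", "Qui", "Glc", "MeGlc")  # one representative per class


def composition_class(codes) -> tuple[str, ...]:
    """Map residue codes to the sorted mass-class multiset used when
    comparing compositions (Qui and MeXyl collapse to one class)."""
    return tuple(sorted(_CLASS_LABEL[c] for c in codes))


def _candidate_steps_to_classes(candidate: GlycanCandidate) -> list[str]:
    return [_CLASS_LABEL[codes[0]] for codes in candidate.steps]


def _is_submultiset(a: list[str], b: list[str]) -> bool:
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    return all(cb[k] >= v for k, v in ca.items())


def _subset_sums(target: float, tol: float, res: dict[str, float], max_size: int = 6):
    """Residue multisets (as sorted class-label tuples) whose residue masses
    sum to ``target`` within ``tol``."""
    from itertools import combinations_with_replacement

    out = set()
    for size in range(1, max_size + 1):
        for combo in combinations_with_replacement(_CLASS_CODES, size):
            if abs(sum(res[c] for c in combo) - target) <= tol:
                out.add(composition_class(combo))
    return sorted(out)


def infer_composition(
    s: Spectrum,
    tol: float = 0.05,
    mode: str = "mono",
    aglycon_range: tuple[float, float] = (350.0, 700.0),
) -> tuple[tuple[str, ...], list[str]]:
    """Estimate the glycan residue multiset of a query spectrum.

    For non-sulfated compounds the Y-type ladder alone reads the composition
    (it runs down to the bare-aglycon Y0).  For sulfated compounds the Y
    ladder stalls once every remaining unit is needed to hold the charge's
    sulfates, so the sulfate-carrying core is read from the B side instead:
    every parent-free fragment (no peak one residue step above it) is tested
    as the B ion of the complete glycan, whose mass fixes the total residue
    sum (m = sum residues + n_SO3 * SO3 - H) and, via the precursor, the
    implied aglycon mass — required to fall in the plausible range for
    (nor)lanostane aglycons.  The residue sum is decomposed by exhaustive
    subset-sum over the four residue mass classes; competing readings are
    ranked by agreement with the Y ladder, by the presence of sub-B ions one
    residue below the anchor, by consistency with the sulfo-monosaccharide
    diagnostics, and deterministically thereafter.

    Returns ``(composition, log)``: the sorted mass-class multiset
    (``"Qui/MeXyl"`` for the isobaric class) and a log of ambiguous choices
    (isobaric subset-sum collisions and route disagreements).
    """
    from collections import Counter

    log: list[str] = []
    candidates = sequence_glycan(s, tol=tol, mode=mode)
    y_classes = _candidate_steps_to_classes(candidates[0]) if candidates else []
    n_s = infer_sulfation(s, tol=tol, mode=mode).count

    if n_s == 0:
        if not candidates:
            return (), log
        best_len = candidates[0].n_steps
        readings = sorted(
            {tuple(sorted(_candidate_steps_to_classes(c)))
             for c in candidates if c.n_steps == best_len}
        )
        if len(readings) > 1:
            # includes the unresolvable case: Qui + Glc and MeGlc + Xyl are
            # the same elemental formula (C12H20O9), so ladder crossings
            # through that identity tie at any mass accuracy
            log.append(
                "competing ladder readings of equal length: "
                + " / ".join("+".join(r) for r in readings[:4])
            )
        return tuple(sorted(y_classes)), log

    SO3 = piece("SO3", mode)
    H = piece("H", mode)
    NA = piece("Na", mode)
    res = {c: residue_mass(c, mode) for c in _CLASS_CODES}
    if s.precursor_mz is None:
        raise ValueError("spectrum has no precursor m/z")
    m_salt = s.charge * s.precursor_mz + s.charge * NA

    # anchors are sought among singly-charged interpretations only: the B ion
    # of the full glycan is observed singly charged as well, while deconvoluting
    # a genuinely singly-charged B ion at charge 2 would fabricate a mass
    # sitting exactly one residue step above it (2m + H - m = sum residues +
    # SO3), i.e. a systematic false anchor.
    eqs = sorted((float(m) for m in s.mz), reverse=True)
    eq_arr = np.array(eqs)
    step_masses = [res[c] for c in _CLASS_CODES] + [res[c] + SO3 for c in _CLASS_CODES]

    def parent_free(m: float) -> bool:
        return not any(np.any(np.abs(eq_arr - (m + d)) <= tol) for d in step_masses)

    # sulfated units named directly by diagnostics
    diag_units: list[str] = []
    col = 0 if mode == "mono" else 1
    for name, masses in _SULFATE_DIAGNOSTICS.items():
        if name == "HSO4-":
            continue
        if np.any(np.abs(s.mz - masses[col]) <= tol):
            diag_units.append(_CLASS_LABEL[name.split("SO3")[0]])
    fallback = tuple(sorted(y_classes + diag_units[: max(n_s, 1)])[:6])

    y_counter = Counter(y_classes)
    scored: list[tuple[tuple, tuple[str, ...]]] = []
    for e in eqs:
        aglycon_implied = m_salt - e - H + n_s * (H - NA)
        if not aglycon_range[0] <= aglycon_implied <= aglycon_range[1]:
            continue
        if not parent_free(e):
            continue
        target = e + H - n_s * SO3
        sols = _subset_sums(target, tol, res)
        if len(sols) > 1:
            log.append(
                f"isobaric collision: residue sum {target:.4f} matches "
                + " / ".join("+".join(c) for c in sols)
            )
        children = sum(
            1
            for c in _CLASS_CODES
            if np.any(np.abs(eq_arr - (e - res[c])) <= tol)
            or np.any(np.abs(eq_arr - (e - res[c] - SO3)) <= tol)
        )
        for comp in sols:
            cc = Counter(comp)
            y_overlap = sum(min(cc[k], y_counter[k]) for k in y_counter)
            diag_ok = all(cc[d] >= 1 for d in set(diag_units))
            scored.append(
                ((y_overlap, children, comp == fallback, diag_ok, comp), comp)
            )
    if scored:
        scored.sort(key=lambda t: (-t[0][0], -t[0][1], -t[0][2], -t[0][3], t[0][4]))
        best = scored[0][1]
        rivals = sorted({c for _, c in scored if c != best})
        if rivals:
            log.append(
                "competing composition readings: "
                + " / ".join("+".join(c) for c in rivals[:4])
            )
        if not _is_submultiset(y_classes, list(best)):
            log.append(
                f"B-anchored composition {best} does not contain the full "
                f"Y-ladder reading {tuple(sorted(y_classes))}"
            )
        return best, log
    log.append("no B-side anchor found; composition from Y ladder + diagnostics")
    return fallback, log


# --- aglycon features --------------------------------------------------------


@dataclass(frozen=True)
class AglyconFlags:
    lactone_CO2_loss: bool
    acetoxy_60: bool
    acetoxy_lactone_104: bool
    water_losses: bool
    evidence: tuple[Evidence, ...]


_AGLYCON_LOSSES = (
    ("acetoxy_lactone_104", "AcOH_CO2"),
    ("acetoxy_60", "AcOH"),
    ("lactone_CO2_loss", "CO2"),
    ("water_losses", "H2O"),
)


def detect_aglycon_features(s: Spectrum, tol: float = 0.05, mode: str = "mono") -> AglyconFlags:
    """Flag aglycon-related neutral losses from any fragment-pair or
    precursor-fragment mass difference: 60 (acetic acid, acetoxy group),
    104 (AcOH + CO2: acetoxy AND 18(20)-lactone), 44 (CO2, lactone) and
    18 (water)."""
    if s.precursor_mz is None:
        raise ValueError("spectrum has no precursor m/z")
    sulfated_chem = s.charge >= 2
    eq = [
        _equivalent_mass(float(m), z, sulfated_chem, mode)
        for m in s.mz
        for z in range(1, s.charge + 1)
    ]
    idx = [i for i in range(s.n_peaks) for _ in range(1, s.charge + 1)]
    eq.append(_equivalent_mass(s.precursor_mz, s.charge, sulfated_chem, mode))
    idx.append(-1)
    eq_arr = np.array(eq)

    flags = {name: False for name, _ in _AGLYCON_LOSSES}
    evidence = []
    for name, loss_key in _AGLYCON_LOSSES:
        loss = piece(loss_key, mode)
        diff = eq_arr[:, None] - eq_arr[None, :]
        hit_i, hit_j = np.nonzero(np.abs(diff - loss) <= tol)
        for i, j in zip(hit_i, hit_j):
            flags[name] = True
            evidence.append(
                Evidence(
                    int(idx[j]),
                    float(eq_arr[j]),
                    f"neutral loss {loss_key} ({loss:.4f}) from "
                    + ("precursor" if idx[i] == -1 else f"peak {idx[i]}"),
                )
            )
            break  # one evidence line per rule suffices
    if flags["acetoxy_lactone_104"]:
        # the 104 loss implies an acetoxy group AND an 18(20)-lactone
        flags["acetoxy_60"] = flags["acetoxy_60"] or True
        flags["lactone_CO2_loss"] = flags["lactone_CO2_loss"] or True
    return AglyconFlags(
        lactone_CO2_loss=flags["lactone_CO2_loss"],
        acetoxy_60=flags["acetoxy_60"],
        acetoxy_lactone_104=flags["acetoxy_lactone_104"],
        water_losses=flags["water_losses"],
        evidence=tuple(evidence),
    )


# --- side-chain classification -----------------------------------------------


@dataclass(frozen=True)
class SideChainMatch:
    class_key: str
    hits: int
    n_signature: int
    rank: int  # 1-based; ties share a rank
    matched_losses: tuple[int, ...]


def classify_side_chain(
    s: Spectrum,
    reference_mz: float | None = None,
    tol: float = 0.05,
) -> list[SideChainMatch]:
    """Rank the side-chain classes by how many of their signature
    neutral losses appear as losses from the reference ion (default: the
    precursor).  Ties share a rank and are reported as ties."""
    ref = reference_mz if reference_mz is not None else s.precursor_mz
    if ref is None:
        raise ValueError("no reference ion: provide reference_mz or a precursor")
    observed = ref - s.mz  # neutral losses from the reference
    scored = []
    for key, cls in SIDE_CHAIN_CLASSES.items():
        matched = tuple(
            loss
            for loss in cls.losses.values()
            if np.any(np.abs(observed - loss) <= tol)
        )
        scored.append((key, len(matched), len(cls.losses), matched))
    scored.sort(key=lambda t: (-t[1], -(t[1] / t[2]), t[0]))
    out = []
    rank = 0
    prev = None
    for pos, (key, hits, n_sig, matched) in enumerate(scored, start=1):
        score_key = (hits, round(hits / n_sig, 9))
        if score_key != prev:
            rank = pos
            prev = score_key
        out.append(SideChainMatch(key, hits, n_sig, rank, matched))
    return out


# --- analog reasoning --------------------------------------------------------


@dataclass(frozen=True)
class AnalogHypothesis:
    record_id: str
    difference_da: float  # signed, query minus library
    nominal_difference: int
    interpretation: str


#: characteristic precursor mass differences between structural analogs.
_ANALOG_TABLE = (
    (176, residue_mass("MeGlc"), "MeGlc unit"),
    (162, residue_mass("Glc"), "Glc unit"),
    (146, residue_mass("Qui"), "Qui (or MeXyl) unit"),
    (132, residue_mass("Xyl"), "Xyl unit"),
    (58, MASS["C2H2O2"], "acetate group"),
    (30, 30.010565, "CH2O: Glc vs Xyl substitution"),
    (18, MASS["H2O"], "H2O"),
    (16, 15.9949146221, "O"),
    (14, 14.0156500638, "CH2"),
    (12, 12.0, "C"),
    (2, 2.0156500638, "double bond (2H)"),
)


def annotate_analogs(
    query_precursor: float,
    library,
    tol: float = 0.02,
    mode: str = "mono",
) -> list[AnalogHypothesis]:
    """Propose structural-analog relationships by precursor mass difference.

    A library record whose precursor differs from the query by one of the
    characteristic differences (176/162/146/132 monosaccharides, 58 acetate,
    30 Glc-vs-Xyl, 18/16/14/12/2 small modifications; both signs) yields a
    hypothesis.  An exact precursor match is not an analog (it belongs to the
    exact-match channel) and yields nothing here.
    """
    if not library:
        raise ValueError("analog annotation needs a non-empty library")
    out = []
    for rec in library:
        spec = rec.spectrum if isinstance(rec, LibraryRecord) else rec
        if spec.precursor_mz is None:
            continue
        d = query_precursor - spec.precursor_mz
        if abs(d) <= tol:
            continue
        for nominal, mono, meaning in _ANALOG_TABLE:
            delta = mono if mode == "mono" else float(nominal)
            if abs(abs(d) - delta) <= tol:
                sign = "+" if d > 0 else "-"
                out.append(
                    AnalogHypothesis(
                        record_id=spec.id,
                        difference_da=round(d, 4),
                        nominal_difference=nominal if d > 0 else -nominal,
                        interpretation=f"{sign}{nominal} Da: {meaning} vs {spec.id}",
                    )
                )
                break
    return out


# --- combined report ---------------------------------------------------------

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class AnnotationReport:
    """The combined structural-inference report for one query spectrum."""

    query_id: str
    sulfation: SulfationEstimate
    glycan_candidates: list[GlycanCandidate]
    branch_pairs: list[tuple[int, int, int]]
    aglycon: AglyconFlags
    side_chain: list[SideChainMatch]
    analogs: list[AnalogHypothesis]
    unexplained_peaks: list[int]
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def annotate(
    s: Spectrum,
    library=None,
    tol: float = 0.05,
    precursor_tol: float = 0.02,
    mode: str = "mono",
) -> AnnotationReport:
    """Run the full rule engine on one spectrum and collect the report.

    Major peaks (>10% of the base peak) not cited by any evidence line or
    ladder step are listed as unexplained.
    """
    sulfation = infer_sulfation(s, tol=tol, mode=mode)
    candidates = sequence_glycan(s, tol=tol, mode=mode)
    branches = branch_hypotheses(candidates[:10])
    aglycon = detect_aglycon_features(s, tol=tol, mode=mode)
    side_chain = classify_side_chain(s, tol=max(tol, 0.5)) if s.precursor_mz else []
    analogs = (
        annotate_analogs(s.precursor_mz, library, tol=precursor_tol, mode=mode)
        if library
        else []
    )
    cited: set[int] = set()
    for ev in sulfation.evidence + aglycon.evidence:
        if ev.peak_index >= 0:
            cited.add(ev.peak_index)
    for c in candidates:
        cited.update(c.peak_indices)
    threshold = 0.1 * s.base_peak_intensity()
    unexplained = [
        int(i)
        for i in range(s.n_peaks)
        if s.intensity[i] > threshold and i not in cited
    ]
    return AnnotationReport(
        query_id=s.id,
        sulfation=sulfation,
        glycan_candidates=candidates,
        branch_pairs=branches,
        aglycon=aglycon,
        side_chain=side_chain,
        analogs=analogs,
        unexplained_peaks=unexplained,
    )
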
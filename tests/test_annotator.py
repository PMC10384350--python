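"""Rule-based inference: sulfation, glycan sequencing, aglycon flags,
side-chain classification, analog reasoning and end-to-end recovery."""

import numpy as np
import pytest

from saponinms.annotator import (
    annotate,
    annotate_analogs,
    branch_hypotheses,
    classify_side_chain,
    composition_class,
    detect_aglycon_features,
    infer_composition,
    infer_sulfation,
    sequence_glycan,
)
from saponinms.chem_model import AglyconSpec, GlycanTree, GlycanUnit, Glycoside
from saponinms.fragmenter import SIDE_CHAIN_CLASSES
from saponinms.speclib import Spectrum
from saponinms.synthetic import SimulationConfig, generate_structure, simulate_spectrum


def spectrum_from(mzs, intensities=None, precursor=None, charge=1, sid="q"):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.full(mzs.size, 100.0)
    return Spectrum(
        mz=mzs, intensity=intensities, precursor_mz=precursor, charge=charge, id=sid
    )


class TestInferSulfation:
    def test_multiply_charged_adduct_rule(self, psolusoside_a):
        spec = simulate_spectrum(psolusoside_a, rng=np.random.default_rng(0))
        est = infer_sulfation(spec)
        assert est.count == 2 and not est.lower_bound
        assert any("HSO4" in e.rule for e in est.evidence)

    def test_no_evidence_gives_zero(self):
        spec = spectrum_from([500.0, 700.0], precursor=900.0)
        est = infer_sulfation(spec)
        assert est.count == 0 and est.evidence == ()

    def test_trisulfated_round_trip(self, rng):
        while True:
            g = generate_structure(rng)
            if g.n_sulfates == 3:
                break
        spec = simulate_spectrum(g, rng=np.random.default_rng(1))
        assert infer_sulfation(spec).count == 3

    def test_singly_charged_diagnostic_lower_bound(self, psolusoside_e):
        spec = simulate_spectrum(psolusoside_e, rng=np.random.default_rng(2))
        est = infer_sulfation(spec)
        assert est.count == 1 and est.lower_bound

    def test_missing_precursor_rejected(self):
        with pytest.raises(ValueError):
            infer_sulfation(spectrum_from([100.0]))


class TestSequenceGlycan:
    def test_two_peak_single_step(self):
        spec = spectrum_from([824.0, 1000.0], precursor=1000.0)
        cands = sequence_glycan(spec, tol=0.5, mode="nominal")
        assert len(cands) == 1
        assert cands[0].steps == (("MeGlc",),)

    def test_isobaric_step_stays_ambiguous(self):
        spec = spectrum_from([854.0, 1000.0], precursor=1000.0)
        cands = sequence_glycan(spec, tol=0.5, mode="nominal")
        assert cands[0].steps == (("Qui", "MeXyl"),)

    def test_published_ladder_reading(self):
        """The psolusoside C1 peak list reads as MeGlc loss then Xyl loss."""
        peaks = [1363, 1231, 1213, 1187, 1169, 1099, 1081, 1055, 1037, 1407]
        # Y ions intense, secondary losses weaker (as observed)
        inten = [30, 100, 20, 20, 20, 100, 20, 20, 20, 80]
        spec = spectrum_from(peaks, inten, precursor=1407.0)
        cands = sequence_glycan(spec, tol=0.5, mode="nominal")
        top = cands[0]
        assert top.steps[0] == ("MeGlc",)
        assert top.steps[1] == ("Xyl",)

    def test_empty_result_allowed(self):
        spec = spectrum_from([100.0, 200.0], precursor=900.0)
        assert sequence_glycan(spec) == []

    def test_branch_hypotheses_on_branched_structure(self):
        g = Glycoside(
            "b",
            AglyconSpec(neutral_mass=500.0),
            GlycanTree(
                [GlycanUnit("Xyl"), GlycanUnit("Qui"), GlycanUnit("Glc")],
                branches=[(2, [GlycanUnit("MeGlc")])],
            ),
        )
        spec = simulate_spectrum(g, rng=np.random.default_rng(3))
        cands = sequence_glycan(spec)
        assert branch_hypotheses(cands[:10])


class TestAglyconFeatures:
    def test_lactone_co2_from_published_list(self):
        peaks = [1363.0, 1231.0, 1099.0, 1407.0]
        spec = spectrum_from(peaks, precursor=1407.0)
        flags = detect_aglycon_features(spec, tol=0.5, mode="nominal")
        assert flags.lactone_CO2_loss
        assert not flags.acetoxy_60

    def test_residue_only_spectrum_all_false(self):
        spec = spectrum_from([1000.0, 824.0, 692.0], precursor=1000.0)
        flags = detect_aglycon_features(spec, tol=0.05)
        assert not any(
            [flags.lactone_CO2_loss, flags.acetoxy_60, flags.acetoxy_lactone_104,
             flags.water_losses]
        )

    def test_acetoxy_lactone_round_trip(self):
        g = Glycoside(
            "a",
            AglyconSpec(neutral_mass=520.0, lactone="18(20)", n_acetoxy=1),
            GlycanTree([GlycanUnit("Xyl"), GlycanUnit("Qui")]),
        )
        spec = simulate_spectrum(g, rng=np.random.default_rng(4))
        flags = detect_aglycon_features(spec)
        assert flags.acetoxy_60 and flags.acetoxy_lactone_104
        assert flags.lactone_CO2_loss
        assert flags.evidence  # every flag cites a peak and a rule


class TestClassifySideChain:
    def test_colochiroside_a1_losses(self):
        prec = 1193.0
        losses = [372, 360, 228, 202, 188, 128, 70]
        spec = spectrum_from([prec - l for l in losses], precursor=prec)
        ranked = classify_side_chain(spec, tol=0.5)
        assert ranked[0].class_key == "OAc,H,H,-|d25"
        assert ranked[0].hits == 7

    def test_delta24_loss_series(self):
        """The 128/202/228/360/372 neutral-loss series marks a Delta-24
        holostane side chain."""
        prec = 1309.0
        spec = spectrum_from([prec - l for l in [128, 202, 228, 360, 372]],
                             precursor=prec)
        ranked = classify_side_chain(spec, tol=0.5)
        assert ranked[0].class_key == "OAc,H,H,H|d24"

    def test_empty_spectrum_scores_zero(self):
        spec = spectrum_from([1000.0], precursor=1000.0)
        ranked = classify_side_chain(spec, tol=0.5)
        assert all(m.hits == 0 for m in ranked)
        assert all(m.rank == 1 for m in ranked)  # a full tie is a tie

    @pytest.mark.parametrize("key", sorted(SIDE_CHAIN_CLASSES))
    def test_self_consistency_all_classes(self, key):
        """Simulated spectra of each class rank that class in the top tie
        group (the two 22E/22Z diene rows are identical and always tie)."""
        g = Glycoside(
            "sc",
            AglyconSpec(neutral_mass=500.0, lactone="18(20)", n_acetoxy=1,
                        side_chain_class=key),
            GlycanTree([GlycanUnit("Xyl", sulfated=True), GlycanUnit("Qui"),
                        GlycanUnit("Glc"), GlycanUnit("MeGlc")]),
        )
        spec = simulate_spectrum(g, rng=np.random.default_rng(5))
        ranked = classify_side_chain(spec, tol=0.5)
        top = [m.class_key for m in ranked if m.rank == 1]
        assert key in top


class TestAnalogs:
    def lib(self, *pairs):
        return [spectrum_from([100.0], precursor=p, sid=n) for n, p in pairs]

    def test_oxygen_addition(self):
        hyps = annotate_analogs(1325.0, self.lib(("H6-like", 1309.0)), tol=0.02,
                                mode="nominal")
        assert len(hyps) == 1
        assert hyps[0].nominal_difference == 16
        assert "O" in hyps[0].interpretation

    def test_exact_match_is_not_analog(self):
        assert annotate_analogs(1309.0, self.lib(("same", 1309.0))) == []

    def test_difference_table_both_signs(self):
        """Brute-force check of the signed difference table."""
        table = [176, 162, 146, 132, 58, 30, 18, 16, 14, 12, 2]
        base = 1307.0
        lib = self.lib(*[(f"p{d}", base - d) for d in table],
                       *[(f"m{d}", base + d) for d in table])
        hyps = annotate_analogs(base, lib, tol=0.02, mode="nominal")
        got = {(h.record_id, h.nominal_difference) for h in hyps}
        expected = {(f"p{d}", d) for d in table} | {(f"m{d}", -d) for d in table}
        assert got == expected

    def test_extra_meglc(self):
        hyps = annotate_analogs(1483.0, self.lib(("rec", 1307.0)), mode="nominal")
        assert hyps[0].nominal_difference == 176
        assert "MeGlc" in hyps[0].interpretation

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_analogs(1000.0, [])


class TestRecovery:
    def test_noiseless_recovery(self):
        """Composition multiset recovered for >=95% of 100 noiseless
        grammar-valid structures; sulfate count exact whenever z >= 2;
        failures are logged."""
        rng = np.random.default_rng(42)
        structures = [generate_structure(rng, name=f"g{i}") for i in range(100)]
        ok = 0
        for i, g in enumerate(structures):
            spec = simulate_spectrum(g, rng=np.random.default_rng(10_000 + i))
            if spec.charge >= 2:
                assert infer_sulfation(spec).count == g.n_sulfates
            comp, log = infer_composition(spec)
            true = composition_class(u.code for u in g.glycan.units)
            if comp == true:
                ok += 1
            else:
                assert log, "failed recovery must leave a log entry"
        assert ok >= 95

    def test_noise_degrades_gracefully(self):
        """Recovery is monotone non-increasing across sigma in
        {0, 0.005, 0.01, 0.02} with 20% spurious peaks (common random
        numbers: identical unit-normal offsets scaled by sigma)."""
        rng = np.random.default_rng(42)
        structures = [generate_structure(rng, name=f"g{i}") for i in range(40)]
        rates = []
        for sigma in (0.0, 0.005, 0.01, 0.02):
            cfg = SimulationConfig(noise_sigma_mz=sigma, spurious_peak_fraction=0.2)
            ok = 0
            for i, g in enumerate(structures):
                spec = simulate_spectrum(g, config=cfg,
                                         rng=np.random.default_rng(20_000 + i))
                comp, _ = infer_composition(spec)
                if comp == composition_class(u.code for u in g.glycan.units):
                    ok += 1
            rates.append(ok)
        assert all(a >= b for a, b in zip(rates, rates[1:])), rates


class TestAnnotateReport:
    def test_report_schema(self, psolusoside_a):
        spec = simulate_spectrum(psolusoside_a, rng=np.random.default_rng(6))
        rep = annotate(spec)
        assert rep.schema_version == "1.0"
        assert rep.sulfation.count == 2
        assert rep.glycan_candidates
        assert 0 <= rep.glycan_candidates[0].score <= 1
        d = rep.to_dict()
        assert set(d) >= {"sulfation", "glycan_candidates", "aglycon",
                          "side_chain", "unexplained_peaks"}

    def test_unexplained_peaks_listed(self):
        spec = spectrum_from([400.0, 824.0, 1000.0], [900, 100, 100],
                             precursor=1000.0)
        rep = annotate(spec)
        assert 0 in rep.unexplained_peaks  # the intense 400 Da peak
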
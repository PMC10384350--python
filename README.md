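# saponinms

MS/MS annotation toolkit for sea-cucumber triterpene glycosides (saponins):
in-silico glycosidic fragmentation of (poly)sulfated glycosides under
negative-mode CID, rule-based structural inference from product-ion spectra,
spectral-library search with retention-time confirmation, and molecular
networking. A synthetic structure/spectrum generator makes every part
testable without instrument data.

## Who it is for

Marine natural-product and metabolomics groups profiling holothurian extracts
by LC-ESI-MS/MS. Sea-cucumber triterpene glycosides are lanostane-type
aglycons glycosylated at C-3 with 1–6 monosaccharides (Xyl, Qui, Glc, MeGlc,
MeXyl; xylose is always the first unit, methylated units are always terminal)
and up to four sulfate half-esters. Their negative-mode CID spectra are
dominated by glycosidic-bond cleavages, which this package generates,
searches and reasons over.

## The model

**Adducts.** Non-sulfated compounds ionize as [M−H]⁻; sulfated compounds are
sodium salts M that lose n Na⁺, giving [M−nNa]ⁿ⁻ with the observed charge n
equal to the sulfate count for n ≥ 2.

**Glycosidic ladder** (Domon–Costello nomenclature). Y ions retain the
aglycon; every descendant-closed set of glycan units is removable, so branch
combinatorics (Y₂α/Y₁β-type combined cleavages) are enumerated exhaustively.
B/C ions retain the non-reducing end, with the charge held by a sulfate:

    B:  m/z = (Σ residues + n_SO3·79.9568 − z·1.00783) / z      C = B + H₂O
    Y:  m/z = (M_salt − Σ residues_cleaved − s·SO₃ − (z+s)·Na + s·H) / z

where s counts cleaved sulfated units (they depart with their counter-ion).
Residue masses are Xyl 132, Qui/MeXyl 146, Glc 162, MeGlc 176 (nominal);
Qui and MeXyl are isobaric and are never resolved by mass — annotations keep
the ambiguity explicit. Secondary losses encode the aglycon chemistry:
−CO₂ (lactone ring), −60 (acetoxy → acetic acid), −104 (acetoxy **and**
18(20)-lactone, C₂H₄O₂+CO₂), −H₂O. Sulfate chemistry adds HSO₄⁻
charge-reduction (m/z′ = (z·m/z − 96.9601)/(z−1)), neutral SO₃ loss, the
HSO₄⁻ diagnostic at 96.96 and sulfo-monosaccharide anions (XylSO₃ 211,
GlcSO₃ 241, MeGlcSO₃ 255). Thirteen side-chain structural classes carry
published neutral-loss signatures (b/f/h fragment families) used for
classification.

**Dereplication.** Square-root-intensity cosine with greedy one-to-one peak
pairing, precursor pre-filter, and a retention-time gate (default 0.3 min) to
separate isomers with near-identical spectra. Modified cosine (peaks may
match offset by the precursor mass difference) feeds molecular networking
with the standard filters: score > 0.7, > 6 matched peaks, mutual top-10
rank, molecular-family cap of 100 nodes.

## Worked example

```python
from saponinms import reference
from saponinms.fragmenter import FragmentationConfig, theoretical_spectrum

e = reference.psolusoside_e()          # monosulfated tetraoside, [M-Na]- 1163
for f in theoretical_spectrum(e, FragmentationConfig(mode="nominal", cross_ring=True)):
    if f.ion_type in ("precursor", "Y", "B", "A02", "diagnostic_HSO4",
                      "diagnostic_sulfomonosaccharide"):
        print(f"  {f.mz:7.1f}  {f.ion_type:<12} {f.label}")
```

prints (abridged to the assigned series):

```
     97.0  diagnostic_HSO4 [HSO4]-
    241.0  diagnostic_sulfomonosaccharide [GlcSO3-Na]-
    417.0  B            [MeGlc+GlcSO3-Na]-
    475.0  A02          [MeGlc+GlcSO3+C2H2O2-Na]-
    563.0  B            [MeGlc+GlcSO3+Qui-Na]-
    695.0  B            [MeGlc+GlcSO3+Qui+Xyl-Na]-
    987.0  Y            [M-Na-MeGlc]-
   1163.0  precursor    [M-Na]-
```

reproducing the published psolusoside E assignments: the B-series walks the
chain inwards from the terminal MeGlc in residue-mass steps (695 → 563 is
−132, a xylose; 563 → 417 is −146, the quinovose), 475 is the 0,2-type
cross-ring variant (+C₂H₂O₂ = 58), 241 names the sulfated glucose, and 96.96
flags sulfation itself. The same engine run on a query spectrum in reverse
(`saponinms.annotator`) reads sulfate count, glycan sequence/composition,
aglycon flags and side-chain class back off the peaks.

Command-line equivalents: `saponinms fragment | annotate | search | network |
simulate` (see `--help` on each).

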
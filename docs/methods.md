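# Methods

This note records the models, conventions and design choices behind
`saponinms`, in the order data flows through the package.

## Mass bookkeeping (`chem_model`)

Two mass modes run through everything. **Monoisotopic** mode is the working
mode for measured data; **nominal** mode uses the integer residue and
neutral-loss masses conventionally quoted for this compound class (Xyl 132,
Qui/MeXyl 146, Glc 162, MeGlc 176; SO₃ 80, HSO₄ 97, CO₂ 44, H₂O 18, AcOH 60,
AcOH+CO₂ 104, C₂H₂O₂ 58, C₅H₁₀ 70) and reproduces published integer fragment
ladders bit-exactly. Charge carriers are the proton (1.007276 Da) and Na⁺
(22.989770 Da); the electron mass is neglected throughout, which is three
orders of magnitude below every matching tolerance used. A sulfate is
modeled as +SO₃ on a hydroxyl with one Na⁺ counter-ion in the neutral salt —
the only convention consistent with [M−nNa]ⁿ⁻ adducts and with the
sulfate-retaining B-ion masses.

One diagnostic deliberately keeps its accurate mass in both modes: the HSO₄⁻
anion at 96.9601 (H₂SO₄ minus a proton), because it is conventionally quoted
as "96.9" even inside otherwise-integer ladders.

Aglycons may be specified by elemental formula or by bare neutral mass.
The reference psolusoside/cucumarioside fixtures use bare nominal masses
back-computed from published precursor m/z values, since molecular formulas
of the individual compounds are not republished here and the ladder
arithmetic needs only the printed masses.

The Qui/MeXyl pair is isobaric (both C₆H₁₀O₄ residues). No operation in this
package ever resolves it by mass: sequencing emits the ambiguity set
{Qui|MeXyl} and compositions use a joint mass class.

## Fragment generation (`fragmenter`)

Y-type ions are enumerated over **all descendant-closed unit sets** of the
glycan tree (≤6 units ⇒ ≤2⁶ sets, so exhaustive enumeration is exact and
cheap); this covers combined cleavages across branches. B/C ions are
generated for every non-reducing-end subtree that can hold the charge: in
sodium-salt chemistry a subtree needs ≥1 sulfate (sulfate-free subtrees are
skipped and logged at debug level), in [M−H]⁻ chemistry any non-root subtree
may deprotonate, but the whole-glycan B ion is not emitted because it is not
observed in that chemistry. Fragment charge z′ is capped by
min(precursor charge, retained sulfates), except in [M−H]⁻ chemistry where
z′ = 1.

The HSO₄⁻ charge-reduction formula is implemented in its general form
m/z′ = (z·m/z − 96.9601)/(z − 1), which reduces to the z = 2 → 1 case of the
published ladders.

Cross-ring chemistry is restricted to a single 0,2-type variant, implemented
as +C₂H₂O₂ (58) on B ions and off by default: that is the only cross-ring
composition recoverable from published assignments, and only the additive
variant is attested. Z ions (Y − H₂O) are config-gated for the same reason —
the series is mentioned but rarely assigned.

Secondary losses apply only to aglycon-retaining ions (precursor, Y, Z):
CO₂ (and CO₂+H₂O) for any lactone, −60 for acetoxy groups, −104 only for the
acetoxy + 18(20)-lactone combination, and optional water losses (on by
default). Side-chain ions are emitted from the precursor using the
13-class signature table; the signatures are defined at integer precision in
both modes because the underlying table is printed at integer precision.

Labels follow the field's bracket notation exactly ("[M−2Na−MeGlcSO3]−",
"[MeGlc+GlcSO3−Na]−"), with ASCII hyphens; fragments are deduplicated by
(label, charge) and sorted by m/z, making output deterministic.

## Structural inference (`annotator`)

Neutral-loss reasoning operates on singly-charged-equivalent masses: an ion
of charge z at m/z x maps to z·x + (z−1)·m_Na in salt chemistry (proton
otherwise), so multiply-charged ladders participate in differencing.

**Sulfation**: for z ≥ 2 the adduct rule fixes the count at z; for z = 1 the
diagnostics (96.96 and the sulfo-monosaccharide anions) give a lower bound
of 1, reported as such. Conflicting evidence is exposed, not adjudicated.

**Sequencing** is a depth-first search from the precursor over peak-to-peak
differences matching the four residue masses (plus their sulfated-salt
variants, residue + SO₃ + Na − H, so that cleavage of a sulfated unit is a
step too). Maximal ladders are ranked by step count, then summed matched
intensity, then a fixed lexicographic residue order (MeGlc < Glc < Qui/MeXyl
< Xyl) for determinism. Branch hypotheses are pairs of ladders that diverge
and later reconverge on a shared peak — possible only when two arms are
removable in either order.

**Composition** combines three channels, mirroring how an analyst reads
these spectra. For non-sulfated compounds the Y ladder runs to the bare
aglycon and is complete on its own. For sulfated compounds the Y ladder
stalls once every remaining unit is needed to retain the charge's sulfates,
so the sulfate-carrying core is read from the B side: every parent-free peak
(no peak one residue step above it) is tested as the whole-glycan B ion,
whose mass fixes the total residue sum (m = Σresidues + n·SO₃ − H) and — via
the precursor — an implied aglycon mass required to fall in 350–700 Da, the
range plausible for (nor)lanostane aglycons. The residue sum is decomposed
by exhaustive subset-sum over the four residue classes; competing readings
are ranked by Y-ladder agreement, sub-B-ion support, consistency with the
sulfo-monosaccharide diagnostics, and deterministically thereafter.
Anchors are only sought among singly-charged interpretations: deconvoluting
a genuinely singly-charged B ion at charge 2 fabricates a mass exactly one
residue step above it (2m + H − m = Σresidues + SO₃), a systematic false
anchor this restriction eliminates. Ambiguities — genuinely isobaric
subset-sums such as Xyl+MeGlc vs Qui+Glc (Δ ≈ 0.0001 Da), or Xyl+CO₂
mimicking a MeGlc step within a 0.05 Da tolerance — are logged; they are the
residual failure modes of recovery.

Default tolerances are 0.02 Da (precursor) and 0.05 Da (fragment), the
values the networking workflow for these data uses; nominal mode uses
±0.5 Da.

**Side-chain classification** counts signature losses from the precursor per
class and ranks by (hits, hit fraction of the row). Several rows are subsets
of others and the Δ²²E,²⁴/Δ²²Z,²⁴ rows are mass-identical, so ties are real
and are reported as shared ranks; the self-consistency guarantee is that the
true class is in the top tie group.

**Analog reasoning** uses the characteristic precursor differences
{176, 162, 146, 132, 58, 30, 18, 16, 14, 12, 2} Da in both signs, with an
exact precursor match routed to the library-search channel instead.

## Library search and networking (`speclib`, `networking`)

The cosine uses square-root intensity weighting — standard practice; the
vendor match-score formula behind published library scores is unpublished,
so those values are not numerically reproduced and only rank behavior is
guaranteed. Peak pairing is greedy (highest √intensity products first, each
peak used once); exhaustive-assignment oracles in the test suite pin the
greedy result to the optimum on small instances. The RT gate default of
0.3 min is the largest retention-time discrepancy observed between standards
and re-detected features in the published identification table; RT failures
are kept but ranked below all passers, which is what disambiguates isomers
with near-identical spectra.

Networking applies, in order: modified cosine on all pairs; edge kept when
score > 0.7 **and** matched peaks ≥ 7 (the strict reading of "more than 6");
mutual top-10 rank filter (ties broken by higher matched count, then node
id — the upstream behavior is unspecified, this choice makes output
order-independent); then the family cap, deleting the globally
lowest-scoring edge of any component above 100 nodes and recomputing
components, ties by lower matched count then lexicographic edge id.

MGF I/O reads through pyteomics and writes through a small normalized writer
(4-decimal peaks, sorted metadata) so that write∘read is byte-stable — an
invariant the tests rely on. Malformed-record errors carry the file path and
record index (the underlying parser does not expose line numbers). The mzML
reader is a minimal lxml-based reader for centroided peak lists, precursor
information, polarity and retention time; vendor conversion is out of scope.

## Synthetic data (`synthetic`)

The generator draws grammar-valid structures: 2–6 units rooted at Xyl,
methylated units terminal, one optional single-unit branch at position 1
or 2, sulfate counts at the frequencies of the 191-compound reference
collection (61/55/43/23/9 for 0–4), lactone frequencies likewise
(150/16/25 for 18(20)/18(16)/none), aglycon mass uniform on [450, 600] Da,
and a uniformly drawn side-chain class. Spectra are the theoretical fragment
set with an ion-type intensity model (Y most intense, then B, then secondary
losses — the qualitative intensity ordering of these spectra), log-normal
intensity jitter (σ = 0.3 log-units), Gaussian m/z noise and a configurable
spurious-peak fraction. Noise offsets are drawn unconditionally and scaled
by σ, so runs differing only in σ share unit-normal offsets (common random
numbers); the graceful-degradation guarantee is tested under that coupling.

What the simulator does **not** emulate: chromatographic peak shape, isotope
envelopes, collision-energy response, intensity physics beyond the
qualitative ordering, and real co-isolation chimeras. Passing tests
therefore demonstrate the correctness of the arithmetic and inference logic
under the stated noise model, not instrument-grade performance.

The RT model is additive with only the **signs** structurally constrained by
the observed reversed-phase trends: intercept 12.5 min; first sulfate −0.5,
each further sulfate −1.0; +1.5 per acetoxy; +1.3 for the 18(20)-lactone
(18(16) neutral); −3.0 for an oxygenated side chain; −0.4 per unit beyond a
bioside; +1.6 for a saturated side chain. Magnitudes were chosen once so
grammar-valid structures predict inside the observed 4.3–18.9 min window
without hitting the clip bounds; no quantitative RT model is published, so
these are free parameters. Tetrasulfated compounds get no RT by default,
mirroring their irreproducible reversed-phase elution (direct infusion in
practice); this is configurable.

## Problem sizes

The default test and acceptance runs use 100 structures for recovery, 40
records for self-search, 40 structures per noise level, 20 spectra for the
network oracle and 150 for the family-cap check — sizes chosen to exercise
every code path at interactive speed while keeping all stochastic assertions
comfortably away from their thresholds.

## Known limitations

- Full cross-ring (A/X) enumeration is not implemented; published
  assignments do not determine those compositions.
- Positive-mode chemistry is out of scope.
- The composition estimator assumes an aglycon in 350–700 Da; exotic
  aglycons outside that window would suppress valid B-side anchors.
- Intensity prediction is a rank model only; never compare simulated
  intensities to measured ones quantitatively.
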
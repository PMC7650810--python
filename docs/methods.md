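# Methods

## Scope and data model

The package operates on three text artifacts: glycan lists (the search
database), peak-list exports from MALDI-TOF instruments, and pathway maps.
A *composition* counts monosaccharides in excess of a named core —
`C`/`N2` for Man₃GlcNAc₂ and `N1` for Man₃GlcNAc₁ — in the five-digit
order Hex, HexNAc, Fuc, NeuAc, NeuGc. Pauci-mannose structures smaller
than the trimannosyl core (Man₁₋₂GlcNAc₂) carry a signed Hex digit
(`-20000` = Man₁GlcNAc₂); this is the one deliberate extension of the
notation, chosen over excluding those real catabolic structures from the
list. O-acetyl groups have no digit and are rendered as a `+nAc` suffix.

## Mass model

Masses are strictly additive over residues. All constants derive at import
time from elemental formulas (residues as dehydro forms: Hex C₆H₁₀O₅,
HexNAc C₈H₁₃NO₅, Fuc C₆H₁₀O₄, NeuAc C₁₁H₁₇NO₈, NeuGc C₁₁H₁₇NO₉) and IUPAC
monoisotopic atomic masses, never from transcribed decimal tables. The
default chemistry (`aoWR-methylester`) adds one CH₂ per sialic acid
(methyl esterification of the carboxylate), the aoWR reducing-end label
(aminooxy-acetyl-Trp-Arg, C₁₉H₂₆N₆O₅, condensed as an oxime, net
+aoWR−H₂O) and a proton adduct, so the reported value is the m/z of the
singly protonated labelled glycan. Whether an instrument's export is
better matched by the neutral labelled mass is a calibration question the
user answers through the config: every increment (label, sialic-acid
derivatization, adduct) is a named entry in a flat key=value file, so
2-AB, RapiFluor-MS or linkage-specific alkylamidation chemistries are a
config file, not a code change. The internal standard A2GN1 (disialylated
biantennary glycan on the single-GlcNAc core, `N1:22020`) is priced by the
same function.

## The bundled taxonomy

The taxonomy is data: one CSV row per structural type with min/max ranges
for antennae, mannose arm, Gal, GalNAc, NeuAc, NeuGc, Fuc and acetyl,
plus a fucosylation-site attribute. Cross-cutting structural rules are
enforced by the enumeration engine:

* capped units (Gal + GalNAc) never exceed the antenna count;
* sialic acids never exceed the capped units;
* fucoses are limited by the available sites — the core GlcNAc (when the
  core retains it), antenna GlcNAcs (Lewis-type) and capped units
  (H-type) — and by a global maximum of 3;
* O-acetyl sits on sialic acids: at most 2 and never more than the number
  of sialic acids (one sialic acid may carry two O-acetyls);
* a `fuc_site = core` type puts fucose on the reducing-end GlcNAc only.

The 43 *N*-glycan types comprise: high-mannose Man₅₋₉ (1), glucosylated
precursors Glc₁₋₃Man₉ (1), pauci-mannose Man₁₋₄ without and with core
fucose (2), six hybrid types (mannose arm 1–3, one antenna with optional
Gal; neutral/NeuAc/NeuGc × without/with core fucose — hybrid fucosylation
is modelled as core fucosylation only), thirty complex types (antennae
1–4 × {neutral, NeuAc 1–4, NeuGc 1–4, mixed NeuAc+NeuGc} × {non-, fucosylated}),
and a three-type LacdiNAc family (GalNAc-capped antennae 1–4, up to 3
LacdiNAc units and 3 Gal: neutral ± fucose; NeuAc₁₋₂-sialylated ± fucose;
fucosylated NeuGc forms). Within a type, range combinations that produce
the same composition (e.g. mannose-arm/Gal splits of a hybrid) collapse
to one record; records are unique on (composition, type), and the same
composition may appear under several types — deliberately, since such
records are isobaric alternatives the annotation step reports together.
With these tables the default enumeration yields 900 *N*-glycan records.

The FNG table holds the same 43 rows on the N2 core plus the N1 rows.
Because ENGase cleaves the chitobiose core and removes the reducing-end
GlcNAc — the residue that carries core fucose — the four types that exist
only through core fucosylation (PM-F, Hy-F, Hy-SF, Hy-GF) are
structurally impossible on N1 and are omitted, leaving 39 N1 types, 82
types and 1770 records in total. The exact per-type ranges (e.g. the
LacdiNAc family's Gal ≤ 3 or the antenna range of its NeuGc row) are
curation choices of the bundled tables, not constraints of the engine;
users who disagree edit the CSV.

Out of scope by design: linkage/anomericity, polylactosamine extension,
sulfation, glucuronic acid, polysialic acid, O-glycans and
glycosphingolipid glycans.

## Annotation and drift calibration

Matching is two-stage. Coarse matching takes every (record, peak) pair
with |m/zᵒᵇˢ − m/zᵗʰᵉᵒ| ≤ tolerance — a closed interval, in Da, read from
the experiment's metadata. Observed deviations drift systematically with
m/z, so a linear model δ = β₀ + β₁·m/z is fitted before acceptance:

1. candidate clusters are the maximal sliding windows of width
   tolerance/2 over the sorted deviations (the internal standard's own
   deviation included), ranked by size with ties toward the smallest
   median |δ|;
2. each cluster is fitted by ordinary least squares and refined by up to
   three trimmed refits: members whose residual exceeds the acceptance
   distance max(3 × median absolute residual, 0.005 Da) are dropped and
   the line refitted;
3. the first cluster whose fitted line passes within the acceptance
   distance of every matched internal standard is adopted — the standard
   is a known true glycan signal, so it anchors the choice when a band of
   contaminants happens to be denser than the glycan cloud. If no cluster
   is validated, the identity model (β = 0) is used and a warning is
   raised; with fewer than two candidates the model is likewise identity.

The 0.005 Da floor keeps the acceptance band from collapsing to zero on
noise-free (or very clean) data; 3×MAD tracks the actual residual scatter
otherwise. A candidate is accepted when |δ − (β₀ + β₁·m/z)| is within the
acceptance distance; per record, the peak with the smallest corrected
residual wins, ties broken toward larger area, then lower m/z, so
quantities are single-valued. Every list record appears exactly once in
the result, undetected records with quantity 0. Calibration can be
disabled (`--no-calibration`), in which case the identity model with the
full tolerance as acceptance distance reproduces plain tolerance matching.

## Quantification and statistics

Quantities are absolute: qᵢ = (areaᵢ / area_IS) · pmol_IS · 100/µg
protein, in pmol per 100 µg protein. A missing or zero-area internal
standard is a hard error. The unique-glycan count collapses accepted,
quantified records to distinct theoretical m/z (4 decimals); the standard
is a spike-in, never an analyte, and appears in neither the expression
table nor the count.

Per series the table reports mean, sample S.D. (n−1) and C.V. = S.D./mean
(blank, not 0, when the mean is 0); per pair of series a two-sided
pooled-variance Student's *t* with df = n₁+n₂−2 (Welch optional).
Identical samples — including the all-zero case of undetected glycans —
give t = 0, p = 1. p-values are raw; no multiple-testing correction is
applied, matching the p < 0.05 pathway-highlight convention, and should
be treated as screening values when hundreds of glycans are tested.
Series with one experiment get blank S.D./C.V. and undefined tests, with
a warning.

## Pathway maps

Maps are CSV grids; a glycan is a vertical 4-cell block (class label,
type label, core-qualified notation, localization) identified by its
notation cell, and arrow tokens (`ra.png`, `la.png`, `ua.png`, `da.png`)
are rendered as inline glyphs so maps written for the original
image-based convention load unchanged. Localization colors: yellow = ER,
pale blue = Golgi, gray = cytoplasm, magenta = lysosome. Binding keys on
(core, notation); when several structural types share a cell's
composition their quantities are summed and the cell is flagged
composite (its p-value is then recomputed on the summed replicate
quantities). Unbound cells render as "not measured"; rendering is total
over any parsable map. Values mode highlights diff > 0 ∧ p < threshold
in red and diff < 0 ∧ p < threshold in blue — strictly less than, so
p exactly at the threshold is never highlighted. The bundled fused map is
illustrative (dolichol precursor → ER glucosylated forms → high-mannose →
Golgi hybrid/complex/pauci-mannose; FNG release → Gn1 processing →
Man₅GlcNAc₁ → lysosome); the format, not the artwork, is the contract.

## Synthetic studies

The simulator emulates the shape of a replicated condition-series study.
Per planted glycan it places a peak at m/zᵗʰᵉᵒ + (0.05 Da + 2·10⁻⁶·m/z)
drift plus Gaussian centroid jitter (σ = 0.2 mDa, truncated at 4 mDa so a
planted peak can never fall outside the acceptance band of a correct
fit); areas are proportional to planted pmol relative to the internal
standard (10 pmol, area scale 2·10⁴, 50 µg protein, tolerance 0.5 Da)
with multiplicative lognormal noise (σ = 0.1 — areas stay positive and
instrument CVs are relative). Contaminants are placed near unplanted list
entries at 0.4–0.95 × tolerance offsets and resampled until they are at
least 0.02 Da off the drift line with respect to *every* list record
within tolerance — without that rule a dense list makes some
"contaminants" legitimately annotatable and the ground truth ill-defined.
Everything is reproducible per seed, and changing the seed changes noise
but never the planted truth; a ground-truth manifest accompanies every
study.

What passing the synthetic tests does and does not show: the generator
reproduces linear drift, relative-intensity noise and off-line
contaminants, but not isotope envelopes, matrix adducts, detector
saturation, baseline effects or m/z-dependent response factors, so the
pipeline's behaviour on real spectra with those features is not certified
by the suite — only the correctness of the matching, calibration,
quantification, statistics and rendering logic is.

## Numerical and interface choices

* Tolerances and deviations are in Da throughout (a ppm switch would be a
  config concern, not a code change).
* m/z values are written and compared at 4 decimals; quantities are
  written at full float precision and round-trip bit-exactly.
* List sorting is (taxonomy order, m/z ascending); two runs with the same
  tables produce byte-identical CSV.
* The workbook path uses `.xlsx` (one tab per measurement, tab name =
  experiment name); delimiter for flat peak lists is sniffed per file
  (tab vs comma).
* HTML outputs are self-contained (CSS bars, inline SVG), with no
  external assets or scripts.

## Known limitations

Structural isomers sharing a composition are reported together, not
resolved; the linear drift model cannot capture strongly non-linear
calibration errors; cluster selection assumes the true glycan cloud plus
standard outnumbers any accidental contaminant band within a
tolerance/2-wide deviation window once the standard anchor is applied;
and absolute quantification inherits the assumption that signal response
per mole is comparable across glycans in the measured mass range.
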
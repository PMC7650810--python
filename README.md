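# glycotag

A toolkit for quantitative MALDI-TOF glycomics of *N*-glycans and free
*N*-glycans (FNGs). It covers the three steps that are usually done by hand
in spreadsheets:

1. **Glycan lists** — rule-driven enumeration of semi-comprehensive
   *N*-glycan and FNG lists with theoretical *m/z* under a configurable
   derivatization chemistry (default: aoWR reducing-end label with
   methyl-esterified sialic acids, reported as the protonated species).
   The bundled taxonomy defines 43 *N*-glycan structural types and 82 FNG
   types and enumerates 900 *N*-glycan and 1770 FNG records; both tables
   are plain CSV and editable.
2. **Annotation, quantification and statistics** — peak-list exports
   (3 header rows; *m/z* in column 1, peak area in column 7; tab or comma
   delimited; multi-tab `.xlsx` workbooks supported) are matched against a
   glycan list within an *m/z* tolerance, corrected for systematic mass
   drift by fitting a line to the dominant deviation cluster (validated by
   the spiked internal standard A2GN1), quantified absolutely in
   pmol / 100 µg protein, and summarized per condition series with mean,
   S.D., C.V. and pooled-variance Student's *t*-tests for every pair of
   series.
3. **Pathway maps** — per-glycan expression changes are bound onto a fused
   *N*-glycan + FNG biosynthetic pathway written as a CSV grid and rendered
   as self-contained HTML, either as per-series bar charts or as
   difference / ratio / *p*-value cells with significant increases and
   decreases (strictly *p* < 0.05) in red and blue.

Who it is for: mass-spectrometry glycomics groups that export peak lists
from MALDI-TOF instruments and want reproducible annotation, absolute
quantification and a pathway-level overview without manual spreadsheet
work.

## The model in brief

For a composition with counts (Hex, HexNAc, Fuc, NeuAc, NeuGc) in excess of
a named core (C/N2 = Man₃GlcNAc₂, N1 = Man₃GlcNAc₁) the theoretical mass is

    m = m_core + h·M_Hex + n·M_HexNAc + f·M_Fuc
        + a·(M_NeuAc + M_deriv) + g·(M_NeuGc + M_deriv)
        + ac·M_acetyl + M_H2O + M_label + M_adduct

with every constant derived from elemental formulas at import time.
Observed deviations δᵢ = m/zᵒᵇˢ − m/zᵗʰᵉᵒ are modelled as a linear drift
δ = β₀ + β₁·m/z fitted on the largest deviation cluster that contains the
internal standard; a candidate match is accepted when its residual from
that line is within the acceptance distance max(3·MAD, 0.005 Da).
Quantities are qᵢ = (areaᵢ / area_IS) · pmol_IS · 100/µg_protein.
Group comparisons use the two-sample pooled-variance Student's *t*
(df = n₁+n₂−2; Welch's form optional); *p*-values are reported raw, with no
multiple-testing correction.

## Worked example

```
$ tag list --kind N --out n_glycans.csv
tag list: wrote 900 records to n_glycans.csv

$ head -4 n_glycans.csv
N
A2GN1,2448.9281
C:20000,1635.6266,HM
C:30000,1797.6794,HM
```

Row 1 flags an *N*-glycan list; row 2 holds the internal standard and its
*m/z*; each record row is composition (core : five-digit notation),
theoretical *m/z*, structural type. `C:20000` is Man₅GlcNAc₂ (two Hex in
excess of the core), a high-mannose (HM) glycan at *m/z* 1635.6266 as the
protonated aoWR-labelled species.

Simulate a two-series study (3 replicates each, 20 planted glycans, 2-fold
increase in the second series) and analyse it:

```
$ tag simulate --list n_glycans.csv --seed 7 --series "wt(-),NPC(-)" \
      --glycans 20 --fold-change 2 --out study
tag simulate: wrote 7 files to study

$ tag expression --list n_glycans.csv --inputs study --out results
tag expression: processed 6 experiments into results

$ tag pathway --exp-list results/exp_list.csv --pair "wt(-),NPC(-)" \
      --mode values --out pathway.html
tag pathway: wrote pathway.html
```

`results/` contains one `out_list_*.csv` (per-glycan annotation:
composition, notation, type, theoretical *m/z*, deviation, area,
pmol/100 µg — zeros for undetected glycans) and one calibration plot per
experiment, plus the study-level `exp_list.csv`, a Cluster-3.0-compatible
`cluster_input.txt` and `each_glycan_quant.html`. A few rows of
`exp_list.csv` from this run:

```
composition    type   m/z         mean[wt(-)]  mean[NPC(-)]  p[wt(-)|NPC(-)]
C:-20000       PM      987.4153   1.146        2.237         0.03
C:31010+1Ac    Hy-S   2347.8804   1.619        2.876         0.00022
C:21101+1Ac    Hy-GF  2347.8804   1.619        2.876         0.00022
```

The first row is Man₁GlcNAc₂ (a pauci-mannose glycan two mannoses short of
the trimannosyl core, hence the signed Hex digit) roughly doubling between
series. The next two rows are *isobaric*: an acetylated sialylated hybrid
and an acetylated NeuGc-fucosylated hybrid share one *m/z* (Fuc + NeuGc and
Hex + NeuAc have identical elemental composition), so the signal is
annotated under both structures — distinguishing them needs MS/MS. In
`pathway.html` the planted cells appear in red with their fold change and
*p*-value; unmeasured map cells read "not measured".

## Layout

- `src/glycotag/` — `chem`/`masses` (elemental constants, mass config),
  `composition` (five-digit notation), `taxonomy` (rules tables),
  `listing` (enumeration + list CSV), `peaklist` (instrument exports,
  workbooks), `annotate` (matching, calibration, quantification),
  `expression` (series statistics, result files), `pathway` (map CSV,
  binding, HTML), `simulate` (synthetic studies with ground truth),
  `report` (HTML), `cli`.
- `src/glycotag/data/` — bundled taxonomy tables (`rules_n.csv`,
  `rules_f.csv`) and the default fused pathway map.
- `docs/methods.md` — models, defaults, numerical choices, limitations.
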
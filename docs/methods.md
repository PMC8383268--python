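# Methods

## Scope and shape of the method

`tpscreen` models suspect screening as a deterministic evidence
pipeline over four kinds of records: suspects (expected compounds),
features (picked LC-HRMS peaks), monitoring metadata (what was applied,
registered and detected where), and reference materials (spectral
library, purchased standards). Each stage either annotates a
suspect×feature hit or removes it; nothing is stochastic at screening
time, so identical inputs always give identical reports.

## Mass and isotope arithmetic

Monoisotopic masses come from the NIST isotope tables bundled with
pyteomics. Ion m/z uses singly charged species only:

* neutral molecule + adduct: `m/z = M ± m_p` with the proton mass
  `m_p = 1.00727646` Da ([M+H]+ / [M−H]−);
* ionic (fragment) composition: `m/z = M − z·m_e` with the electron
  mass `m_e = 0.00054858` Da.

The electron-mass correction matters at the 5th decimal and is required
to reproduce published diagnostic fragment values (e.g. C4H7O2+ at
87.04406). Nothing is rounded internally; rounding happens only at
presentation.

Isotope patterns are simulated at unit-mass-offset resolution by
convolving per-element natural-abundance distributions over all atoms
(square-and-multiply over `numpy.convolve`). That is deliberately
coarse: it supports A+2/A chlorine scoring (≈0.320 per Cl, ≈0.64 for
two) but not fine isotope structure, which the screening logic never
needs. Chlorine counting takes the argmin over k ∈ {0..3} of
|observed − simulated A+2/A| for pure Cl_k patterns; when the two best
candidates differ by less than a tolerance (default 0.08 in relative
abundance) the A+4/A ratio breaks the tie and the estimate is flagged
low-confidence. Contributions of C/N/O to A+2 are below 0.01 for
pesticide-sized molecules and cannot move the argmin between ratios
spaced 0.32 apart.

Subformula enumeration is an exhaustive depth-first search over the
element lattice bounded by the precursor ion composition, pruned by
partial-sum mass bounds, filtered by ring-plus-double-bond equivalents
RDBE ≥ −0.5 (half-integer values are legitimate for even-electron
ions), and sorted by absolute mass error. The test suite checks it
against a naive nested-loop enumeration.

## Suspect list

The list is the union of monitored targets, their key metabolites,
additional parents, and those parents' key metabolites. Metabolite
structures shared between several parents are collapsed by (canonical
Hill formula, whitespace/case-normalized name) with merged parent
links; a flag disables collapsing when raw per-parent counts are
wanted. Every entry carries both-polarity expected m/z computed once
from its formula, so downstream stages never reparse chemistry.

## Gates and their defaults

No instrument prescribes these thresholds; they are conventional
starting points, all exposed in `ScreeningConfig`:

| parameter | default | meaning |
| --- | --- | --- |
| `ms1_tol_ppm` | 5 | suspect-matching window |
| `ms2_tol_ppm` / `ms2_tol_mda` | 10 / 5 | fragment match: ppm with an absolute milli-Da floor for low masses |
| `min_points` | 7 | minimum samples across a peak |
| `asymmetry_range` | 0.5–2.0 | right/left half-height width ratio |
| `min_snr` | 3 | apex above baseline noise (outer 20 % of trace) |
| `rt_window_spreads` | 3 | RT tolerance in residual spreads of the calibrant line |
| `min_calibrants` | 5 | points required for the RT model |
| `ms2_intensity_floor` | 0.05 | fraction of base peak considered in plausibility |
| `rt_tol_min` | 0.2 | RT agreement for standard confirmation (min) |

The RT model is an ordinary least-squares line of retention time on a
hydrophobicity descriptor (the package uses log10 K_foc where
available). A suspect without a descriptor is "unknown", never
"fail" — missing data must not discard candidates.

Fragment evidence tiers: *strong* with ≥2 diagnostic matches, or ≥2
library matches and ≥80 % of observed product ions explainable as
precursor subformulas; *moderate* with exactly one diagnostic/library
match and ≥50 % explainable; *weak* otherwise. An empty spectrum is
weak, not disqualifying. A populated spectrum with zero library matches
and <50 % explainable peaks contradicts the candidate and removes it at
the fragment stage.

## Monitoring integration

Evidence per suspect and site: parent registered there, applied there
(within a 10-year lookback — historical applications legitimately
explain persistent TPs years later), detected there, and a mobility
flag when both K_foc values exist (TP more mobile than parent explains
frequent TP detection despite a rarely detected parent). Retention:
strong/moderate chemistry always survives; weak hits survive iff the
parent was applied or detected at the site. When monitoring contradicts
the source entirely (parent never registered, applied or detected
anywhere), a chemically confident identification is *kept* but carries
a source warning: identity and source attribution are separate claims.

Confidence levels 1–5 (lower = better) follow the community's ordinal
scale. 2a requires the full library spectrum (all library fragments,
including every diagnostic one); 2b requires ≥2 diagnostic fragments;
3 is exactly one supporting fragment; 4 requires an unequivocal
formula, operationalized as: exactly one suspect-list formula within
the MS1 window whose chlorine count matches the isotope pattern; 5 is
exact mass only. Level 1 is reserved for reference-standard
confirmation (RT within tolerance and ≥2 standard fragments
recovered); a standard that fails either check refutes the candidate
as a false positive. Dual-polarity detections collapse to one structure
keeping the best level.

## Semiquantification

Responses are internal-standard-normalized areas (one IS per polarity),
blank-subtracted, fit by least squares over matrix-matched levels
0.1/1/10 µg/L. Linearity requires R² ≥ 0.98 (configurable) and a
positive slope; with exactly two detected points the line is exact and
only the slope sign is judged. Bins are left-closed: [0.1, 1), [1, 10),
[10, ∞), so an estimate of exactly 1.0 µg/L reports "1–10". Fallbacks:
no linearity → "detected"; lowest level undetected and estimate <1 →
"<1"; negative back-calculated estimate → "<0.1" with an audit note.
A solvent-only calibration can be loaded but plays no role in range
assignment.

## Synthetic scenarios

The generator emulates the assumed study design: two sites (E, M), two
four-week campaigns of weekly composite samples, both polarities,
spiked TPs at known concentrations (defaults cycle 0.05/0.3/3/30 µg/L,
the midpoints and below-limit point of the four ranges), ~10 %
multiplicative (log-normal) area noise, a configurable fraction of TPs
with library spectra and standards, and uniform-m/z decoy features kept
20 ppm away from any suspect so ground truth stays unambiguous.
Retention times are drawn from the same descriptor line the RT model
fits, plus Gaussian jitter; isotope clusters follow the simulated
pattern of each formula; MS2 spectra are copied from the library record
when one exists. Compound formulas are random CHNOS(Cl) compositions in
pesticide-like ranges — structural realism (real degradation chemistry,
adduct diversity, matrix suppression, RT drift) is *not* modeled, so
passing tests demonstrate the correctness of the decision logic and the
statistical behavior of the estimators, not instrument-level
performance on real extracts.

A separate accounting fixture hand-shapes a candidate set (23
strong/moderate hits of which 4 suspects appear in both polarities, 19
monitoring-rescued weak hits, 8 unsupported weak hits, standards for 26
of the 38 unique structures with 11 constructed to match) so the
retention, deduplication and confirmation arithmetic is verifiable
end-to-end.

Default test problem sizes (handfuls of parents, 2–8 weeks, ≤10 decoys
per sample) were chosen so the whole suite exercises every stage in
seconds while keeping ≥200 replicates wherever a rate is asserted.

## Known limitations

* Only [M+H]+ and [M−H]− are supported; no multimers, adducts beyond
  protonation, or multiply charged species.
* Peak-quality scoring uses half-height widths and edge noise, not a
  full chromatographic model; heavily overlapping peaks are out of
  scope (the generator does not produce them).
* The evidence-tier and confidence-level rule tables formalize
  narrative expert judgment; borderline real-world cases will need the
  thresholds revisited.
* The raw-data cascade of a real campaign is not reproducible from
  synthetic inputs; only its monotone structure (each gate can only
  shrink the hit set) is asserted.
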
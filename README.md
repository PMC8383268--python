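# tpscreen

Monitoring-integrated LC-HRMS suspect screening of pesticide
transformation products (TPs) in surface water.

## The problem

Pesticide monitoring programs quantify a fixed list of parent compounds,
but many pesticides reach surface water mainly as transformation
products — degradates formed in soil or water that are often more polar,
more mobile, and rarely covered by target methods. Suspect screening
with high-resolution mass spectrometry (HRMS) can look for hundreds of
expected TPs without reference standards, but chemical evidence alone
(exact mass, fragments, retention) is frequently too thin for trace-level
TPs: reference spectra are missing, signals are weak, and candidates get
discarded.

`tpscreen` implements a two-step workflow that combines the chemical
evidence with *monitoring knowledge* — which parents are registered,
applied, and detected at each sampling site, and how mobile each TP is
relative to its parent (soil organic-carbon partitioning, K_foc). Weak
but monitoring-supported candidates are kept instead of discarded;
chemically confident candidates whose presumed parent was never used
nearby are flagged as likely coming from another source.

It is aimed at environmental analytical chemists running screening
campaigns against regional monitoring databases, and at method
developers who need a fully synthetic, ground-truthed testbed for
screening logic.

## What it computes

- **Suspect list**: monitored target pesticides, their regulatory "key
  metabolites", additional parents of interest, and *their* key
  metabolites — each with neutral monoisotopic mass and expected
  [M+H]+ / [M−H]− m/z.
- **Evidence cascade**: exact-mass matching (ppm tolerance) → peak
  shape and S/N gate → retention-time plausibility against a linear
  hydrophobicity model → MS2 evidence (library and diagnostic fragment
  matches, and the fraction of product ions explainable as subformulas
  of the precursor ion, `m/z = Σ nᵢmᵢ − z·mₑ`).
- **Isotope-pattern chlorine counting**: the observed A+2/A ratio is
  matched against convolved natural-abundance patterns
  (≈0.32 per Cl), with A+4 as tie-breaker.
- **Retention decision**: strong/moderate chemistry always retained;
  weak hits retained iff the parent was applied or detected at the
  site; contradicted source plausibility attaches a warning, never
  deletes a confirmed structure.
- **Confidence levels** on the standard ordinal scale 1–5 (1 =
  confirmed by reference standard, 2a = library spectrum, 2b =
  diagnostic fragments, 3 = one supporting fragment, 4 = unequivocal
  formula, 5 = exact mass only), with cross-polarity deduplication.
- **Semiquantification** into ordinal ranges <0.1, 0.1–1, 1–10,
  >10 µg/L from IS-normalized matrix-matched calibration at
  0.1/1/10 µg/L, with the two standard fallbacks ("detected" when the
  curve is non-linear; "<1" when the lowest level was not detected).

A seeded synthetic-scenario generator produces the complete input set
(registry, metabolite table, picked-feature tables, MSP library,
monitoring metadata, standards, calibration) with known ground truth.

## Worked example

```sh
tpscreen simulate --seed 3 --out demo
tpscreen run-all --config demo/config.json --out demo/report
```

with `demo/config.json` pointing at the generated files
(`{"inputs": {"registry": "demo/registry.csv", ...}}`) prints the stage
counts

```json
{
 "matched": 96,
 "after_peak_rt": 96,
 "after_fragments": 96,
 "retained": 96,
 "unique": 6,
 "confirmed": 2,
 "false_positives": 0
}
```

i.e. 96 suspect hits survived all gates, collapsing to 6 unique spiked
TPs, 2 of which were confirmed at level 1 against reference standards.
`demo/report.csv` begins

```
suspect_id,name,formula,confidence_level,polarities,parent_ids,sites,concentration_range,source_warning,last_application
P000-TP2,tp-000-2,C7H8ClNO4,1,positive,P000,E;M,E:<0.1;M:<0.1,False,2016-08-04
P004-TP2,tp-004-2,C12H25ClO3,1,negative,P004,E;M,E:1-10;M:1-10,False,2010-09-11
P002-TP1,tp-002-1,C6H10ClN2O2,2a,positive,P002,E;M,E:0.1-1;M:0.1-1,False,2015-07-10
```

reading: TP `P000-TP2` was confirmed (level 1) in positive mode at both
sites at under 0.1 µg/L; its parent `P000` was last applied in August
2016. Adding `--disable-monitoring` reruns the chemistry-only baseline;
the retained count can only drop (here 96 → 64), which is exactly the
benefit the monitoring integration buys.

In the library API the same run is
`tpscreen.run_pipeline(PipelineInputs(...))`.

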
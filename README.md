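# miplantpremat

Classification of plant pre-miRNA hairpins and their mature miRNAs from
structure-sequence features, with a homology-seeded genome scanner.

Plant miRNA precursors fold into stem-loop (hairpin) structures that
are longer and structurally messier than animal precursors, and coding
sequence is full of hairpin-like segments that are *not* precursors.
This package is for computational biologists who want to (1) separate
real plant pre-miRNA hairpins from such pseudo hairpins, (2) locate the
mature miRNA on a precursor, and (3) discover candidate miRNAs in
genome-scale sequence by homology to known matures.

## The method

* A **152-feature descriptor** of a folded hairpin in six groups:
  nine MFE indices (e.g. MFEI1 = (MFE/L)/GC, MFEI4 = MFE/tot_base_pairs,
  plus begin/end-window variants MFEI7–9), dinucleotide and GC
  composition with stem mismatch counts, two-temperature thermodynamics
  (dS, dH, Tm), base-pair type proportions, 96 structure-nucleotide
  triplet frequencies ("G(((", "A.((", … over the whole stem and its
  first/last 21 bases), and RNAfold ensemble features (dP, dG, dQ, dD,
  dF, their shuffle z-scores, NEFE, Freq, Diversity, Diff).  Folding is
  ViennaRNA at 37 °C; features are min–max scaled to [−1, 1].
* **Training corpora**: pseudo hairpins mined from CDS windows
  (60–150 nt) under base-pair, GC, MFEI, consecutive-mismatch and
  stability filters (a fitted sigmoid f(x) = a/(b + e^{x·c}) of
  x = MFE/length); mature-stage segments cut by *interception* — the
  precursor trimmed so the miRNA*–miRNA span forms the termini.
* **B-SVM-RFE feature selection**: SVM-RFE (eliminate the smallest
  squared weight of a linear SVM) with information-gain backtracking —
  eliminated high-gain features are provisionally re-admitted and kept
  when 5-fold CV error strictly improves.
* A **two-stage RBF-SVM** (precursor stage, then a mature-locating
  stage over pairing-closed sub-segments longer than 55 nt), with
  SMOTE rebalancing (x_new = x + rand·(y − x)) for the 1:5
  mature-stage class ratio, grid-searched (C, γ), and SE/SP/Acc/Gm
  evaluation.
* A **genome scanner**: queries split into four nearly equal seeds,
  exact KMP seed matching, Hamming verification with ≤2 mismatches
  (complete by pigeonhole), hairpin-context extraction and filtering,
  then two-stage classification.

See `docs/methods.md` for the full conventions and assumptions.

## Worked example

```python
from miplantpremat import FeatureConfig, extract_all, intercept, MatureAnnotation
from miplantpremat.simulate import HairpinSpec, make_hairpin

# a 201-nt synthetic single stem-loop precursor
record, _ = make_hairpin(HairpinSpec(stem_len=95, loop_len=11, gc=0.5,
                                     degrade=0.02, seed=7), plant_mature=False)
print(len(record), record.structure.mfe)

mature = MatureAnnotation(record.id, mir_interval=(147, 168),
                          star_interval=(30, 51))
trimmed = intercept(record, mature)
print(len(trimmed))

vec = extract_all(trimmed, FeatureConfig(shuffles=8, seed=0))
d = vec.as_dict()
print(round(d["MFEI1"], 3), round(d["dP"], 3), round(d["%G+C"], 3))
```

prints

```
201 -189.5
138
-1.775 0.449 0.493
```

— the original precursor is 201 nt with an MFE of −189.5 kcal/mol (a
near-perfect designed repeat is far more stable than a typical real
precursor); interception (trimming everything before the miRNA* and
after the mature miRNA) leaves 138 nt; on the trimmed hairpin the
length-normalised MFE over GC content (MFEI1) is −1.775, 44.9 % of
positions are paired (dP) and the GC fraction is 0.493.  MFE values are
specific to the pinned folding engine (ViennaRNA 2.7.2 here).

Training and prediction follow the usual model/results pattern:

```python
from miplantpremat import PrecursorClassifier
results = PrecursorClassifier.from_dataframe(feature_df).fit(seed=0)
print(results.summary())
metrics = results.evaluate(test_df, test_labels)   # SE, SP, Acc, Gm
```

The same pipeline is scriptable from the shell:
`miplantpremat simulate hairpins`, `fold`, `intercept`, `features`,
`mine-negatives`, `select`, `train`, `predict`, `scan`.

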
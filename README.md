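# strainpheno

Tools for asking how the *physical* gut environment — acidity and particle
concentration — shapes which bacteria can grow. The package implements a
complete analysis chain for high-throughput phenotyping of gut bacterial
strains under pH and osmolality stress, and for connecting those phenotypes
to genome annotations and to community composition:

1. **Growth quantification** — parse plate-reader kinetic runs (OD600 sampled
   every 13 min), discard wells whose OD rises no earlier than sterile
   controls, keep the three most mutually similar of four technical
   replicates, and fit each curve with the modified Gompertz model

   $$\mathrm{od}(t) = y_0 + A\,\exp\!\left(-\exp\!\left(\tfrac{\mu_m e}{A}(\lambda - t) + 1\right)\right)$$

   so the maximum growth rate $\mu_m$ (OD/h), asymptotic rise $A$ (OD) and lag
   $\lambda$ (h) are direct parameters. Metrics are normalized within each
   strain across all eight conditions (pH 4–8; ~440–1800 mOsm/kg).
2. **Environmental pH inference** — BCECF is a ratiometric dye: the emission
   ratio $R = F_{490}/F_{440}$ (em 535 nm) rises monotonically with medium pH.
   After per-timepoint background subtraction against a dye-free sister well,
   a per-experiment monotone calibration curve inverts $R(t)$ to pH$(t)$.
3. **Annotation featurization** — PATRIC-style subsystem exports are counted
   into features named `"<Column> = <value>"` (e.g. a genome with seven
   "DNA repair, bacterial" subsystem rows gets feature value 7), plus binary
   taxonomy indicators (`"Family = Bacteroidaceae"`).
4. **Decision-stump feature ranking** — every feature is scored by a
   single-feature one-level regression tree predicting the four normalized
   max-OD outputs jointly: the threshold minimizing the total squared error
   over both leaves is found exhaustively over midpoints of consecutive
   distinct values. Under shared 5-fold cross-validation each feature gets a
   mean train and test error; features are ranked by their **worst** (maximum)
   rank across the two, penalizing overfit features, and the decision
   threshold reported for binary partitions is the mean over folds.
5. **Community correlations** — family-level relative abundances from
   multi-donor fecal fermentations are correlated (Pearson r) against the
   numeric pH or osmolality gradient, pooling donors, with zeros kept as real
   observations.

A first-class synthetic-data module generates all three input kinds with known
ground truth (Gompertz curves with noise, contaminated controls, BCECF
channels consistent with a pH trajectory, annotation tables with planted
predictive features, communities with planted abundance–condition slopes), so
every stage is testable without the deposited experimental data.

## Worked example

The `analysis/` scripts run the whole chain on synthetic data (seed 1):

```bash
python analysis/01_simulate_inputs.py      # plate + layout + calibration
python analysis/02_quantify_growth.py
python analysis/03_infer_ph.py
python analysis/04_rank_features.py
python analysis/05_community_correlations.py
```

prints

```
48 strain x condition metrics (38 growing); median |mu error| = 0.44%
QC actions: 0
144 BCECF wells; max |pH error| = 0.00e+00; 100.0% of points inside the calibration range
ranked 608 features over 5 folds
  planted 'Osmotic stress cluster': worst_rank=1, mean test error=0.0142
  planted 'Choline uptake and conversion to betaine': worst_rank=10, mean test error=0.0231
  top feature: 'Subsystem Name = Osmotic stress cluster' (mean threshold 0.50)
pooled family correlations with osmolality (6 donors x 8 levels):
  Lachnospiraceae      r = -0.85
  Bacteroidaceae       r = -0.52
  Bifidobacteriaceae   r = -0.42
  Lactobacillaceae     r = +0.41
  Enterobacteriaceae   r = +0.65
  Enterococcaceae      r = +0.75
```

Reading this: fitted maximum growth rates recover the generating values to a
median 0.4%; the noiseless BCECF round trip is exact; the planted
osmotolerance subsystem is the top-ranked feature out of 608; and the planted
family responses survive compositional renormalization and noise with the
expected signs — osmotolerant Enterococcaceae correlate positively with the
osmolality gradient, osmosensitive Lachnospiraceae negatively. Tables land
under `results/`.

There is also a CLI (`strainpheno simulate|growth-fit|ph-infer|featurize|rank|commcorr`)
wrapping the same library calls for use on external files in the documented
CSV/TSV dialects.

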
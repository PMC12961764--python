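# domtransect

Integrative **¹H NMR + FT-ICR-MS analysis of dissolved organic matter (DOM)**
along river-to-coastal-ocean transects.

DOM is one of Earth's largest reduced-carbon reservoirs, and its fate in
estuaries is controlled by molecular transformations that no single analytical
window resolves. Ultrahigh-resolution mass spectrometry (FT-ICR-MS) yields
thousands of molecular formulas per sample but no structural information; 1D ¹H
and 2D COSY NMR resolve structural motifs (aliphatic, acetyl, carbonyl- and
oxygen-adjacent, olefinic, aromatic protons) but not individual compounds.
`domtransect` implements the full statistical workflow that links the two, for
researchers in environmental metabolomics and marine biogeochemistry:

* **NMR processing** — resampling, solvent excision (4.70–5.05 and
  3.20–3.45 ppm), structural-section integration, equal-width binning
  (half-open bins, exact counts), SNR-3 noise filtering of COSY grids,
  diagonal-bin flagging and removal, data-matrix assembly;
* **bin-size optimization** — sweep bin sizes from coarse to fine, track the
  mean pairwise Bray–Curtis dissimilarity among samples, fit
  *y = a·ln(n_bins) + b*, and select the knee by exhaustive two-segment
  least-squares search;
* **molecular-formula tools** — CHNOSP parsing, H/C, O/C,
  DBE = 1 + C − H/2 + N/2 + P/2 and the modified aromaticity index
  AI_mod = (1 + C − O/2 − S − H/2)/(C − O/2 − S − N − P) (clamped to 0),
  van Krevelen compound groups (saturated, saccharide, unsaturated, highly
  unsaturated, aromatic, PAC) and the three sulfur boxes (dissolved black
  sulfur; highly unsaturated S; sulfurized aliphatic compounds);
* **diversity** — richness and base-2 Shannon index (with diagonal exclusion
  for COSY), Bray–Curtis dissimilarity matrices;
* **multivariate statistics** — PCoA (classical scaling), envfit-style
  post-hoc vector fitting with permutation tests, exact-enumeration Spearman
  correlation maps in van Krevelen space, and canonical correlation analysis
  (CCorA, Pillai's trace permutation test) linking the NMR- and MS-based
  ordinations;
* **a synthetic transect generator** — eight pooled samples (river, four
  brackish mangrove-fringed, seawater, and two tidal-creek samples) with
  salinity-linked aromatic/aliphatic gradients, diagonal-dominated COSY
  grids, per-sample chemical-shift jitter, and a mangrove-localized
  sulfurized-aliphatic signal, with ground truth attached for recovery tests.

## Worked example

```python
from domtransect.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))

print(report.section_fractions.round(1).loc[["RW", "BW2", "SW"]])
print("PC1+PC2 variance, NMR block: "
      f"{100 * report.proportion_explained['nmr'][:2].sum():.0f}%")
fit = report.vector_fits["nmr"].loc["salinity"]
print(f"salinity vector: r = {fit['r']:.2f}, p = {fit['p_value']:.4f}")
cc = report.ccora_summary
print(f"CCorA: first canonical r^2 = {cc['squared'].iloc[0]:.2f}, "
      f"Pillai p = {cc['p_value'].iloc[0]:.3f}")
```

prints

```
     aliphatic  acetyl  alpha_carbonyl  alpha_oxygen  olefinic  aromatic
RW        30.0     9.5            15.7          31.3       4.5       9.0
BW2       33.1    10.0            16.5          30.2       3.5       6.8
SW        37.0    10.6            17.5          28.6       2.2       4.0
PC1+PC2 variance, NMR block: 64%
salinity vector: r = 0.95, p = 0.0021
CCorA: first canonical r^2 = 0.92, Pillai p = 0.006
```

Reading the output: each row is one sample's percent of ¹H intensity per
structural section — aliphatic protons rise from 30% (river) to 37%
(seawater) while aromatic protons fall from 9% to 4%, the classic
terrestrial-to-marine shift. The salinity covariate fits the COSY-based
ordination strongly (r > 0.5 is the conventional "strong" threshold), and
CCorA shows that the structural (NMR) and compositional (MS) ordinations
share their leading gradient.

The same stages are available from the shell:

```bash
domtransect simulate --out bundle/ --seed 1
domtransect process-nmr --bundle bundle/ --out nmr/ --bin-size-1d 0.10 --bin-size-2d 0.05 --snr 3
domtransect optimize-bins --bundle bundle/ --mode 2d --sizes 0.02:1:geometric:15 --out sweep.tsv
domtransect classify-ms --table bundle/formulas.tsv --out classified.tsv
domtransect correlate --bundle bundle/ --covariate salinity --out map.tsv
domtransect ccora --bundle bundle/ --permutations 719 --seed 1
domtransect report --out report/ --seed 1
```

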
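# evflux

Quantitative pipelines for two recurring measurements in autophagy /
extracellular-vesicle (EV) biology:

1. **Fluorescence-field quantification.** Cells expressing the tandem
   mRFP(TagRFP)-GFP-LC3 sensor report autophagic flux: autophagosomes carry
   both red and green signal, autolysosomes only red because lysosomal pH
   quenches GFP. `evflux` segments cells from multi-channel fields
   (median 7×7 → Gaussian σ=1 → threshold → morphological closing →
   removal of components < 5000 px), extracts per-field (or per-cell) mean
   channel intensities, and computes the "yellow signal" colocalization
   score, mean(TagRFP × eGFP) over the cell mask. A companion chain counts
   live/dead cells on Hoechst + propidium-iodide fields with a
   Laplacian-of-Gaussian detector (σ=6, minimum inter-cell distance 10 px)
   and PI-positivity scoring.
2. **PS-EV proteome differential abundance.** For label-free
   (MaxLFQ-style) protein intensity matrices: log2 normalization,
   proteotypic-peptide filtering, outlier-replicate removal, stochastic
   imputation anchored at the dataset minimum, empirical-Bayes moderated
   t-tests of every treatment against the control with Benjamini–Hochberg
   FDR control, volcano classification, hypergeometric over-representation
   analysis (ORA), and overlap reporting against reference databases such
   as ExoCarta and Vesiclepedia.

The moderated statistic for protein *g* shrinks the pooled residual
variance s²_g (df d_g) toward a scaled-inverse-χ² prior (d₀, s₀²)
estimated by log-variance moment matching:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
    t̃_g  = (mean_treat − mean_ctrl) / (s̃_g · √(1/n_t + 1/n_c)),   df = d₀ + d_g

d₀ = 0 reduces to the classical pooled t-test, d₀ = ∞ to a fixed-variance
z statistic.

Because raw microscopy and proteomics deposits are not required to
exercise the methods, the package ships first-class synthetic-data
generators with full ground truth: cell-shaped tapered discs with
sub-threshold debris and a known live/dead partition, and abundance
matrices with scaled-inverse-χ² per-protein variances, a spiked
differential fraction and intensity-dependent missingness.

## Worked example

```python
import numpy as np
from evflux import (SyntheticImageSpec, generate_flux_field, CellSegmenter,
                    composite_sum, field_intensities, SyntheticProteomeSpec,
                    generate_abundance_matrix, log2_normalize,
                    impute_min_random, moderated_ttest, volcano_table,
                    summarize_calls)

# --- imaging arm: segment one synthetic flux field and extract signal
field, truth = generate_flux_field(SyntheticImageSpec(seed=1))
mask = CellSegmenter().segment(composite_sum(field))
s = field_intensities(field, mask)[0]
print("components:", mask.n_components, "foreground px:", mask.area)
print("mean TagRFP: %.1f  mean eGFP: %.1f  coloc: %.1f"
      % (s.channel_means["TagRFP"], s.channel_means["eGFP"], s.colocalization))

# --- proteomics arm: full differential-abundance chain
matrix, _ = generate_abundance_matrix(SyntheticProteomeSpec(seed=1))
m = impute_min_random(log2_normalize(matrix), seed=1)
table = volcano_table(moderated_ttest(m), adj_p_cut=0.05, lfc_cut=1.0)
print(summarize_calls(table))
```

prints

```
components: 5 foreground px: 37381
mean TagRFP: 109.5  mean eGFP: 109.2  coloc: 11977.1
call        enriched  depleted    ns
comparison
T1-vs-CTR         45        31  1924
```

All five simulated cells are recovered as components ≥ 5000 px (the two
debris discs are removed by the area rule); the channel means sit near
the simulated base intensity of 100 plus the background of 10, and the
colocalization score is the mean per-pixel TagRFP×eGFP product inside
the mask. In the proteomics run, 2000 proteins with 10% true
differential abundance at ±1 log2 unit yield 76 calls at adjusted
p < 0.05 and |log2FC| > 1, split by sign.

The same functionality is exposed as a CLI — `evflux simulate-image`,
`simulate-proteome`, `flux`, `viability`, `diffprot`, `ora`, `overlap` —
where every run writes a JSON manifest (parameters, seeds, input digests,
per-stage counts) for replay.

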
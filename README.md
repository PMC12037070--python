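# rrnclust

Quantitative pipelines for studying the spatial clustering of ribosomal RNA
(*rrn*) operons on the *Escherichia coli* chromosome. Six of the seven *rrn*
operons, spread over half the 4.6 Mb genome, co-localize into a cluster; the
package implements the three measurement chains used to quantify that
organization and its disruption (e.g., by heat shock or elevated σ factor
levels), each exercisable end-to-end on synthetic data with ground truth.

It is aimed at bacterial cell-biology and chromosome-organization labs that
collect one or more of:

1. **Two-color focus-pair distances** (`rrnclust.imaging`). Chromosomal loci
   tagged with orthogonal parS/ParB fluorescent systems appear as diffraction-
   limited foci. The pipeline detects maxima per channel after white-tophat
   background subtraction, pairs every GFP focus with its closest CFP focus,
   converts pixel separations to nm (1 px = 62 nm), and summarizes
   distributions by median and quartiles. Two conditions are compared by the
   median fold change *f* = med(treatment)/med(control) with a two-sided
   Mann–Whitney U p-value reported alongside; "de-clustering" is called when
   *f* ≥ 2.5 (configurable, including an absolute-nm threshold variant).

2. **Mu-transposition contact maps** (`rrnclust.mu_contacts`). Phage Mu
   transposes into DNA it physically touches, so insertion frequency from a
   fixed donor locus proxies chromosomal contact frequency. The genome is
   partitioned into 100 equal bins (~46 kb); per-bin insertion counts
   *I<sub>b</sub>* are corrected for sequencing depth and for the replication
   copy-number gradient via each bin's share of total mapped reads
   *R<sub>b</sub>*:

   *f<sub>b</sub>* = (*I<sub>b</sub>* / Σ*I*) / (*R<sub>b</sub>* / Σ*R*),

   rescaled per replicate to percent of the maximum bin (max = 100),
   averaged over replicates (mean ± sample SD), and compared between
   conditions at *rrn*-containing bins with a two-tailed Student *t* test
   (α = 0.05).

3. **dCas9 pulldown enrichment** (`rrnclust.pulldown`). Spectral counts from
   locus-directed dCas9 pulldowns are depth-matched to a lacZ-gRNA control
   pulldown, converted to per-replicate log2 target/control ratios, and
   standardized with a robust z-score, z = (x − median)/(1.4826·MAD), over
   the protein bulk. A protein is called enriched when z > 2.5 in every
   replicate; an empirical FDR comes from recomputing the statistic under
   all target/control label swaps. Calls are intersected across sgRNAs into
   an upset-style membership table.

`rrnclust.synth` generates inputs for all three chains (log-normal pair
separations rendered as Gaussian spots; multinomial insertions under a
contact profile times a 2× ori→ter copy-number gradient, with matched
coverage; negative-binomial spectral counts with planted enrichment),
carrying exact ground truth. `rrnclust.assays` provides Miller units,
MU = 1000·A420/(t·A600·0.02), and CFU survival fractions.

## Worked example

```python
import numpy as np
from rrnclust import imaging, synth

config = imaging.ImagingConfig()
pairsets = {}
for condition in ("clustered", "declustered"):
    params = synth.FociSimParams(n_cells=300, seed=42)
    sim, truth = synth.simulate_foci_field(params, condition=condition)
    gfp = imaging.detect_foci(sim.gfp_image, config, channel="GFP")
    cfp = imaging.detect_foci(sim.cfp_image, config, channel="CFP")
    pairs = imaging.to_nm(imaging.match_pairs(gfp, cfp, config), config)
    s = imaging.summarize(pairs)
    pairsets[condition] = pairs
    print(f"{condition}: n={s.n}  median={s.median_nm:.0f} nm "
          f"(Q1 {s.q1_nm:.0f}, Q3 {s.q3_nm:.0f}); "
          f"truth median {np.median(truth.true_pair_distances_nm):.0f} nm")

res = imaging.compare_conditions(pairsets["clustered"],
                                 pairsets["declustered"], config)
print(f"fold change {res.fold_change:.2f}, "
      f"Mann-Whitney p = {res.p_value:.2e}, declustered = {res.declustered}")
```

prints

```
clustered: n=300  median=131 nm (Q1 87, Q3 187); truth median 127 nm
declustered: n=300  median=548 nm (Q1 386, Q3 763); truth median 537 nm
fold change 4.18, Mann-Whitney p = 4.85e-86, declustered = True
```

All 300 simulated locus pairs per condition are recovered by detection and
pairing; the recovered medians sit within a few nm of the generating truth,
and the 4.2-fold median increase crosses the 2.5-fold rule, so the
de-clustered condition is flagged while the p-value (driven by the large
*n*) is reported for reference.

A `rrnclust` console script exposes the same stages
(`rrnclust simulate|imaging|mu|pulldown|assays --help`); every run writes a
manifest JSON with parameters, seed, and output hashes.

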
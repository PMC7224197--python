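# rootpheno

Image-based storage-root phenotyping and genomic analysis for clonal crop
breeding trials.

Storage-root crops such as cassava are scored for root size and shape by
eye, which is subjective and cannot describe within-plot variation.
An alternative is to photograph the harvested roots of each plot on a
green reference board carrying painted circles of known diameter, and to
measure every root from the image. `rootpheno` implements that pipeline
end to end:

1. **Image phenotyping** — hue-threshold segmentation of the board
   photograph, connected-component particle extraction, and seven
   descriptors per root: area, perimeter, Feret diameter (maximum
   caliper), circularity (4πA/P²), roundness (4A/πM²), solidity
   (A/convex-hull area) and aspect ratio, converted from pixels to cm
   with the scaling coefficient √(circle area px² / circle area cm²).
2. **Stage-1 mixed models** — per-plot trait means and per-plot standard
   deviations (root-uniformity traits), fitted by REML as
   y = Xm + Z_clone c + Z_range r + ε (range optionally nested in
   location, disease severity optionally a fixed covariate), yielding
   variance components, broad-sense heritability H² = σ²_c/(σ²_c+σ²_e),
   GCV/PCV, clone BLUPs with reliabilities, and de-regressed BLUPs.
3. **Genomic prediction** — marker QC (missingness, Hardy-Weinberg,
   MAF), a VanRaden genomic relationship matrix, GBLUP via spectral
   REML, and 5-fold × 25-replicate cross-validated accuracy.
4. **GWAS** — mixed-linear-model association with a
   leave-one-chromosome-out GRM, MAF > 0.05, and a Bonferroni threshold
   computed from the number of markers actually tested.
5. **Synthetic data** — board images with analytically known geometry
   and simulated augmented trials (QTL + polygenic architecture, range
   and covariate effects, a disease score confounded with a resistance
   locus), so every stage can be validated against ground truth.

## Worked example

```python
import rootpheno as rp
from rootpheno.stage1 import fit_stage1, deregress, variability_stats
from rootpheno.gwas import mlma_scan

# --- a synthetic board with two roots of known geometry (10 px/cm) ---
spec = rp.BoardSpec(n_roots=2, px_per_cm=10, seed=1, root_shape_params=[
    rp.RootShape(a_cm=6, b_cm=2),                       # 6x2 cm ellipse
    rp.RootShape(a_cm=8, b_cm=3, theta=0.7, exponent=3) # blockier outline
])
img, truth = rp.generate_board_image(spec)
scale = rp.detect_scale_circles(img)
print(f"scaling: {scale.n_circles_used} circles, "
      f"{scale.scaling_coefficient:.3f} px/cm")
print(rp.phenotype_image(img)[["area", "feret", "aspect_ratio"]].round(3))
```

```
scaling: 5 circles, 10.003 px/cm
     area   feret  aspect_ratio
0  84.754  15.991         2.667
1  37.695  11.903         2.997
```

The true scale is 10 px/cm; the ellipse's analytic area and maximum
caliper are π·6·2 = 37.70 cm² and 12 cm, measured as 37.695 cm² and
11.90 cm. The second root's truth is 84.80 cm² / 16.01 cm.

```python
# --- a simulated 500-clone trial, 2 plots per clone ---
geno = rp.simulate_genotypes(n_clones=500, n_markers=1000, seed=2)
sim = rp.simulate_trial(
    geno,
    rp.TrialParams(trait="area", mu=120, h2_plot=0.4,
                   sigma2_range=40, sigma2_e=400),
    rp.DesignSpec(plots_per_clone=2), seed=2)

vc, est = fit_stage1(sim.phenotypes, "area", model=2)
h2, gcv_pct, pcv_pct = variability_stats(vc)
print(f"H2={h2:.2f}  GCV={gcv_pct:.2f}%  PCV={pcv_pct:.2f}%")

dereg = deregress(est).set_index("clone_id")
scan = mlma_scan(dereg["deregressed_egv"], geno, trait="area")
print(f"tested {scan.attrs['n_tested']} markers, Bonferroni cutoff "
      f"{scan.attrs['bonferroni_neg_log10']:.2f}, "
      f"{int(scan['significant'].sum())} significant")
```

```
H2=0.42  GCV=14.04%  PCV=21.78%
tested 995 markers, Bonferroni cutoff 4.30, 3 significant
```

The REML components recover the generating values (true plot-basis H² is
0.40), and the scan flags markers near the simulated QTL. The same steps
are available from the shell:

```bash
rootpheno simulate boards --seed 3 --out boards/
rootpheno phenotype --images boards/ --out roots.csv
rootpheno simulate trial --seed 3 --out trial/
rootpheno stage1 --plots trial/plot_phenotypes.csv --trait area --model 2 --out s1/
rootpheno predict --pheno s1/area_mean_egv.csv --geno trial/dosages.csv --seed 3 --out pred/
rootpheno gwas --pheno s1/area_mean_egv.csv --geno trial/dosages.csv --out gwas/
```

All stages are deterministic given `--seed`: rerunning produces
byte-identical tables.

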
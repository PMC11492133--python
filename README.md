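# tfcrkit

Tools for calling and characterising **transcription-factor-binding-site
clustered regions (TFCRs)** from motif hits in accessible chromatin.

In ATAC-seq-accessible regions, motif matches (TFBSs) pile up in dense local
clusters. Each such cluster behaves like a candidate cis-regulatory element:
the more distinct TF families that can bind it, and the more tightly their
sites pack, the stronger its association with the expression of nearby
genes. `tfcrkit` quantifies this for developmental series such as early
human embryogenesis (2Cell → 4Cell → 8Cell → ICM → primed hESC), where the
coupling between regulatory-element complexity and expression switches on
at zygotic genome activation (ZGA, the 8Cell stage in human).

The pipeline:

1. **Call TFCRs.** The unnormalised Gaussian kernel sum over TFBS interval
   midpoints is evaluated per chromosome (σ = 300 bp, 10-bp grid). Every
   local maximum of the density is a TFCR; a site contributes to it when
   its kernel weight at the peak is ≥ 0.1, i.e. when it lies within
   σ·√(2 ln 10) ≈ 644 bp of the peak.
2. **Score complexity.** TC = Σ kernel weights over contributing sites
   after family deduplication (same-family sites with overlapping
   intervals count once, keeping the maximum weight). Width TW is the span
   of the contributing sites, cw = TC / TW is the unit-base complexity,
   and CAS is the mean score of overlapping ATAC peaks. Within a sample,
   TFCRs are decile-binned TC0 (lowest) … TC9 (highest).
3. **Link to genes.** Nearest-TSS pairing in both directions with all
   exact-distance ties retained; the absolute peak–TSS distance d
   classifies every link: R1 (d ≤ 2 kb, proximal/promoter-like),
   R2 (2–27 kb), R3 (27–50 kb), R4 (d > 50 kb, long-range "LR-TFCRs").
   The cuts can also be re-derived from the local extrema of the distance
   density, whose modes sit near 500 bp and 27 kb with a valley near 2 kb.
4. **Associate with expression.** Spearman correlations of TC / TW / CAS
   against log10(FPKM + 1) per region and stage; the saturating law
   y = a·log10(TC + c) + b with c = 0.03; Welch t-tests with the
   `*`/`**`/`***`/`****` significance ladder.
5. **Track dynamics.** Positional TFCR identity across stages (≥ 1 bp
   interval overlap) yields gained / lost / kept sets per stage and
   stage-stable regions (the interval-intersection chain); per-gene TC
   trajectories are z-standardised and clustered with fuzzy c-means
   (c = 6, m = 2), mirroring soft time-course clustering.
6. **Spatial context.** TAD co-localisation of long-range links (peak and
   TSS in the same domain or not) and phase-separation TF (PSTF)
   annotation of TFCRs from an LLPS-derived TF name list, with grouped
   complexity/expression comparisons.

A first-class synthetic-data generator (`tfcrkit.synthetic_data`) emulates
all of this structure with known ground truth — planted cluster centers and
complexities, a bimodal-plus-tail TSS-distance mixture, a saturating
expression law, tiling TADs, a PSTF effect, and a five-stage panel with a
planted activation stage — so the whole pipeline is testable without any
external data.

## Worked example

```python
import tfcrkit as tk

config = tk.SyntheticConfig(seed=1, n_genes=500)
paths, truth = tk.generate_bundle(config, "example_bundle")

family_map = tk.read_family_map(paths.family_map)
tfbs = tk.read_fimo_tfbs(paths.tfbs, family_map)
tfcrs = tk.call_tfcrs(tk.kde_density(tfbs), tfbs, stage="demo")
tk.assign_tc_bins(tfcrs)
print(f"{len(tfbs)} TFBSs -> {len(tfcrs)} TFCRs")

genes = tk.read_gene_tss(paths.genes, format="bed")
links = tk.classify_regions(
    tk.link_nearest(tfcrs, genes, direction="tfcr_to_gene"),
    tk.RegionThresholds(*tk.DEFAULT_THRESHOLDS),
)
for region, frac in tk.region_proportions(links).items():
    print(f"{region}: {100 * frac:.1f}%")

expr = tk.read_expression_table(paths.expression)
gene_links = tk.link_nearest(tfcrs, genes, direction="gene_to_tfcr")
tc = {t.tfcr_id: t.tc for t in tfcrs}
x = [tc[l.tfcr_id] for l in gene_links if not l.is_no_tfcr]
y = [expr.log_expr(l.gene_id) for l in gene_links if not l.is_no_tfcr]
rho = tk.spearman(x, y)
fit = tk.fit_log_model(x, y)
print(f"Spearman(TC, log10(FPKM+1)) = {rho.rho:.3f} ({rho.stars})")
print(f"log fit: y = {fit.a:.2f}*log10(TC + {fit.c}) + {fit.b:.2f}, R^2 = {fit.r_squared:.3f}")
```

Output:

```
4326 TFBSs -> 500 TFCRs
R1: 45.2%
R2: 17.2%
R3: 16.2%
R4: 21.4%
Spearman(TC, log10(FPKM+1)) = 0.778 (****)
log fit: y = 1.51*log10(TC + 0.03) + 0.24, R^2 = 0.632
```

Every planted cluster is recovered as one called TFCR; the region mix
reflects the planted distance mixture (≈45% promoter-proximal, ≈20%
long-range), and complexity correlates strongly with expression because
the generator plants a saturating log law between them.

The same analyses run from the shell:

```bash
tfcrkit simulate --seed 1 --n-genes 400 --panel --out panel/
tfcrkit run-panel --config config.yaml   # stage manifest + parameters
```

`run-panel` writes per-stage TFCR tables (BED6+ and TSV), link tables,
trajectory memberships, and a single `report.json` aggregating counts,
per-region correlations, gained/lost/stable dynamics, and TAD/PSTF
comparisons. Reruns with the same config are byte-identical.

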
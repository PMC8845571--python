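# gradientnet

Directed interaction networks, niche breadth and gene–taxon associations for
microbial communities along a soil-pH gradient.

## The problem

Aluminum becomes soluble (and toxic) as Al³⁺ in soils below pH ≈ 5, and the
bacteria that persist there carry recognisable Al-resistance genes.  Given a
continental survey of paddy soils — an OTU count table, a taxonomy, a
functional-gene array (Al-resistance and antioxidant probes with known source
genera) and per-sample chemistry — `gradientnet` answers, end to end:

1. **Who is Al-tolerant?**  OTUs whose genus matches a source organism of an
   Al-resistance probe.
2. **How do tolerant taxa depend on each other as acidity increases?**  The
   acidic samples (pH < 5.1) are arranged into a pseudo-series with equal
   ΔpH = 0.01 steps.  Treating pH as the "time" axis, each taxon's
   dependency is profiled by its noise color (power-spectrum slope: white ≈
   no dependency → pink → brown → black ≈ strongest), the series is screened
   for neutrality, and a sparse signed interaction matrix is inferred under
   the Ricker model

   x_i(t+1) = x_i(t) · exp( r_i + Σ_j A_ij x_j(t) + ε_i(t) )

   by bagged forward-stepwise ridge regression of the log-ratios
   ln x_i(t+1) − ln x_i(t) on the community state (a LIMITS-style
   procedure).  Nonzero off-diagonal entries A_ij ≠ 0 are directed edges
   j → i; each taxon is then **influential** (out-edges only), **sensitive**
   (in-edges only), **bidirectional** (both) or an orphan.
3. **Do the roles differ ecologically?**  Levins' niche breadth
   B_j = 1 / Σ_i P_ij² per OTU and its community mean (Bcom) per role and pH
   bin, with Duncan/Tukey letter groupings; plus Spearman-FDR gene–taxon
   networks (edges at r > 0.6, BH-corrected q < 0.01) and simple/partial
   Mantel tests linking community dissimilarity to gene profiles and
   environment.

Because the original survey data are not required, the package ships a
first-class synthetic-study generator (`gradientnet.synthetic`) that emulates
the survey's statistical structure — 13 regions × 3 fields × 11 subsamples =
429 samples over pH 3.6–8.7, Al³⁺ = a·e^(−b·pH)·ε, a planted sparse
interaction matrix driving the tolerant taxa along the acidic series, and
gene signals mixed from the taxa they are linked to — together with the
ground truth needed to score recovery.

## Worked example

```python
from gradientnet import SimulationConfig, run_synthetic_pipeline

result, truth = run_synthetic_pipeline(SimulationConfig(seed=1))

print("tolerant recovered exactly:", result.tolerant_ids == truth.tolerant_set)
print("inferred roles:", result.roles["role"].value_counts().to_dict())
print("neutrality:", result.neutrality.verdict, round(result.neutrality.pvalue, 3))
print("noise colors:", result.noise_profile["noise_type"].value_counts().to_dict())
a, b, r2 = result.al_fit
print(f"Al ~ {a:.0f}·exp(-{b:.2f}·pH), R² = {r2:.2f}")
```

prints (seed 1):

```
tolerant recovered exactly: True
inferred roles: {'sensitive': 4, 'influential': 4, 'bidirectional': 4}
neutrality: structured 0.02
noise colors: {'pink': 7, 'brown': 5}
Al ~ 10725·exp(-1.70·pH), R² = 0.59
```

Here the gene-based screen recovered the planted tolerant community exactly;
the pH series is classified as structured (so interaction inference is
warranted); every taxon shows non-white noise, i.e. successive pH steps are
not independent; and the fitted Al³⁺–pH exponential recovers the generator's
decay.  `result.roles` compared with `truth.true_roles` gives the
role-recovery rate (11/12 taxa at this seed).

The same stages are exposed on the command line:

```bash
gradientnet simulate --seed 1 --out study/
gradientnet identify --otu study/otu_table.tsv --tax study/taxonomy.tsv \
    --genes study/genes.tsv --meta study/metadata.tsv --out tolerant.txt
gradientnet series --otu study/otu_table.tsv --meta study/metadata.tsv \
    --max-gap 50 --out series/
gradientnet infer --series-file series/series.tsv --out network/
```

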
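# symbiospec

Community-scale analysis of specialization in lichen symbioses: which
cyanobacterial partners (*Nostoc* phylogroups) are available in a forest,
which ones each lichen-forming fungus (mycobiont) actually uses, and what
drives the difference — across forests spanning a wide latitudinal gradient.

The package is aimed at community ecologists working with marker-gene
genotyping of symbiont communities (e.g. *rbcLX* sequences of lichen
cyanobionts sampled thallus-by-thallus across sites). It covers the full
path from aligned sequences to inference:

1. **Phylogroup delimitation** — pairwise JC69 distances
   (`d = -(3/4) ln(1 - (4/3)p)`), threshold selection at the widest
   "barcode gap" inside a 0.001–0.01 substitutions/site band, single-linkage
   clustering.
2. **Interaction tables** — counts `n(f, i, j)` per forest `f`, mycobiont
   `i`, phylogroup `j`; availability `q_{fj} = Σ_i n(f,i,j) / Σ_{ij} n(f,i,j)`;
   inclusion filters (≥ 10 thalli regionally, ≥ 4 locally).
3. **Specialization metrics** per species and scope —
   partner richness; Simpson's index `D_i = Σ_j p_{ij}²`; the standardized
   Kullback–Leibler index `d'` with `d_i = Σ_j p_{ij} ln(p_{ij}/q_j)`
   rescaled to [0, 1]; bias-corrected Chao1 and exact (hypergeometric)
   rarefaction for sampling efficiency.
4. **Beta-diversity turnover** across scales —
   `β_total = β_repl + β_rich` on incidence sets, with each comparison
   classified as no turnover / nested / partial / total replacement.
5. **Composition drivers** — collinearity screening, redundancy analysis
   (RDA) of the forest × phylogroup matrix on climate and stand structure,
   variation partitioning via adjusted R² and inclusion–exclusion.
6. **Specialization drivers** — GLMMs with crossed random intercepts
   (forest, mycobiont species): Poisson for richness, Gaussian for
   ln Simpson and √d'; type-III Wald tests, Nakagawa R²m/R²c, VIF,
   Moran's I.
7. **Distributional ranges** — great-circle ranges of species and
   phylogroups, richness–range regression, partner-limitation screening.

A built-in synthetic community generator (environmentally filtered forest
pools, Dirichlet partner preferences, Jukes–Cantor sequence evolution)
provides ground truth for every stage, so the entire pipeline is testable
offline.

## Worked example

Each capability has a narrative script under `examples/`. Running
`python examples/02_delimit_phylogroups.py` prints:

```
sequences:            1366
selected threshold:   0.003341 substitutions/site
phylogroups found:    30
matches truth:        True
```

i.e. from 1366 simulated marker sequences the barcode-gap rule picks a
threshold of 0.0033 substitutions/site — just above the largest
within-phylogroup distance — and the resulting clusters coincide exactly
with the phylogroups the generator evolved the sequences from.

`python examples/06_mixed_models.py` fits the three driver models; for the
d' response it prints:

```
=== dprime (gaussian, transform=sqrt, n=222) ===
  R2 marginal 0.03 | conditional 0.64
  random variances: forest=0.0000, species=0.0088
```

The wide gap between marginal and conditional R² says that mycobiont
identity (the species random intercept), not the environment, explains most
of the variation in d' — specialization toward rare vs abundant partners is
a property of the fungus.

The same pipeline runs from the shell:

```bash
symbiospec all --seed 1 --out run1        # simulate + full analysis
symbiospec simulate --seed 7 --out data   # stagewise
symbiospec delimit  --seed 7 --out data
symbiospec metrics  --seed 7 --out data
```

Re-running any command with the same seed reproduces every output table
byte-for-byte. Real data can be supplied in the same formats: an aligned
FASTA with `|forest=<id>|species=<name>` header tags, a thallus TSV
(`thallus_id, forest, species, guild, repro_mode, phylogroup`), and a forest
metadata TSV (coordinates, elevation, canopy, DBH, bioclim variables).

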
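# oilcomm

Community-ecology inference for oil-amended marine microcosms.

When crude oil enters cold seawater, the resident bacterial community
reorganizes within days: obligate hydrocarbon degraders bloom and
decline, opportunists take over, and the choice of dispersant — a
synthetic formulation versus a biogenic surfactant such as rhamnolipid —
changes which taxa win. `oilcomm` implements the statistical chain used
to characterize such experiments from a 16S ASV table, a rooted
phylogeny, and a predicted gene-content matrix:

- **Diversity**: per-sample richness and Shannon entropy *H = −Σ pᵢ ln pᵢ*;
  Bray-Curtis, unweighted and weighted UniFrac distances; principal-
  coordinate analysis; two-factor PERMANOVA with sequential
  (adonis-style) sums of squares partitioning *SS_total = Σ_{i<j} d²ᵢⱼ/n*
  into treatment, time, and residual *R²* with permutation p-values.
- **LCBD**: each sample's local contribution to beta diversity,
  *LCBDᵢ = Gᵢᵢ / SS_total* from the Gower-centred matrix, with
  taxon-permutation inference.
- **Community assembly**: abundance-weighted MPD/MNTD and their
  standardized effect sizes NRI/NTI against a taxa-label randomization
  null (positive values = phylogenetic clustering = environmental
  filtering; the field's +2 threshold is reported, and a one-sample
  t-test checks whether replicate NTI values exceed it).
- **Drivers**: hierarchical best-subset OLS regression of scalar
  community properties on treatment/day indicators (AIC/BIC); a
  minimal-ASV subset search that greedily conserves beta diversity
  (Pearson *r* between subset and full Bray-Curtis matrices, default
  floor 0.95); Wilcoxon rank-sum differential abundance with
  Benjamini-Hochberg control and the log₁₀ ratio of group median
  proportions.
- **Taxa-function robustness**: the functional profile *F(c) ∝ cᵀG* of a
  composition under a genome-content matrix *G*; random
  removal/replacement perturbations; and attenuation *α = 1/s* from the
  through-origin fit *f = s·t* of functional shift on taxonomic shift —
  higher α means the community's function resists taxonomic disturbance.
- **Chemistry**: hydrocarbon biomarker ratios from GC peak areas
  (Pr/nC17, nC18/Ph, P/9MP, methylphenanthrene composites) and Welch
  tests of their change through incubation time.
- **Synthetic experiment generator**: Yule phylogenies, phylogenetically
  structured genome content with a tunable core-function (redundancy)
  fraction, treatment×time count tables with environmental filtering,
  responder-clade blooms, planted driver taxa, and Dirichlet-multinomial
  noise — every analysis stage has planted ground truth to recover.

## Worked example

Simulate the default microcosm design (6 treatments × 5 days × 3
replicates + 1 in-situ baseline = 91 samples, 300 taxa, 500 gene
families) and run every stage:

```bash
oilcomm run --out demo_run --seed 7
```

or equivalently from Python:

```python
from oilcomm import RunConfig, run_all
manifest = run_all(RunConfig(out_dir="demo_run", master_seed=7))
print("\n".join(manifest["summary"]))
```

which prints (abridged):

```
PERMANOVA treatment: R2=0.381 p=0.005
PERMANOVA day: R2=0.047 p=0.005
NTI BEWAF: mean=2.52 P(mean>2)=0.0125
NTI CEWAF: mean=3.06 P(mean>2)=2.87e-09
NTI FSC: mean=1.16 P(mean>2)=nan
NTI SW: mean=1.42 P(mean>2)=0.994
driver subset (CEWAF): size=63 r=0.943 PERMANOVA(time) R2=0.563 p=0.005
differential abundance CEWAF vs WAF: 138 taxa at q<0.05
attenuation WAF day 28: alpha=10.19
attenuation BEWAF day 28: alpha=11.14
Pr/nC17 BEWAF d14->d28: diff=+1.304 p=0.00954 (more alkane biodegradation)
```

Reading this: treatment explains 38% of the Bray-Curtis variance
(permutation p = 0.005 at 199 permutations); the oil- and
dispersant-amended communities are phylogenetically clustered (mean NTI
above +2, significantly so for CEWAF), while the in-situ baseline and
seawater control are not; a 63-taxon subset reproduces the CEWAF
beta-diversity structure at r = 0.94; and the planted late acceleration
of alkane degradation in the biosurfactant treatment shows up as a
significant rise in the pristane/heptadecane ratio between days 14
and 28.

Each subcommand (`simulate`, `diversity`, `phylo`, `drivers`,
`diffabund`, `robustness`, `chemistry`) runs its stage alone on TSV /
newick inputs; `oilcomm run --config run.yaml` drives everything from a
YAML config, and a master seed makes the whole run bit-reproducible.

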
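# mirwaves

Developmental small-RNA expression analysis for hemimetabolan insect
ontogeny: read-to-miRNA quantification, 3′-end nontemplated tail profiling,
stage-wise differential expression, Spearman-threshold coexpression modules
with SVD metagenes, and cross-species miRNA-family comparison.

## Who this is for

Small-RNA biologists studying how miRNA expression is organised across
embryonic and post-embryonic development — in particular designs like the
German cockroach *Blattella germanica* ontogeny series: 11 stages
(non-fertilized egg NFE; embryo days ED0, ED1, ED2, ED6, ED13; nymphal
instars N1, N3, N5, N6; adult) with 2 replicate libraries each. The package
ships a synthetic-data generator that emulates that design with a known
ground truth, so every stage of the analysis can be validated by parameter
recovery before it touches real data.

## The methods at the core

* **Quantification.** Reads of 16–29 nt are assigned to annotated mature
  miRNAs by exact templated-prefix matching (5′ end within ±2 nt of the
  annotated mature, ≤5 nt of untemplated 3′ residue; multi-matching reads
  split 1/k). Counts are normalised as counts per million (CPM); family
  expression is the sum of member CPM, with families defined by the seed
  (mature positions 2–8).
* **3′-tail profiling.** The untemplated residue of each assigned read is
  classified: equal to the genomic continuation → templated extension (not a
  modification); all-A → adenylation; all-U → uridylation; else other. The
  per-library modification frequency is n_modified / n_assigned.
* **Differential expression.** Median-of-ratios size factors
  s_ℓ = median_g (K_gℓ / (∏_ℓ K_gℓ)^(1/L)), a method-of-moments NB
  dispersion α̂_g = max(0, Σ_c(s²_gc − μ̄_gc) / Σ_c μ̄²_gc) with one-sided
  shrinkage toward the across-gene mean, and a Wald test on
  log2FC = log2((μ̄_B + ½)/(μ̄_A + ½)) with the delta-method SE from
  Var(K) = μ + αμ², Benjamini–Hochberg adjusted (significant at q < 0.05).
* **Coexpression.** Tie-corrected Spearman ρ over the 11 stage-mean CPM
  profiles; genes are connected where ρ > 0.9 (strict), modules are
  connected components (≥3 genes), and the largest module is re-thresholded
  at ρ > 0.925 to resolve submodules. Each module's metagene is the first
  right singular vector of the z-scored member × stage matrix, oriented to
  correlate positively with the mean member profile.
* **Cross-species comparison.** Family-level CPM sums restricted to families
  present in every species, converted to relative abundance, then average-
  linkage clustering on 1 − Pearson distance and PCA over
  log10(proportion·10⁶ + 1), with the top-|loading| families reported as the
  drivers.
* **Developmental time.** Stages are aligned across species as percent of
  embryo development, 100·h/432 for an 18-day embryogenesis at 29 °C.

## Worked example

```python
from mirwaves import comparative, coexpression as cx, quantify as qt, simulate as sim

# developmental-time model: hours after oviposition -> % development
model = comparative.StageModel()
model.percent("ED0", 2), model.percent("ED2"), model.percent("ED6"), model.percent("ED13")
# (1.85, 11.0, 33.0, 72.0)

# simulate the 11-stage x 2-replicate design and recover the planted waves
counts, truth = sim.simulate_counts(sim.SimConfig())
profiles = cx.stage_means(qt.cpm_normalize(counts))
rho = cx.spearman_matrix(profiles)
network = cx.build_network(rho, 0.9)
for m in cx.find_modules(network):
    print(m.module_id, len(m.members))
for s in cx.split_largest(network, rho, 0.925):
    print(s.module_id, len(s.members))
```

prints

```
CoMod-1 40
CoMod-2 20
CoMod-3 20
CoMod-4 12
CoMod-1.1 20
CoMod-1.2 20
```

— four coexpression modules: the largest (40 genes) holds both early-embryo
waves and splits at the 0.925 cut-off into the ED0–ED1 wave (A1, 20 genes)
and the ED0–ED6 wave (A2, 20 genes); the other three are the acute ED2
spike, the post-embryonic wave, and the maternally loaded genes. Against the
generator's truth the module assignment has adjusted Rand index 1.0.

The same analysis runs end-to-end from the shell:

```
mirwaves all --outdir run1            # simulate -> quantify -> DE -> network -> compare
mirwaves simulate --outdir sim --fastq
mirwaves network --cpm cpm.tsv --threshold 0.9 --sub-threshold 0.925 --out-dir net
```

Each run directory contains the effective config and a manifest with
SHA-256 checksums of every output; rerunning with the same config
reproduces them byte for byte.

## Layout

```
src/mirwaves/
  stages.py        shared 11-stage design constants
  simulate.py      synthetic genome/annotation/counts/reads + ground truth
  catalog.py       miRNA gene models, biogenesis filter, families, clusters
  quantify.py      read assignment, tails, CPM, families, length histograms
  diffexp.py       size factors, NB dispersion + Wald test, BH-FDR
  coexpression.py  Spearman network, modules, metagenes, CV, Welch test
  comparative.py   % development, shared families, clustering, PCA drivers
  pipeline.py      end-to-end orchestration with manifest + checksums
  cli.py           `mirwaves` command-line interface
docs/methods.md    model assumptions, parameter choices, limitations
```
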
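# Methods

This note documents the models behind `mirwaves`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want to know about.

## Study design

All modules share one design constant: eleven developmental stages in fixed
order — NFE (non-fertilized egg), ED0, ED1, ED2, ED6, ED13 (embryo days),
N1, N3, N5, N6 (nymphal instars), Adult — with two replicate libraries per
stage (`STAGE_rep1/2`). The developmental-time model places the embryonic
stages at 8, 24, 48, 144 and 312 h after oviposition on an 18-day (432 h)
embryogenesis, so percent of development is 100·h/432: ED0 ≈ 1.85–2%,
ED1 ≈ 6%, ED2 ≈ 11%, ED6 ≈ 33%, ED13 ≈ 72%. The total duration is
configurable per species; percent development is linear in hours and
unit-scale invariant.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is validated against.

**Expression waves.** Five peak-normalized 11-stage templates: maternal
(NFE-loaded, decaying through ED1, small adult bump — maternally deposited
miRNAs that reappear in the adult female ovary), A1 (early embryo, peak
ED0–ED1), A2 (mid-embryo, peak ED1–ED2 extending to ED6), B (acute ED2
spike, decaying after), C (post-embryonic ramp). Templates are defined by
*stage ranks* with geometrically spaced values (factor 1.7 between
consecutive ranks). Two properties were designed in once, by rank
arithmetic, and are load-bearing:

1. Spearman(A1, A2) = 1 − 6·20/1320 = 0.9091, strictly inside (0.9, 0.925]:
   A1 and A2 genes merge into one module at the 0.9 network cut-off and
   separate at the 0.925 submodule cut-off.
2. Every other template pair is far from both cut-offs (0.84 at the
   closest, B vs A2).

The 1.7× spacing makes a rank flip of a gene's stage means a ≥3σ event at
the default noise level, so empirical gene–gene correlations concentrate
tightly on the template values. Across 50 arbitrary seeds the full
4-module + A1/A2-split recovery succeeded 49 times (one seed produced a
single cross-pair above 0.925 and the largest module failed to split); the
default fixture seed is part of the fixture definition and recovers
perfectly.

**Default fixture (157 genes).** Wave sizes maternal 12, A1 20, A2 20, B 20
(including 4 MIR-309-like paralogs — the ED2-spike family), C 20, plus 65
background genes; provenance mix 88 conserved / 11 previously described /
58 newly discovered, matching the catalog. Background genes get independent
lognormal stage wiggles (σ = 0.35), so their pairwise rank correlations are
null and they stay isolated in the network.

**Counts.** Per-gene stage mean = scale_g · template(stage) with
scale_g ~ lognormal(0, 0.6). Stage totals are held constant by construction:
the background pool absorbs the stage-dependent wave mass (the wave genes
peak at 30% of the library), playing the role of the highly expressed
conserved miRNAs that dominate real libraries. Without this, per-stage
normalisation warps every gene's effective profile by a shared stage factor
and the designed rank bands do not survive. Replicate counts are
NB(mean · size factor, α) with per-library size factors lognormal(0, 0.05);
α = 0 degenerates to Poisson. Default dispersion α = 0.02 — the libraries
this emulates are pooled-specimen preparations whose replicate variability
is close to technical; a library-scale default of 10⁶ counts makes even the
smallest template values well covered (≳30 counts).

**Reads.** Default 10⁵ reads per library (the real libraries carry millions
of reads; 10⁵ keeps every binomial recovery bound comfortably tight while
the whole 22-library simulation stays in seconds — the problem size used
throughout the tests and the acceptance script). miRNA reads are the mature
sequence (20% are 3′-trimmed by 1 nt); piRNA-like decoys are 27–29-nt
genomic fragments from loci ≥40 bp away from any precursor, at
stage-dependent fractions (0.50 at ED0–ED1 where the relative miRNA share
dips, 0.25–0.35 elsewhere; these fractions are free parameters — the source
data show them only graphically). A stage-dependent fraction of miRNA reads
carries a 1–3 nt nontemplated tail: rates default to 0.20 at ED0–ED1
(inside the observed 15–26% early-embryo band) and 0.09 elsewhere (inside
7–11%), with composition 50% adenylation, 25% uridylation, 25% other.

**Forced mismatch.** The toy annotation sets the genomic base immediately
downstream of every mature 3′ end to C, so A- and U-tails can never be
genome-templated; "other" tails start with G for the same reason.
Templated-extension ambiguity is therefore absent from generated data by
design and is exercised by a dedicated fixture instead.

**Toy annotation.** Hairpins are flank + 21–23-nt arm + 15-nt loop +
reverse-complement arm + flank; the mature occupies one arm and the star is
the other arm shifted so both duplex ends carry the canonical 2-nt 3′
overhang under the symmetric fold p(i) = N−1−i. The default catalog has 166
gene models: 63 new genes (three triplets and three pairs share identical
matures → 54 distinct; six further pairs share a seed → 48 families), a
4-gene MIR-309-like cluster, and 43 of the new genes in nine clusters of
2–10 genes spanning ~8–70 kb.

**What the generator does not emulate.** No sequencing errors, no adapter
remnants, no 5′ isomiR shifts, no mismatch between the catalog and the
genome, no piRNA biology beyond the 28-nt length peak, and no
compositional drift between miRNA and non-miRNA classes beyond the decoy
fractions. Passing recovery tests therefore demonstrates the correctness of
the analysis logic under its stated assumptions, not robustness to
alignment noise or annotation error in real libraries.

## Quantification

Assignment is exact templated-prefix matching: a read is assigned to a
mature when its prefix matches the genome starting within ±2 nt of the
annotated mature 5′ end, with ≥16 templated nt and ≤5 nt of 3′ residue.
There is deliberately no mismatch-tolerant alignment. Reads matching k > 1
distinct matures contribute 1/k to each (per-read weights always sum to 1);
identical matures encoded by paralogous genes are one expression unit.
The CPM denominator is miRNA-assigned reads, not raw library size: decoy
(non-miRNA) reads vary by stage and would otherwise distort stage
comparisons. A 3′ residue equal to the genomic continuation counts as
templated extension, i.e. unmodified — the conservative reading of
"nucleotides beyond the annotated 3′ end"; `count_templated_extensions`
flips it.

## Differential expression

A deliberately explicit re-implementation of the standard NB pipeline,
not a wrapper: median-of-ratios size factors (reference = per-gene
geometric mean over libraries, genes with any zero excluded; the median is
taken over plain ratios, so scaling one library by c scales its factor by c
relative to the others), a moment dispersion estimate pooled over stages
with replicates, and a Wald test with delta-method SEs and a 0.5
pseudocount on the fold change (stability at two replicates).

One estimator choice deserves its own paragraph: the dispersion shrinkage
is **one-sided** — α_g = ᾱ + ½·max(α̂_g − ᾱ, 0), where ᾱ is the across-gene
mean of the raw moment estimates. With two replicates the raw estimate has
about one degree of freedom per stage; symmetric shrinkage leaves half of
the genes claiming less-than-typical dispersion, and their Wald statistics
are overconfident (empirical type-I error 0.07–0.10 at nominal 0.05 in null
simulations). Flooring at the mean restores calibration (0.039–0.065 across
null seeds at α = 0.1, 1000 genes, 2 + 2 replicates) at a small cost in
power for genuinely quiet genes. Calibration is a statistical guarantee,
verified by simulation, not an exact one.

BH adjustment is the textbook step-up with monotonicity enforcement,
applied per transition; significance is q < 0.05.

## Coexpression

Correlations are computed over the 11 replicate-averaged stage means, not
the 22 libraries: the module metagenes are stage profiles, and averaging
suppresses replicate noise at n = 2. Both cut-offs are strict (ρ > 0.9,
ρ > 0.925); anticorrelated pairs are never connected. Minimum module size
is 3 (dyads are noise at this scale; configurable). Constant profiles get
ρ = 0 against everything, with a warning, instead of propagating NaN.
Metagenes z-score each member profile across stages before the SVD so the
first singular vector reflects shape rather than magnitude
(`standardize=False` gives the raw-CPM SVD; in the exact rank-1 case the
raw metagene equals the common profile direction, which is how the
rank-one property is tested). The sign is oriented against the mean member
profile; the vector has unit norm. The expression CV uses the sample
(n−1) standard deviation over the 11 stage means; zero-mean genes are
excluded with a warning. Welch's t-test (scipy) compares CV distributions
between provenance groups.

## Cross-species comparison

Only families with nonzero expression in every species are retained.
Proportions are log-transformed as log10(p·10⁶ + 1) before clustering and
PCA — the abundance distribution is heavy-tailed and the transform keeps a
handful of dominant families from owning every distance (the source
analyses do not state their transform; this is a package choice, as are
average linkage and 1 − Pearson distance, both flag-switchable). PCA driver
families are the top-n by |PC1 loading| with |PC2| breaking ties — an
operationalization of "main drivers of the clustering"; component signs
are fixed by requiring the first library's score to be non-negative.

## Pipeline

One JSON config document drives simulate → quantify → diffexp → network →
compare; unknown keys are rejected, validation errors are aggregated, and
normalisation is idempotent. Every run directory gets the effective config
and a manifest of SHA-256 checksums; all randomness flows from the single
config seed through `numpy.random.SeedSequence`, so reruns are
byte-identical. On failure the offending stage is named and a `failed/`
marker is left beside the partial outputs.

## Known limitations

* Exact-match assignment is only appropriate for data whose reads derive
  from the supplied genome without errors; real libraries need an upstream
  aligner and adapter/quality preprocessing.
* The NB machinery is intentionally simple: no trended dispersion fits, no
  outlier handling, no covariates, no shrunken fold changes. With two
  replicates its power is modest and its dispersion estimates lean heavily
  on the across-gene mean.
* The coexpression cut-offs (0.9/0.925) are taken as given, and the module
  recovery guarantees hold for the generator's noise regime; noisier data
  can fragment modules or blur the A1/A2 band (observed on 1 of 50 seeds).
* Family orthology across species is input metadata; no ortholog inference
  is performed.
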
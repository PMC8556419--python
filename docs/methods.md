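# Methods

`introseek` detects archaic (Neanderthal-/Denisovan-like) introgressed
segments in phased modern-human genomes, assigns each segment to an
ancestral lineage, and reconstructs multi-wave introgression history from
the tract-length distribution. This note records the models, the
numerical choices, and what the synthetic testbed does and does not
emulate.

## Detection model

### Observation states

Every biallelic SNP, polarized to ancestral/derived against an outgroup,
is classified per test haplotype into four states:

1. **test-population-specific** — derived on the test haplotype, absent
   from the archaic and African reference panels;
2. **archaic marker** — derived shared with at least one archaic
   reference haplotype but with no African;
3. **AMH marker** — derived shared with an African but with no archaic
   reference;
4. **common** — everything else, including sites where the test
   haplotype carries the ancestral allele.

Missing reference genotypes are treated as uninformative (the affected
comparison is skipped, never imputed).

### HMM

Hidden states are AMH (0) and archaic (1) local ancestry. For two
adjacent SNPs separated by `d` Morgans the pulse-admixture transition
model is

    P(0→1) = α (1 − e^{−T d}),    P(1→0) = (1 − α)(1 − e^{−T d}),

whose stationary distribution is `(1−α, α)`; `α` is the introgression
proportion and `T` the introgression time in generations. Defaults
`α₀ = 0.02`, `T₀ = 2000` start the EM; the fit is insensitive to these.

**Emission initialization.** Both rows start at the genome-wide observed
state frequencies; the two *cross-diagnostic* entries —
e(AMH marker | archaic) and e(archaic marker | AMH) — are down-weighted
by `(1 − ε)` with `ε = 0.99` and rows renormalized. `1 − ε` is thus the
relative rate at which a diagnostic marker appears on the wrong ancestry
background (incomplete lineage sorting, reference-panel sampling), and
each diagnostic state starts with a 100-fold likelihood contrast. An
alternative parameterization that puts `ε`-scaled mass directly on the
diagnostic entries leaves the two rows nearly identical at realistic
marker frequencies and collapses the EM to a degenerate symmetric
solution, so it was rejected.

**Constrained EM.** Per iteration the six free emission entries get the
exact multinomial M-step; the two cross-diagnostic entries stay frozen
at their initial values (they govern false crossover of diagnostic
markers, and freezing them keeps the false-detection rate down). `α` is
updated to the mean posterior archaic mass and `T` to the number of
ancestry switches on the MAP (Viterbi) paths divided by
`2α(1−α) × total map length` — the moment identity for the expected
junction density under pulse admixture. The MAP switch count is used
deliberately instead of the posterior junction expectation: the latter
is dominated by micro-flicker at isolated diagnostic sites (each
spurious archaic marker contributes posterior mass for a transient
archaic visit), which runs `T` several-fold above the tract scale,
shortens the HMM's memory `~1/T` Morgans, and fragments decoded tracts
across marker-poor stretches. Because the `α/T` step is moment-style
rather than an exact M-step, it is accepted only when the pooled
log-likelihood does not decrease (generalized-EM safeguard); the
emission step alone can never decrease it, so the recorded
log-likelihood trace is non-decreasing by construction. Convergence:
relative log-likelihood change < 1e-5, max 200 iterations; `α` clamped
to [1e-6, 0.5], `T` to [1, 1e5]. `T` is a segment-scale nuisance
parameter, not the dating estimate; dating comes from the tract-length
fit downstream.

**Decoding.** Viterbi (deterministic and reproducible); maximal archaic
runs become segments. A boundary between two adjacently decoded states
is placed at the midpoint of the flanking SNP pair, rounded toward the
shorter archaic segment; runs touching the first/last site end at that
site. Mean forward–backward posteriors are attached per segment.
Posterior-threshold decoding was considered and rejected: it requires an
arbitrary threshold and produces ragged fragment edges, while boundary
placement between informative flanking SNPs is what the tract-length
analysis downstream needs.

## Lineage matching

The reference phylogeny is the clock tree
`(outgroup, (AMH, (archaic₁, archaic₂)))` parameterized by three node
depths in expected substitutions per bp (one-way). Calibration fits the
depths by least squares to genome-wide mean pairwise difference
densities between role groups (the expected density between two leaves
is twice their MRCA depth), with the root set on the outgroup edge;
non-nested estimates are clamped. A few haplotypes per group suffice for
these genome-wide means.

Each candidate segment's profile — mismatch count and callable bp
against the *nearest* haplotype of each group — is matched against seven
origins: the two archaic terminal edges, the archaic-ancestor node, the
internal "unknown archaic" edge, the AMH terminal edge (false positive),
the AMH/archaic ancestor node (ILS), and the rootward edge. Counts are
modeled as independent Poisson with mean `2 × depth × callable bp`. Two
parameters are profiled per placement: the attachment depth `t` on the
edge and a **per-segment terminal nuisance length `c` added to every
expected distance**. `c` absorbs segment-lineage-specific excess
divergence — private variants and ancestral alleles lost in the single
sequenced reference genomes — which otherwise inflates all of a
segment's distances symmetrically and masquerades as deep divergence;
without it, genuinely asymmetric (lineage-diagnostic) profiles leak into
the unknown-archaic placement. Given `c` the depth MLE is closed-form,
so the profile likelihood is maximized on a refined 1-D grid over `c`.
Exact ties go to the more rootward (more conservative) placement.

The split time to the matched reference is `t/μ` generations
(`μ = 1.25e-8` /bp/generation by default), reported in kya with a 30-year
generation time. Segments labeled ILS or false positive are excluded
from history fitting.

## Introgression history

Surviving tract lengths from a pulse `t_k` generations ago are
exponential in genetic length with rate `u_k = t_k (1 − α_total)` per
Morgan; a K-pulse history gives a K-component mixture. Because segments
shorter than 15 kb are removed before fitting (their boundaries are
dominated by detection noise), the mixture is left-truncated: by
memorylessness the shifted lengths remain exponential with the same
rates, but the observed component weights are biased by the survival
factors `e^{−u_k c}` and are corrected back before converting to
admixture proportions `m_k ∝ w_k / u_k` (scaled to the lineage's
genome-wide ancestry fraction). Ignoring the truncation biases the time
estimates low by ~25% at the default scale.

Two detection-aware preprocessing steps: same-haplotype segments
separated by less than the 15-kb floor are merged (a marker desert
splitting one long tract otherwise biases wave times up), and, when more
than one wave is selected, waves with proportion < 0.5% and bootstrap
support < 0.5 are screened out and the model refitted — small, unstable
extra waves are a known artifact of segment-detection error.

EM details: 10 random restarts (quantile-spread rate initialization with
jitter), tolerance 1e-8, up to 2000 iterations — exponential mixtures
keep drifting in parameter space well after the log-likelihood change
falls below looser thresholds, which biased the fast rate upward ~15%
at tolerance 1e-6. Wave number is chosen by a forward likelihood-ratio
test, `2ΔlogL ~ χ²(df=2)` at 0.05 (one extra time plus one extra
proportion), with K+1 only attempted when at least `10(K+1)` tracts are
available. Uncertainty: percentile bootstrap over tracts with
re-selection of K; the support ratio is the fraction of resamples
choosing each K. Times convert to kya with 30 years per generation.

## Population statistics

Decoded segments reduce to piecewise-constant local-frequency tracks.
Coverage counts bp with frequency strictly above 0.02. The
ancestry-sharing ratio `S_ij = Σ_k p_ik p_jk L_k / (P_i P_j L)` is
evaluated exactly on the refinement of both tracks' breakpoints (no
binning); `S_ii ≥ 1` by Cauchy–Schwarz with equality iff the track is
uniform. Deserts: 100-kb bins of introgression-covered length (union
over populations), two-tailed empirical test at 0.05 — a desert is a
maximal run of bins below the lower 2.5% quantile of the bin
distribution, classified at > 5 Mb and > 10 Mb; the tested bin is not
excluded from the null distribution (with thousands of bins the
distinction is negligible). Introgression diversity is the mean union
length of segments over random haplotype subsamples (10,000 permutations
by default; the full-sample point is deterministic).

## Archaic alleles and enrichment

A derived allele on an inferred archaic segment is archaic with
probability

    P(A) = [p_d^M (1−p) + (1−p_d^M)] · [p_d^Afr m α + (1−p_d^Afr)]

where `p_d^M` is its frequency on inferred modern-human sequence,
`p_d^Afr` its African frequency, `p` the detection power (default 0.9,
near the measured TPR), `m` the back-flow admixture proportion into
Africa and `α` the archaic ancestry proportion (`m`, `α` are data-set
properties with no pretend defaults). The allele is called when
`1 − P(A) < 0.05` (strict).

LD loci are built by greedy left-to-right clustering on phased
haplotypes: a site joins the nearest cluster whose representative tags
it at `r² > 0.8` within 500 kb, else founds a singleton. Enrichment per
tissue compares the gene-expression-associated (GEA) proportion of
archaic loci against 100 random non-archaic locus sets matched on
representative-allele frequency in 1% bins (archaic loci are represented
by an archaic allele, preferentially an eQTL); draws with zero GEA
controls are redrawn. One-sided empirical p-values are
Benjamini–Hochberg-corrected across tissues.

## Synthetic testbed

The generator lays archaic tracts as a Poisson process (starts at
density `m_k u_k` per Morgan, exponential lengths) and paints mutations
site by site as independent Poisson classes tied to the branches of

    outgroup —(6.5 Mya)— (AMH —(700 kya)— (unknown? —(T_split)— (archaic₁ —(450 kya)— archaic₂)))

with `μ = 1.25e-8`, `r = 1e-8` (1 cM/Mb), 30-year generations, African/
non-African split 80 kya, reference-vs-source population split 120 kya.
Crucially, each tract draws its own *lineage* divergence from the
sampled reference: population split plus `Exp(2 Nₑ)` within-population
coalescence (`Nₑ = 3000`), reproducing the ~300-kya mean divergence
between the sequenced references and introgressing lineages — tract
informativeness therefore varies realistically, and marker-poor tracts
are the ones detection misses.

Segregating-polymorphism layers: shared modern-human polymorphism
(density 1.5e-3/bp), African-private (2e-4), test-private (1e-3, so each
test haplotype carries ~1e-4/bp derived alleles invisible to a modest
African panel — the observed non-African rare-variant load), archaic
reference heterozygosity (1e-4 per haplotype), and ancestral (ILS)
polymorphism (5e-4) carried by both archaic lineages (p=0.5), one
lineage (p=0.3 split evenly), or — with p=0.2 — retained by the
introgressing source but *lost in the single sequenced reference
genomes*. Allele frequencies follow a `1/f` spectrum on [0.02, 0.98].
The ILS classes produce both the spurious archaic markers that drive
false positives and the AMH-marker/test-specific sites inside true
tracts that limit power. The African reference panel defaults to 40
haplotypes; panel size directly sets the survival rate of spurious
archaic-marker patterns, and this value reproduces the published
operating point of the detector.

Outgroup-branch mutations are emitted (the outgroup carries the derived
allele), so polarizing by outgroup mis-polarizes them into universally
"derived" common sites, as in real data.

What the testbed does **not** emulate: true coalescent genealogy
(mutation classes are independent Poisson layers, so linkage between
nearby sites is only what the tract structure induces), recombination
within reference panels, phasing or genotyping error, selection, and
continuous migration. Passing benchmarks therefore demonstrates correct
method behavior under the stated marker-sharing structure, not
performance on any particular real cohort.

## Benchmark scales

Reduced problem sizes keep the full benchmark reproducible on a
laptop-class machine: detection replicates use 10 Mb × 20 test
haplotypes (20 seeded replicates), the unknown-lineage grid 40 Mb × 20,
and the two-wave grids 50 Mb × 32 (roughly 400–900 filtered tracts per
scenario, enough for the likelihood-ratio test to resolve well-separated
wave pairs; the close-in-time, one-dominant-wave scenarios are retained
as the expected failure mode). The 144-scenario grid is an approximate
reconstruction of the published families (36 one-wave, 48 two-wave
one-lineage, 36 two-wave two-lineage, 24 unknown-lineage with T_split up
to 610 kya).

## Known limitations

- The painted-mutation testbed is slightly easier than a full
  coalescent for known-lineage detection (fewer chance clusters of
  spurious archaic markers): measured precision runs ~3 points above,
  and FPR ~2× below, the published medians, while TPR matches.
- The per-segment split-time estimate inherits the nuisance-length
  degeneracy on the free edge; estimates are upward-biased by roughly
  the segment's private-variant load when the fixed-edge groups do not
  fully identify `c`.
- Diploid archaic references are treated as two haplotypes and the
  nearest one is used per comparison; no explicit genotype-likelihood
  handling for low-coverage archaic genomes.
- One chromosome per panel; multi-chromosome inputs are analyzed per
  chromosome and pooled downstream.
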
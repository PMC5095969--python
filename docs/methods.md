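# Methods

This note documents the statistical procedures, parameter defaults and
numerical choices behind `epimsap`, and what the synthetic-data generator
does and does not emulate.

## MSAP scoring and summary statistics

Each MSAP locus in each individual is a pair of presence bits from the
EcoRI/HpaII and EcoRI/MspI digests. HpaII is blocked by any methylation of
the CCGG site, MspI only by external-cytosine methylation, so the pairs
map bijectively onto four states: (1,1) unmethylated (type I), (1,0)
hemimethylated (type II), (0,1) internal-CG methylated on both strands
(type III), (0,0) fully methylated (type IV). Lane order is the standard
MSAP convention (first HpaII, then MspI).

Each CCGG site samples four cytosines (two per strand). Types II and III
carry two methylated cytosines, type IV four, giving

    %mC = 100 · (2 nII + 2 nIII + 4 nIV) / (4 (nI + nII + nIII + nIV)).

The hemi/internal/full partition divides nII, nIII, nIV by the methylated
total m = nII + nIII + nIV. Percentages are computed in double precision
and rounded only for presentation (half-up, 2 decimals; integers in
summary echoes).

Two interpretive choices are deliberate and configurable:

* **Type IV counts as methylated** both in %mC (where the formula assigns
  it four methylated cytosines) and in MSL selection. A (0,0) pattern can
  also reflect restriction-site loss; `select_msl(type_iv_as_missing=True)`
  drops it from numerator and denominator instead.
* **"Methylated in at least 5 % of individuals"** is read as the fraction
  of non-missing individuals per locus carrying a methylated state, the
  convention of the standard MSAP analysis packages. Both the 5 %
  threshold and the ≥ 2-unmethylated-individuals polymorphism rule are
  parameters.

Missing cells are excluded from both the numerator and the denominator of
every locus-level fraction.

`check_uniformity` flags any non-constant column of a dominant band
table; it is used to verify that AFLP profiles are identical across
individuals before attributing variation to methylation.

## Binary encoding, distances, PCoA

Polymorphic MSL are recoded 0 (type I) / 1 (types II–IV), a dominant
binary marker matrix. Pairwise distance is Euclidean over the loci shared
(non-missing) by a pair, rescaled by √(L / L_shared) so that squared
distances extrapolate to the full panel; identical profiles give 0, and a
pair with no shared loci is an error. The underlying distance metric of
the original MSAP tooling is not documented anywhere we could follow, so
this choice is stated rather than inferred; it is Euclidean when data are
complete and only approximately Euclidean under rescaling.

PCoA is Gower's classical scaling: double-center −D²/2, eigendecompose
(symmetric solver), scale eigenvectors by √λ. Variance-explained
fractions are taken over positive eigenvalues only; negative eigenvalues
(possible with missing-data rescaling) are excluded from the denominator
and reported as diagnostics. Eigenvalues below max(|λ|)·1e-12 are treated
as zero. Requesting more axes than there are positive eigenvalues
truncates with a warning. For a Euclidean input the embedding over all
positive axes reproduces the input distances to ≤ 1e-9, which the test
suite asserts.

## AMOVA

The one-level analysis of molecular variance operates on squared
Euclidean distances:

    SS_total  = Σ_{i<j} d²_ij / N
    SS_within = Σ_g Σ_{i<j ∈ g} d²_ij / n_g
    σ²_within = SS_within / (N − G)
    σ²_among  = (SS_among/(G−1) − σ²_within) / n0,
                n0 = (N − Σ n_g²/N) / (G − 1)
    Φst       = σ²_among / (σ²_among + σ²_within)

Negative Φst values (expected under the null) are reported as computed,
not clamped. The p-value is the upper-tail permutation probability
p = (#{Φ* ≥ Φ} + 1)/(B + 1) over B random relabelings with fixed group
sizes; B defaults to 9999 (p resolution 10⁻⁴) and the generator is
seeded, so a fixed seed gives byte-identical results. Every group must
have ≥ 2 members. When σ²_among + σ²_within ≤ 0 (degenerate all-identical
input) Φst is defined as 1 if σ²_among > 0 and 0 otherwise.

Two independent checks back this implementation: an oracle computing the
same decomposition from centroid sums of squares (coordinates rather than
distances) on all small group layouts, and a null calibration showing the
rejection rate at α = 0.05 is 0.05 ± 0.02 over 600 simulated datasets
(12 individuals, 30 loci, 199 permutations each — sizes chosen so the
whole suite runs in seconds on one CPU).

## Phenotype statistics

The outlier screen mirrors the field's practice for mutagenized
populations: per-individual one-sample Z-test against the control mean
and *sample* standard deviation (n−1), two-sided, with no multiple-testing
correction by default (a Benjamini–Hochberg flag is provided).
Trait-specific direction labels map the tails to early/late flowering and
small/large rosette. A degenerate baseline (sd = 0) is an error rather
than a silent infinity.

`wilcoxon_rank_sum` dispatches to exact enumeration when
min(n₁, n₂) ≤ 10 and the pooled sample is tie-free, otherwise to the
normal approximation with continuity and tie correction; the two paths
agree within 0.01 in p on tie-free samples of size 8–10.
`proportion_chi_square` is the 2×2 Pearson statistic without continuity
correction (df = 1); a zero margin is an error. `expected_homozygosity(g)
= 1 − (1/2)^g` is the single-seed-descent fixation expectation, strictly
increasing and bounded by 1 (g = 8 gives 0.9961).

## Variant filtering

Four rules, all parameters exposed: (a) evidence — ≥ 3 alternate-
supporting reads in at least one sample (a total-depth mode exists for
callers that only report DP); (b) site quality strictly > 3000 (site
QUAL, not genotype quality); (c) indel adjacency — a SNP within w bases
of an indel of length w is removed, measuring from the SNP position to
the nearest edge of the indel's affected interval [pos, pos + w],
1-based inclusive, with positions inside the interval at distance 0;
(d) shared genotype — sites where every sample carries one identical
genotype are uninformative for treatment contrasts. Indel records
themselves are never emitted; they are tallied in their own rejection
bin. A record failing several rules is attributed to the first failing
rule in the order quality, evidence, indel-adjacency, shared-genotype
(reporting only). Filtering is idempotent and order-independent, and
every input record is accounted for exactly once.

Genotype classes are assigned with the precedence uniform-alternate →
multi-allelic (treated-only before shared) → heterozygous-any →
treated-exclusive homozygous-alternate → unclassified (missing
genotypes). Placing heterozygous above treated-exclusive keeps the two
headline classes disjoint, matching how such partitions are reported;
multi-allelic outranks heterozygous because the extra-allele observation
is the rarer, more specific event.

## CpG islands

Criteria: length ≥ 300 bp, GC > 0.5, observed/expected CpG
= (#CpG · L)/(#C · #G) > 0.6 (0 when #C·#G = 0). N bases never count as
C, G or CpG and are excluded from the effective length. Detection slides
a 300-bp window (step 1) and merges overlapping/adjacent passing
windows. Because a window passes as soon as roughly half of it overlaps a
strong island, the merged span systematically overhangs the true GC-rich
run by up to a window length per side; each merged candidate is therefore
refined to its maximal-scoring subsegment under per-base scores
(1 − gc_min) for G/C, (−gc_min) for A/T and 0 for N (Ruzzo–Tompa-style
segment refinement via Kadane's algorithm), which localizes boundaries to
within a few bases. The refined interval is re-scored against all three
criteria; if it fails it is trimmed greedily one base at a time from
whichever end leaves the better margin, and discarded if it drops below
the minimum length. Emitted intervals are disjoint, sorted, and each
satisfies all criteria when re-evaluated independently. Coordinates are
0-based half-open throughout (BED output included); island coordinates on
real genomes depend on these algorithmic conventions and may differ from
other detectors built on the same three criteria.

## Bisulfite patterns

Contexts follow the plant convention: a cytosine is CG if the next
strandwise base is G, CHG if followed by H then G, CHH if followed by two
H (H ∈ {A, C, T}); sites whose lookahead leaves the region or crosses an
N are INDETERMINATE. Minus-strand sites (G on the reference) are reported
at their plus-strand coordinate.

Amplicons are aligned to their region with a global pairwise aligner
whose substitution matrix scores reference-C/read-T as a full match (the
expected conversion signal), match +1, mismatch −1, gap open −3, extend
−1, free end gaps. Two quality gates reject foreign reads: at least 80 %
of the read must align, and identity on aligned non-C reference
positions must reach 80 % (both configurable). Calls at reference C
positions: read C → methylated, read T → unmethylated, anything else →
ambiguous. Only the declared bisulfite strand of an amplicon is called;
bottom-strand amplicons are handled by reverse-complementing the region.
An in-silico converter (`in_silico_convert`) inverts this exactly, so a
round trip at conversion rate 1 recovers the planted methylation set —
the test suite asserts the exact identity.

Conversion efficiency is the percentage of callable lambda-spike
cytosines read as T (the spike is unmethylated ground truth). Inheritance
fidelity is, per context, the fraction of sites callable in the parent
and every progeny at which all progeny match the parent; ambiguous sites
are excluded from numerator and denominator, and per-progeny pairwise
concordances are reported alongside (each progeny inheriting
independently with per-site retention f makes the joint all-progeny
concordance ≈ f^k, while the pairwise values estimate f itself).

## Synthetic-data generator

All generators draw from one integer seed; per-artifact substreams are
derived deterministically from (seed, artifact-name CRC), so identical
seeds give byte-identical outputs and artifacts are independent of one
another.

* **MSAP**: each cell is multinomial over the four states with per-dose
  frequencies defaulting to the observed dose profiles (counts
  110/11/73/52 at 0 mM through 129/11/70/35 at 50 mM, each row normalized
  by its own total; the published row totals 246–248 are preserved in
  the table above but normalization removes the discrepancy from the
  simulation). The default design is the 27-individual survey (5 control,
  4/4/9/5 at 1/5/20/50 mM, largest class at 20 mM) with 246 loci. Loci
  are exchangeable — no locus effects, linkage or individual effects —
  so recovery tests validate estimator behaviour, not biological
  covariance structure.
* **Phenotypes**: control values are Normal with the control cohort
  moments (flowering 65.8 ± 6.9 d, rosette 2.5 ± 0.7 cm); treated values
  are Normal with a configurable sd inflation (default 1.0, so the
  treated background is null apart from planted outliers — the
  population-level variance expansion reported for real treated cohorts
  is available via `sd_inflation`). Outliers (default 5 % of treated) are
  planted at exactly μ ± 3·sd with random sign: the displacement is
  deterministic so truth labels are unambiguous and screen power is a
  property of the test, not of where sampling noise happened to put the
  outlier. A separate generator draws progeny families from the
  published family moments.
* **Genome**: iid background at GC 0.30 with planted islands that
  interleave explicit CG dinucleotides (rate 0.25) into GC 0.65 single
  bases, giving island observed/expected CpG well above 1. Real genomes
  are CpG-depleted outside islands and have repeat structure; the
  generator's background is iid, so detection tests demonstrate boundary
  behaviour under clean contrast, not performance on real chromatin.
* **Bisulfite**: one region (default 600 bp, GC 0.5), parent methylation
  drawn per context (defaults CG 0.85, CHG 0.60, CHH 0.30, a typical
  plant heterochromatic profile), progeny copying each parental site
  with per-context fidelity (defaults CG 1.0, CHG 0.9, CHH 0.85,
  mirroring the observation that symmetric contexts are inherited more
  faithfully), reads converted in silico at rate 0.995 by default, and a
  fully unmethylated lambda pair converted at the same rate.
* **Variants**: per-record genotype class drawn from a configurable mix,
  and quality / read-depth / indel-adjacency failures planted
  independently (10 % each by default). Records are spaced 1 kb apart so
  only deliberate indel companions trigger adjacency. Truth records each
  locus's class, failed rules and expected survival.

## Simulation scales

Statistical acceptance checks run at sizes chosen to make Monte-Carlo
noise small relative to their tolerance bands while keeping the whole
suite fast on a single CPU: 600 datasets × 199 permutations for the AMOVA
null calibration; 5000 control / 2000 treated individuals for the
Z-screen calibration (the large control cohort keeps baseline-estimation
noise well below the binomial width of the false-positive band);
2000–3000 bp regions for conversion and fidelity estimation; 40
replicates for dose-response monotonicity.

## Known limitations

* One-level AMOVA only; no hierarchical designs or NML/AFLP-based
  differentiation.
* The MSAP distance convention (Euclidean with missing-data rescaling)
  is an explicit choice, not a reconstruction of the original tooling,
  so Φst values on real data may differ slightly from other pipelines.
* Hemimethylation at internal vs external cytosines cannot be separated
  by the two-enzyme design; both collapse into type II.
* CpG-island coordinates are convention-dependent (window, merge,
  refinement); only the three defining criteria are portable.
* The bisulfite caller assumes one contiguous amplicon placement and
  Sanger-like single sequences per individual; it is not a WGBS caller
  and does no read-level quality handling.
* Generators keep methylation, phenotype and variant artifacts mutually
  independent; no coupling between methylation loss and phenotype shift
  is modeled.
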
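# Methods

This note records the models and procedures `promenh` implements, the
conventions it fixes where the underlying definitions leave room, and what
the synthetic-data generator does and does not emulate.

## Coordinates and element anatomy

All genomic coordinates are BED-style: 0-based, half-open `[start, end)`.
Relative coordinates place 0 at the anchor base (TSS, or enhancer midpoint)
and increase in the direction of transcription, so minus-strand elements are
analysed on their reverse complement. A bidirectional enhancer is treated as
carrying two TSSs: the reverse transcript initiates at the interval start,
the forward transcript at `end − 1`, and the midpoint is
`floor((start + end)/2)`. For strand-`.` enhancer records this TSS
convention is asserted rather than derived from data. The promoter region
used for binding-density summaries covers relative `[−500, +200)` (700 nt)
on the element's strand.

## CpG-island calling

A 100-nt window slides in 1-bp steps. Per window, GC% = 100(n_C + n_G)/L and
CpG obs/exp = n_CpG · L / (n_C · n_G) (0 when either base count is 0), with
n_CpG counting dinucleotide start positions fully inside the window. Windows
containing `N` fail both thresholds — composition is never fabricated. A
call is emitted per maximal run of qualifying window starts (GC ≥ 50 %,
obs/exp ≥ 0.6) whose span — first window start to last window end — is
≥ 200 bp. Because the spans of two distinct runs can overlap (they share up
to 99 flanking bases), overlapping calls are merged afterwards so emitted
islands are disjoint; the per-call mean GC and obs/exp are then
length-weighted means over the merged runs' qualifying windows.

The obs/exp ratio is used as a plain ratio against 0.6, the
Gardiner-Garden & Frommer convention; a ×100 scaling sometimes written into
the formula is equivalent if the threshold is scaled to 60, and is not
applied here.

Association rules differ deliberately between element classes: a *promoter*
is CGI-associated when any island is called within its `[−200, +200]`
TSS window (the island need not touch the TSS); an *enhancer* is associated
only when a called island contains one of its two TSS bases, matching the
stricter overlap phrasing used for divergent transcripts.

## Core promoter elements

Each CPE is a PWM with log-odds weights
`w_bi = log2(((f_bi + pc·q_b)/(1 + pc))/q_b)`, uniform background
q_b = 0.25 and pseudocount pc = 0.01 by default. The shipped asset
(`assets/cpe_pwms.yaml`) builds the twelve matrices (TATA, Inr, BREu, BREd,
DPE, MTE, DCE I–III, XCPE1, TCT, Pause Button) from published IUPAC
consensus sequences, with canonical start positions relative to the TSS
(TATA at −31, Inr at −2, DPE at +28, …) and cutoffs expressed as a fraction
(0.8) of each matrix's maximum achievable score. These defaults make the
pipeline runnable and swappable, but they are consensus-derived stand-ins:
they will not numerically match motif calls made with experimentally fitted
matrices and per-matrix cutoffs. Cutoffs are *inclusive* (score ≥ cutoff
calls a hit) — one consistent convention avoids floating-point knife edges.
Windows containing `N` never match. DPE carries a dependency on Inr: DPE
hits are reported only for elements that also have an Inr hit inside the
Inr functional window, reflecting the cooperative TFIID interaction of the
two elements.

### Localized overrepresentation

For a CPE with expected start position e, the functional window is
[e − 2, e + 2] (five start positions). n⁺ counts elements with ≥ 1 hit
starting there. A 5-nt window slides across the scanned span [−500, +200];
per window position the statistic is the number of *elements* with a hit
starting inside it (not the number of hits — this keeps the background
directly comparable to n⁺). Windows overlapping the functional window are
excluded; μ and σ are the mean and sample standard deviation (ddof = 1,
the marginally conservative choice) over the rest. Significance requires
both the Gaussian upper tail of z = (n⁺ − μ)/σ and the binomial upper tail
P(X ≥ n⁺), X ~ Binomial(n, μ/n), to fall below α (default 0.001,
uncorrected — the twelve per-CPE tests are reported individually). When
σ = 0 the z-score is undefined; the result is flagged degenerate and the
Gaussian tail is reported as 0 (n⁺ > μ) or 1.

### Co-occurrence

For each CPE pair, elements are cross-classified by functional-window
presence into a 2×2 table (a = both, b = first only, c = second only,
d = neither). The co-occurrence tail
p_co = Σᵢ C(a+b, a+i)·C(c+d, c−i)/C(N, a+c), summed to
min{N−a, b, c, N−d}, equals the classical hypergeometric upper tail
P(X ≥ a); p_anti is the mirrored lower tail. Both are evaluated in log
space (log-gamma factorials, log-sum-exp) so values far below 1e-300 stay
meaningful; linear and natural-log values are both returned. The per-test
threshold is α = 0.05/(k(k−1)/2), i.e. 0.05/66 for twelve CPEs. The
two-sided Fisher test used for association tables (e.g. sharp/broad × CGI)
follows the standard "sum of all tables with point probability ≤ observed"
rule, also in log space; the one-sided sums above are kept as printed for
the co-occurrence module.

## CAGE metrics

*Dispersion / sharpness.* Per library i, with x_{i,j} tags at position
j ∈ [−50, +50] on the element's sense strand, c_i = Σ x_{i,j},
m_i = (1/c_i) Σ j·x_{i,j} and s_i = √((1/c_i) Σ (j − m_i)² x_{i,j}).
Elements are *sharp* when the mean of s_i over informative libraries
(c_i > 0) is ≤ 2.5 — the threshold is inclusive — and *broad* otherwise;
elements with fewer than one informative library (configurable) are left
unclassified rather than forced into a class. Enhancers are classified per
transcript: midpoint-relative tags are re-anchored onto each of the two
edge TSSs, giving two records per enhancer.

*Tissue specificity.* Expression is normalized per library to tags per
million (the total over the whole tag table), summed over the window
[−100, +100] on the sense strand (promoters), averaged over a group's
member libraries, scaled by 1000 and transformed as log₂(1 + x). The 1 +
offset is a deliberate deviation from a bare binary logarithm: it keeps
zero-expression groups defined instead of −∞. τ = Σ(1 − x̂ᵢ)/(n − 1) with
x̂ᵢ = xᵢ/max xⱼ is computed over the top-15 groups of each class (tissue,
primary cell) ranked by total log expression across all elements, ties
broken lexicographically for determinism. All-zero profiles leave τ
undefined and flagged. For enhancers, where no per-TSS window is canonical,
expression pools both strands over [−200, +200] around the midpoint — the
package's own convention.

*Directionality.* R pools reverse-strand tags over [mid − 200, mid) and F
forward-strand tags over [mid, mid + 200], all libraries together;
directionality = (F − R)/(F + R) ∈ [−1, 1], with the half-open boundary at
the midpoint chosen once so no tag is double-counted. Enhancers with
F + R = 0 are excluded from summaries rather than scored 0.

## Peak overlap

A "binding event" is one narrowPeak record sharing ≥ 1 base with the
region (half-open intersection); given ChIP-seq's ~500-nt peak resolution,
summit-based counting is not the default but is available
(`PeakIndex(mode="summit")`). Density = 1000 · n_peaks / region length.
Duplicate records each count, so concatenating peak files sums counts.
Maximum H3K27ac signal is taken over all peaks pooled across files
intersecting the element. Counting uses sorted-array arithmetic per
chromosome (count = P − #[start ≥ region.end] − #[end ≤ region.start]),
verified in tests against a quadratic interval-intersection oracle.

## Synthetic data

The generator emulates the *structure* of FANTOM5/EPDnew/ENCODE inputs at
desk scale with exact ground truth; every stage has a recovery test against
the truth tables, and a fixed seed gives byte-identical outputs.

* Each element occupies its own small chromosome (promoters: 1801 nt, TSS
  centred; enhancers: body + 600-nt flanks), making regions independent.
  Background sequence is i.i.d. at GC 41 %.
* CGI fractions default to 0.586 (promoters) and 0.057 (enhancers), the
  proportions of the full-scale datasets. Planted islands are
  **composition-controlled**: a fixed 20-nt tile (65 % GC, two CpG, none
  across seams) is repeated to a Uniform[250, 1200]-nt block covering the
  designated TSS, then hit with 3 % random substitutions. Tiling keeps
  every 100-nt window at GC ≈ 65 %, obs/exp ≈ 0.95, so detection by the
  all-consecutive-windows rule is near-deterministic; a fully stochastic
  island model at the same marginal composition would be missed by that
  strict rule in a material fraction of cases, which would conflate
  generator noise with caller behaviour.
* Motifs are planted by writing the matrix consensus at
  expected position + Normal(0, jitter), DPE only alongside Inr, with
  overlaps resolved in priority order TATA > Inr > DPE > others. Default
  plant rates (TATA 0.15, Inr 0.45, DPE 0.40 among Inr⁺, BREu 0.10,
  TCT 0.10) loosely follow reported promoter prevalences.
* CAGE: sharp elements draw tag positions from a point mass (± 1 nt), broad
  ones from Normal(0, σ = 20) truncated to [−50, 50] — σ chosen so broad
  elements exceed the 2.5 dispersion threshold by construction. Tag depth
  defaults to Poisson(200) per expressed library, with 29 tissue and 36
  primary-cell groups (one library each). Tissue breadth is a binary
  mixture: *specific* elements express in one tissue and one primary cell,
  *ubiquitous* ones in every library. Enhancer tags split between strands by
  a per-enhancer directionality drawn from Beta distributions mapped to
  [−1, 1].
* Sharpness, breadth, directionality Beta parameters, element length and
  peak density are all conditioned on CGI status, with defaults that mirror
  the *direction* of the full-scale findings (CGI → broader initiation,
  broader expression, higher |directionality|, longer elements, higher
  binding density — e.g. 5.06 vs 1.89 events/kb at promoters, 2.46 vs 1.15
  at enhancers) without claiming the full-scale magnitudes. Enhancer length
  is lognormal per group, parameterized to give means ≈ 384/289 bp and
  > 1 kb tail fractions ≈ 2.6 %/0.5 %.

What the generator does **not** emulate: mappability and sequencing-error
artefacts, realistic chromatin state, tag-cluster substructure (sharpness
is a clean two-class mixture, so classification accuracy on synthetic data
overstates accuracy on real CAGE), correlated expression across related
tissues (τ is near-binary here, so synthetic τ medians are more extreme
than the 0.795/0.944 scale observed in real data), and genome-scale element
counts. Passing recovery tests therefore demonstrate correctness of the
*measurement* code under known ground truth, not expected effect sizes on
real data.

## Numerical choices and degenerate inputs

* Exact tail sums and Fisher tests run in log space; tests require
  agreement with exhaustive rational enumeration to 1e-9 relative error for
  all tables with N ≤ 30.
* Score and dispersion thresholds are inclusive (≥ cutoff, ≤ 2.5).
* Ties in top-group selection break lexicographically; iteration orders are
  fixed, so re-running a config reproduces every report number exactly.
* Degenerate inputs have explicit behaviour rather than NaN propagation:
  zero-tag libraries are uninformative, all-zero expression flags τ
  undefined, σ = 0 flags the overrepresentation result, zero-margin tables
  return p = 1 with the odds ratio flagged undefined, empty enhancer sets
  produce promoter-only reports.

## Problem sizes

Defaults are desk-scale by design: 300 + 300 elements in the generator,
500 promoters + 2000 enhancers in the acceptance script, 1000 × 2-kb
sequences for the caller-vs-oracle equivalence check, 2000 regions for
density recovery, 1000 replicates for the type-I-error property. These
sizes give stable recovery statistics (standard errors well inside the
asserted tolerances) while a full test-plus-acceptance run completes in a
few minutes on one CPU.

## Known limitations

* Shipped PWMs are consensus-derived; swap in fitted matrices via the YAML
  asset for real analyses.
* The CGI caller scans fixed windows around TSSs; it does not produce a
  genome-wide island track, and islands wider than the scanned span are
  truncated at its edges.
* Directionality and sharpness conventions at window boundaries (midpoint
  assignment, inclusive extents) are fixed choices among several defensible
  ones; results at single-tag resolution depend on them.
* `tau` operates on whatever expression matrix it is given; the top-15
  group selection is part of the pipeline, not of the statistic.
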
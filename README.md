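# promenh

**CpG-island-dependent, promoter-like characteristics of transcribed enhancers.**

Bidirectionally transcribed enhancers — the CAGE-defined elements of the
FANTOM5 atlas — share a surprising number of sequence and expression
characteristics with promoters, and the magnitude of those characteristics
tracks the presence or absence of a CpG island (CGI) at the element.
`promenh` is a tested, reusable pipeline for this kind of analysis. It is
aimed at regulatory-genomics researchers who want to classify promoters and
enhancers by CGI status and then quantify, per element and per group:

* **CpG islands**, called by the sliding-window rule: a 100-nt window is
  shifted in 1-bp steps; an element region qualifies when all consecutive
  windows across ≥ 200 bp have GC ≥ 50 % and CpG obs/exp =
  (n<sub>CpG</sub> · L)/(n<sub>C</sub> · n<sub>G</sub>) ≥ 0.6.
* **Core promoter elements (CPEs)** — TATA, Inr, BREu, BREd, DPE, MTE,
  DCE I–III, XCPE1, TCT, Pause Button — scanned as position weight matrices
  with score x = Σᵢ w<sub>bᵢ</sub> and matrix-specific cutoffs, with a
  **localized-overrepresentation test**: the number of elements carrying a
  hit in the motif's functional window (expected position ± 2 nt) is
  compared against 5-nt background windows slid across [−500, +200],
  via both a Gaussian z-score and a binomial upper tail.
* **CPE co-occurrence**, with the one-sided hypergeometric tail sums
  p = Σᵢ C(a+b, a+i) C(c+d, c−i) / C(N, a+c) (and the anti-correlation
  analogue), Bonferroni-corrected over all 66 CPE pairs (α = 0.05/66).
* **CAGE metrics**: the dispersion index
  sᵢ = √((1/cᵢ) Σⱼ (j − mᵢ)² x<sub>i,j</sub>) over ± 50 nt with sharp/broad
  classification at mean ≤ 2.5; tissue specificity
  τ = Σᵢ(1 − x̂ᵢ)/(n − 1) over the top-15 expression groups; and enhancer
  transcription directionality (F − R)/(F + R) from strand-specific tag
  counts within ± 200 nt of the midpoint.
* **Peak overlap**: maximum H3K27ac signal per element and
  transcription-factor binding-event density per 1000 nt (promoter region
  −500..+200 around the TSS).

A deterministic synthetic-data generator produces every input format
(FASTA, BED6, narrowPeak, tag tables) with machine-readable ground truth,
so the whole pipeline is testable end-to-end without downloads.

## Worked example

```python
from promenh import SimConfig, run_pipeline

report = run_pipeline(SimConfig(seed=1, n_promoters=150, n_enhancers=150))
```

(`examples/05_full_pipeline.py`; every other capability has its own short
script under `examples/`.) The run prints, among other things:

```
CGI-associated: 59.3% of promoters, 4.0% of enhancers

significantly locally overrepresented CPEs (alpha = 0.001):
  promoter  TATA  n+ =   20  z =   89.5
  promoter  Inr   n+ =   67  z =   25.2
  promoter  DPE   n+ =   27  z =   21.0
  ...

                comparison      kind  n_cgi  n_non_cgi  median_cgi  median_non_cgi            p
         tf_density_by_cgi  promoter     89         61    4.285714        1.428571 3.932162e-13
sharpbroad_cgi_association  promoter     89         61         NaN             NaN 4.456246e-25
```

Reading this: the caller recovers the configured CGI fractions (59 % of
promoters, ~5 % of enhancers); exactly the five CPEs the generator planted
(TATA, Inr, DPE, BREu, TCT) test as locally overrepresented, with n⁺ the
number of elements carrying the motif at its canonical TSS-relative
location; and the CGI-stratified comparisons recover the planted group
effects — CGI elements are denser in binding events (4.3 vs 1.4 events/kb
here) and CGI status associates strongly with broad rather than sharp
transcription initiation (Fisher p ≈ 4 × 10⁻²⁵ at this sample size).

The same stages are available as a thin CLI:

```bash
promenh simulate --seed 1 --outdir inputs/      # write FASTA/BED/TSV/narrowPeak
promenh cgi      --indir inputs/ --outdir out/  # CGI association from sequence
promenh cpe      --indir inputs/ --outdir out/  # PWM hits + overrepresentation
promenh cage     --indir inputs/ --outdir out/  # sharpness, tau, directionality
promenh peaks    --indir inputs/ --outdir out/  # densities and max signal
promenh all      --seed 1 --outdir report/      # everything, consolidated
```

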
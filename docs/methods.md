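# Methods

## Scope and data model

The package implements a desk-scale version of a genome-wide
oxidative-stress regulon analysis: protein occupancies called from
two-channel tiling-array log ratios, occupancy apexes mapped to promoters,
a binding motif discovered at the apexes, H2O2-responsive genes and their
transcription-factor dependency called from replicated time courses, and
growth-fitness deficits scored from mini-culture OD curves. All
coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive, BED 0-based half-open.

## Occupancy calling

A `ProbeTrack` holds ordered probe start positions and per-probe
log2(ChIP/WCE) values. Normalisation is LOWESS on the (A, M) plane
(statsmodels local regression, `frac=0.3`, 2 robustness iterations)
followed by median-centring, and quantile normalisation across arrays
(sorted values replaced by the mean quantile vector, ranks preserved).

The enrichment threshold is `median + 2.5·MAD` with the *unscaled* MAD.
Under Gaussian noise 2.5 unscaled MADs is ≈1.69 σ, an upper tail of ≈4.6% —
close to, but not exactly, a top-3% rank cut; both filters exist and can be
composed, the MAD rule is the default.

Candidate occupancies are maximal runs of ≥ 4 consecutive above-threshold
probes. Each 9-probe window centred on a run probe is tested with the
binomial upper tail P(X ≥ m | 9, Pr), Pr the genome-wide above-threshold
fraction computed after normalisation; the run qualifies if any covering
window has p ≤ 0.001. Windows clip at chromosome ends (the test then uses
the shorter window length). Both strands' probes are pooled into one
positional grid: ChIP enrichment is not strand-resolved. "Linear
smoothing" is implemented as a centred moving average whose window shrinks
at the edges, applied 3 times at width 5 (triple-boxcar; the unit-impulse
centre response is 19/125). The apex is the leftmost maximum of the
smoothed track inside the run; its smoothed value is the enrichment level.

The FDR procedure is a design choice (the operation it stands in for is
only characterised by its bound): probe values are permuted within each
chromosome — preserving the value distribution, the threshold, and Pr,
while destroying spatial runs — and FDR = mean null SER count / observed
count over (default) 100 seeded permutations, clipped to [0, 1].

## Site logic

Apex-to-apex distance defines overlap, inclusive at 200 bp (a strict-`<`
switch exists; the inclusive reading matches how the comparison counts are
reported). Matching is greedy nearest-apex with leftmost tie-break — it is
deterministic and symmetric under input swap. Major sites are those
matched across the two compared experiments; common major sites of two
factors merge matched pairs at the apex midpoint with the factor-mean
level.

Promoter windows: [ATG − 1000, ATG + 200] in reading orientation with the
upstream arm truncated at the nearest annotated neighbour (so only
intergenic sequence counts), or TSS ± 150 bp. Rule `either` is the union;
a site between divergent start codons can be assigned to both genes.
Non-coding genes (tRNA, 5S rRNA) are never targets but truncate their
neighbours' upstream span. Intergenic classification: `intragenic` if the
apex lies in a gene body; `divergent` if the flanking genes transcribe away
from the site on both sides; everything else (co-oriented and tail-to-tail)
is folded into `tandem`, since a tail-to-tail interval is nobody's
promoter.

## Motif discovery

MDscan-style enumeration. Sequences are 150-bp windows centred on apexes,
ordered by descending enrichment; the top 30 seed the search and the next
30 refine it. Seeds are the unique w-mers (w = 7 then 8) of the first 5
seed sequences; each seed collects, per seed sequence, its best w-mer
within 1 mismatch on either strand; candidates supported by fewer than half
of the seed sequences are dropped. Candidates are scored by information
content relative to the 0-order base composition of all input sequences,
the top 10 are refined by adding each refinement sequence's best
positive-scoring site and re-estimating, and the winner is the candidate
with the highest *per-column* information content — the normalisation that
makes widths 7 and 8 commensurable (raw IC grows with width and would
always prefer the wider matrix). Pseudocount 0.5 per base. PSSM scoring
is the maximum summed log-odds over offsets and strands, ambiguous bases
scoring at background; ROC/AUC by threshold sweep, equal to the
Mann–Whitney U statistic scaled by n₁n₂.

## Expression response

Values are log2 ratios to t = 0, times {0, 10, 30, 60, 120} min, 3
replicates, strains wt / atf1Δ / pcr1Δ. Per post-treatment time point the
treated replicates are contrasted against the t = 0 replicates with
d = Δmean/(s + s₀): s the pooled SE, s₀ the median of the per-gene pooled
SEs (percentile configurable). The null is all distinct group-label
permutations when ≤ `n_permutations` exist (with 3 vs 3 replicates all 20
are used), else a seeded sample. FDR(t) = median null exceedance count /
observed count at t = |d|, made monotone by a running minimum from the
smallest |d| upward; an empty 0/0 tail is FDR 0.

A gene is induced (repressed) when ≥ 2 consecutive post-treatment time
points each show replicate-mean fold change > 2 (< ½) at q < 0.05 with a
consistent direction; t = 0 is the reference and not part of the grid. The
FDR default is 0.05 with 0.03 reachable through `ResponseParams.fdr_max`
(both conventions appear in the source material for this rule). Dependency
applies the identical rule to the mutant-vs-wild-type contrast of
0-min-normalised levels; labels: `both`, `atf1_specific`, `pcr1_specific`,
`independent`. Time-to-4-fold is the first linear-interpolated crossing of
log2 4 by a group's replicate-mean profile. Response ranks are dense
descending ranks of the mean 30/60/120-min induction.

## Growth fitness

Curves are lightly smoothed (3-point moving average); baseline = smoothed
minimum is subtracted implicitly by defining half-max as
(smoothed max + smoothed min)/2, making T50 invariant to blank offsets and
OD rescaling and equivariant under time shifts. The plateau is the
smoothed maximum rather than the last sample, so truncated curves remain
scoreable. ΔT50 = T50(stress) − T50(optimal) per replicate pair (negative
values pass through); the deficient score is the ratio of replicate means
(mean-of-ratios available via `aggregate=`; ratio-of-means is the default
for stability when individual wild-type Δs are small), sensitive at ≥ 2
inclusive.

## Integration

Gene-set enrichment uses the hypergeometric law: observed fraction k/K
against chance n/N, two-sided p by minimum-likelihood summation (the
Fisher-exact convention; one-sided tails available). No multiple-testing
correction is applied across cross-table tests — raw p-values are
reported, and the report flags this. Kinase-recruitment dependency de-logs
the stored log2 levels before averaging, because the published ratio column
is only consistent with linear-scale division; the cutoff 0.6 is strict.
Dense ranking of mean factor enrichment ties equal pairs and increments the
successor by one.

## Synthetic study conditions

The generator fixes the conditions every recovery experiment runs under;
they were chosen once, at a desk scale that keeps the full pipeline under a
few seconds, and are not tuned per test.

| parameter | default | why |
|---|---|---|
| genome | 3 × 170 kb | smallest size giving ~30 k probes and 240 genes with realistic gene/gap widths (0.6–1.4 kb genes, 0.45–1.1 kb gaps) |
| tiling | 50-mers every 17 bp, alternating strands | the array design the caller assumes |
| planted sites | 50, triangular kernel, half-width 250 bp | unimodal finite-support peak; the half-width is a free simulator parameter (fragment-size data are not modelled) |
| peak height | N(2.5, 0.5) log2, floor 1 | comfortably above the 2.5-MAD cut at noise σ 0.3 yet overlapping it for the weakest sites |
| probe noise | Gaussian σ 0.3 log2 | matches the median/MAD thresholding assumptions |
| motif | 7-bp ATF/CREB-class consensus TGACGTA, 0.85 dominant base | the binding-site class of the factors modelled |
| time courses | 0/10/30/60/120 min, 3 replicates, noise σ 0.25 | the experimental grid |
| responsive genes | 15% induced, 10% repressed; max fold log-normal(ln 6, 0.4) floored at 2.5 | guarantees the >2-fold rule is exercisable under noise |
| dependency | 50% both, 15% atf1-only, 5% pcr1-only among responsive | dominant-heterodimer structure |
| response shapes | bound genes peak by 30 min; unbound induced delayed (25% at 10 min) | reproduces the direct-vs-indirect timing contrast |
| growth | logistic K = 1, r = 0.05/min, midpoint 300 min; stress lag 120 min, ×3 for sensitive strains; OD noise σ 0.01 | typical mini-culture scales |

Planted sites are intergenic only (the analysis defers intragenic sites),
placed 150–600 bp upstream of a coding gene's ATG, with the motif spliced
into the genome and every promoter-rule target gene recorded at planting
time; a cross-module test asserts the recorded targets equal the promoter
assignment on the ground-truth coordinates. Identical `SimConfig` and seed
give byte-identical outputs.

## What passing tests do and do not show

The generator's noise is Gaussian and independent across probes,
replicates and wells; real tiling arrays have probe-sequence effects,
spatially correlated noise and dye bias beyond the monotone trend that
LOWESS removes, and real peaks are not triangular. Recovery rates measured
here (≥90% of planted sites, apex within ~25 bp, permutation FDR ≪ 4%,
motif total-variation ≤ 0.2, ≥90% dependency accuracy, exact
sensitive-strain recovery) therefore demonstrate correctness of the
statistics and the plumbing under the stated model, not performance on real
microarrays. The headline counts of the original genome-scale experiments
(hundreds of binding sites and responsive genes) depend on the deposited
arrays and are not reproduced at this scale; what is reproduced exactly are
the worked examples computable from the published reference tables bundled
in `stresschip.published`.

## Numerical details and edge cases

- Binomial and hypergeometric tails come from scipy; both are cross-checked
  in the tests against exhaustive enumeration oracles.
- Apex ties break leftmost; overlap-match ties break by distance then
  leftmost apex.
- Tracks shorter than the 9-probe window yield no calls, with a warning.
- A constant expression matrix gives d = 0 (zero denominator defined as
  null) and no calls.
- `estimate_fdr` returns NaN when no SER is observed; pure-noise tracks
  report FDR near 1.
- T50 of a curve that never rises returns its first sample time (half-max
  equals the constant level); censored curves that stop right after the
  inflection still cross because the plateau is the smoothed maximum.
- Seeds: every stochastic step takes a seed or Generator; the pipeline
  derives stage seeds as small fixed offsets from `SimConfig.seed`.
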
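# Methods

## The meiosis model

Each chromosome enters meiosis as a bivalent of four chromatids: two
sister chromatids carrying the SK haplotype and two carrying the Zh
haplotype.  A crossover (CO) is a reciprocal exchange between one
chromatid of each homolog at a position x; the material distal to x
(telomere side) is swapped.  Chromatid identity is anchored at the
centromere — centromeres do not recombine — so cells 1–2 of a simulated
tetrad always carry SK centromeres and cells 3–4 Zh centromeres, and at
any marker outside conversion tracts the four cells segregate 2 SK : 2 Zh.

**CO placement.**  COs are laid down by a stationary gamma renewal
process in genetic distance with shape ν (`interference_shape`).  ν = 1
is a Poisson process (no interference); ν > 1 thins nearby double COs
(positive interference).  Stationarity is achieved by starting the
process a 20-mean-gap burn-in before the chromosome start, so the
expected event count is (genetic length)/(mean gap) for every ν.  The
mean gap is set so the expected genome-wide total per tetrad equals
`co_mean_per_tetrad` (default 38, the study's mean; the observed range
24–50 arises naturally).  Physical and genetic coordinates are related by
a uniform 1 cM/Mb map by default; per-chromosome piecewise rates
(`rate_map`) model recombination-active regions.  With `obligate_co`,
chromosomes drawing zero COs are redrawn; this conditioning slightly
raises the realized mean and is off by default.

**Chromatid choice.**  The first CO of a chromosome picks one SK and one
Zh chromatid uniformly; each subsequent CO reuses the previous CO's
chromatid with probability `reuse_prob_sk` (resp. `_zh`) per homolog.
For consecutive CO pairs the strand-sharing frequencies are in closed
form f2 = r_SK·r_Zh, f3(SK-shared) = r_SK(1−r_Zh), f3(Zh-shared) =
(1−r_SK)·r_Zh, f4 = (1−r_SK)(1−r_Zh); r = 0.5 per homolog gives the
1:1:1:1 null of no chromatid interference.

Carrier cells are derived by tracing strands outward from the centromere:
at each CO the two cells currently copying the engaged strands exchange
strands, so every CO switches parental origin in exactly two cells with
opposite transitions.  A useful emergent property: after several
intervening exchanges the mapping between strands and cells scrambles, so
for widely separated CO pairs (e.g. across the centromere) the cell-level
category frequencies tend to 1/6 : 1/3 : 1/3 : 1/6 rather than uniform,
even with no chromatid interference at the strand level.  Cell-level
1:1:1:1 calibration therefore holds for adjacent (intra-arm) pairs, which
is where the package tests it.

**Conversion tracts.**  With probability `gc_prob_per_co` (default 0.2) a
CO carries a conversion tract of length uniform in [220, 1875] bp (the
validated range), on one of the two recombinant chromatids (uniform),
extending from the exchange point away from the centromere and truncated
at the chromosome end or the recipient's neighbouring switch.  The donor
is the homologous parent — the recipient's centromere-proximal parent —
implemented by displacing the recipient's switch point distally by the
tract length.  Inside a tract the tetrad segregates 3:1 with the donor in
the majority.

**Observation.**  Each call is seen with probability `coverage` (default
0.41) and flipped with probability `error_rate` (default 1e-6, the
multiple-displacement-amplification error scale).  Dropout is i.i.d. per
call; real MDA dropout is spatially correlated, but no correlation
structure is reported for it, so none is modelled — recovery rates under
correlated dropout would be somewhat lower at equal mean coverage.

**Marker map.**  Inter-marker gaps are 4 bp plus an exponential excess
with the scale chosen so the gap median equals the requested spacing
(default 235 bp, the study's median); the ≥4 bp minimum mirrors the
diagnostic-SNP spacing rule.  Gap distributions of real SNP maps are
right-skewed, so the mean gap (~337 bp) exceeds the median.

## Calling pipeline

1. **Segregation classes** per marker per tetrad: 2:2, 3:1 (with majority
   parent), 4:0, or incomplete (<4 calls).  4:0 markers are treated as
   genotyping error.  Complete 3:1 and 4:0 markers are masked before
   segmentation so conversion tracts do not displace the crossover
   interval.
2. **Haplotype segmentation** per cell: two-state (SK/Zh) chain with
   symmetric emission error ε and constant switch probability s per
   interval between informative markers, decoded by Viterbi with ties
   broken toward fewer switches.  Defaults ε = 0.01, s = 1e-4 are robust
   for real data, where mapping artefacts and amplification chimeras add
   errors beyond the nominal rate.  Note the implied resolution: a run of
   k markers is called as a block only if k emission errors cost more
   than one switch, so at the defaults 1–2-marker blocks are absorbed.
   When the per-call error rate is known (as for simulated data) ε should
   be set to it; the recovery analyses use ε = 1e-6 for dropout runs and
   ε = 1e-9 for error-free runs, which resolves single-marker islands
   from tight double COs.
3. **Crossover calling**: block boundaries are candidates (half-open
   1-based interval between flanking informative markers).  One SK→Zh
   candidate is paired with one Zh→SK candidate of another cell by a
   linear assignment maximizing the number of merged pairs and then
   minimizing midpoint distance; candidate intervals must overlap within
   `merge_slack` (default 2500 bp, sized to the maximum conversion-tract
   displacement plus a marker gap).  Unmatched candidates are kept as
   non-reciprocal events and logged, never silently merged.
4. **Interval convention.**  A conversion displaces the recipient's
   apparent switch strictly away from the centromere while the partner
   switches at the true exchange point.  On the right arm the exchange
   point therefore always lies in (min of candidate lefts, min of
   candidate rights]; mirrored on the left arm.  This arm-aware interval
   provably contains the true position under the displacement model; when
   no centromere is supplied the caller falls back to the intersection
   (or hull for slack-merged pairs).  The midpoint is
   floor((left+right)/2).
5. **Conversion tracts**: maximal runs of complete same-majority 3:1
   markers (incomplete markers are transparent; complete 2:2 or 4:0
   markers break a run) within `search_window` (20 kb) of a called CO.
   Donor = majority parent.  Inside a tract *both* carriers show the
   donor allele, so the recipient chromatid is identified as the carrier
   that still matches the donor on the centromere-proximal flank.  Runs
   with a single marker are flagged `single-marker` (possible false
   discovery); runs with no CO nearby are logged as possible
   NCO-associated conversions and not called (NCO detection needs far
   deeper coverage than single-cell data provide).

### Detectability limits

Two event classes are not recoverable from genotypes by any method and
are excluded from recovery denominators: (i) a CO whose conversion tract
runs to the chromosome end leaves no informative marker distal to the
recipient's switch, so the second carrier is unidentifiable; (ii) under
dropout, a double CO whose shared carrier's intervening island is
entirely unobserved is genotypically identical to a single CO between the
other two carriers.  At the scaled genome used for validation these are
~0.1–0.4% of events.

## Filters

Parental diagnostic-SNP calling keeps sites homozygous in both parents
with different alleles, quality ≥ 20, depth in [3, 3× the genome-wide
mean], ≥ 2 uniquely mapped reads (all configurable), then enforces ≥4 bp
spacing greedily left-to-right (keep-first).  Population filtering drops
markers with minor-allele frequency < 0.1 over non-missing calls, then
markers called in < 10 cells, then masks per-cell discordant runs of
≤ 20 markers whose same-parent overlapping run appears in < 5 cells.
With biallelic calls every internal run disagrees with both flanks, so
the rule reduces to internal-run masking with a sharing count.  Note this
filter can mask a genuine double CO spanning ≤ 20 markers in a single
cell; at study-like CO densities (< 1 CO/Mb) such pairs are rare.  The
10-marker QC panel fails a marker whose calls are incompatible with 2:2
(any allele more than twice) or with < 2 cells called, and discards a
tetrad with more than two failing markers.

## Interference statistics

CoC uses non-overlapping windows (1 Mb default) and presence/absence per
unit — per tetrad, or per cell with a cell counted as hit when it
carries the CO — because the rate-product formulation implies disjoint
sites; q·(window) is the presence frequency, D the joint frequency, and
pairs with q₁q₂ = 0 are excluded rather than infinite.  The cell-level
to tetrad-level CoC ratio equals 2·f2 + f3 for double-CO bivalents
(2chr pairs co-occur in 2 of 4 cells, 3chr in 1, 4chr in 0), so the
cell-level CoC exceeds the tetrad-level one exactly when the 4chr share
is below 25%; the validation isolates bivalents with exactly two COs in
distinct windows, where the identity is exact, because windows hosting
non-adjacent CO pairs dilute it toward 1.

Chromatid-interference categories are defined on the union of the two
COs' carrier cells: 2 cells = 2chr, 4 = 4chr, 3 cells labelled by the
centromere parents of the union (one SK + two Zh = 3chr(SK), the
reverse = 3chr(Zh)).  Level 1 pairs one CO from each arm (all cross-arm
pairs); level 2 uses adjacent pairs within an arm (all-pairs mode
available).  Counts are tested against 1:1:1:1 by a chi-square
goodness-of-fit (df 3) on the pooled counts, and their stability is
summarized by subsampling 15 of 24 tetrads 100 times (sampling without
replacement — a subsample, not a classical bootstrap, matching the
published procedure; the published replicate-level P-values imply an
unstated test across replicates and are not reproduced).  Per-cell CO
counts sum to twice the tetrad count, since each CO is carried by two
cells.  Group comparisons of per-tetrad counts use one-way ANOVA, which
for two groups equals the pooled two-sample t-test; the package also
computes that t directly from published group summaries (n, mean, sd).

## Gene context

The ATG and UGA of each transcript are the CDS extremes from GFF3
(strand-aware).  For each CO midpoint the nearest transcript minimizes
the unsigned distance to the ATG–UGA span (0 inside).  The normalized
coordinate is the strand-aware offset from the ATG times 2500/|UGA−ATG|:
negative upstream, 0 at ATG, 2500 at UGA.  The 10-bin histogram takes the
body as 60% of the transcript (six bins over [0, 2500)) and each UTR as
20% (two bins over 2500/3 bp on each side), left-closed; positions beyond
the normalized transcript are counted separately.  Controls are uniform
positions over the concatenated genome, 581 × 5 sets by default; the KS
comparison pools the control sets.

## Problem sizes and numerics

Validation and the acceptance script run on a ten-chromosome, 4-Mb-per-
chromosome stand-in genome (~118k markers at 235-bp median spacing): CO
count per tetrad and marker spacing match the study, so per-event
recovery behaviour is preserved while chromosome-end effects are ~50×
more frequent than at true maize scale (hence the explicit detectability
definition above).  Event-level statistics (CoC, strand categories) are
computed from simulated truth events, which cost nothing to generate, at
whatever replication the Monte-Carlo error requires.  All stochastic
operations take explicit seeds and are reproducible bit-for-bit;
logging records unmatched candidates, excluded pairs and skipped inputs
rather than failing silently.

## Known limitations

* Dropout is spatially uncorrelated; real amplification bias is not.
* 3:1 classification requires all four cells called at a marker, so at
  41% coverage only ~3% of tract markers are classifiable and most
  conversion tracts are invisible; tract detection is therefore validated
  under full observation.
* Heterozygous calls in a haploid cell (possible heteroduplex DNA) are
  treated as missing; no heteroduplex reconstruction is attempted.
* NCO-associated conversions are out of scope (they require ≥50× depth).
* The genetic map is uniform unless a rate map is supplied; no map
  function is fitted from data.
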
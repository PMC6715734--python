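# Methods

This note documents the models and procedures implemented in `meiorec`,
the assumptions behind them, the parameters that matter, the design
decisions taken where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## The synthetic cross

The generator emulates a B6 x CAST hybrid cross carrying two *Prdm9*
alleles (Cast and humanised), each controlling its own hotspot set.

**SNP map.** Founder-diagnostic biallelic SNPs with i.i.d. geometric
inter-SNP gaps, mean `snp_spacing_mean` = 170 bp.  Each allele is a
random base; Strong/Weak classes (S = G/C, W = A/T) follow from the
bases.  Coordinates are 1-based internally (VCF convention); BED output
is 0-based half-open.

**Hotspots.** `n_hotspots` PRDM9 hotspots placed with >= 2 kb spacing.
Heats are lognormal with log-scale sd `heat_shape` = 1.1, chosen so that
the hottest one-sixth of hotspots carries over half of the total heat —
the only constraint available on the empirical heat distribution — while
no single hotspot dominates.  (An earlier Pareto parameterization with
tail index 1.3 satisfied the same top-sixth constraint but placed an
order-one share of all heat on the single hottest hotspot, a regime
incompatible with the observation that the top ~17% of hotspots — not
the top one — carry half the events; it was replaced.)  A fraction
`frac_asymmetric` = 0.3 of hotspots gets a B6 binding ratio x near 0 or
1 (Beta(1.5, 30) at either edge) and, with probability 0.96, a
polymorphism inside its ~30-bp binding motif; near-symmetric hotspots
draw x from Beta(30, 30).  Motifs are centred on a SNP when disrupted
and inside a SNP-free gap otherwise, so the disruption flag and the
variant-overlap measurement agree.

**Meiosis.** The number of homologue-templated DSB repairs transmitted
on a gamete is Poisson with mean `dsb_per_meiosis_mean` = 300; each
resolves as a CO with probability `co_fraction` = 0.10, otherwise as an
NCO.  This count is interpreted at the gamete level (repairs visible on
the transmitted chromatid), which is the quantity the per-meiosis DSB
estimator reconstructs: 270 NCOs + 30 COs observed at full detection in
one meiosis scale back to 300.  A hotspot fires at most once per meiosis
(hotspots are sampled without replacement, and a CO hotspot is not
reused for NCOs in the same meiosis) — repeated firing of one hotspot
within a single meiosis is biologically implausible and, on a scaled
genome, would create spuriously long merged conversion tracts.
NCO hotspots are drawn with probability proportional to heat times the
PRDM9 binding of the gamete's local homologue (x for B6 ancestry, 1-x
for CAST); tract lengths are exponential with allele-specific means
(30 bp Cast, 41 bp humanised), centred at the motif plus a normal
displacement of sd `tract_center_sd` = 200 bp; conversion copies the
other parental haplotype's alleles onto the tract SNPs.  Crossover
interference is not modelled; one obligate CO per chromosome is enforced
by resampling the CO hotspot allocation (the analyses do not depend on
interference).  The X chromosome and indels are not simulated;
sex-specific rates are off by default (`sex_heat_multiplier` = 1).

**Pedigree.** Two inbred founders -> one F1 pair -> 11 sequenced F2;
18 breeding lines each run F2 pair -> F3 pair -> F4 pair (sequenced) ->
4 F5 offspring (72 sequenced).  F3 and breeder F2 animals exist as truth
genomes but are not genotyped.  Truth events are retained per meiosis,
and each haplotype carries both an allele array and an ancestry array —
they differ exactly at converted sites, which is what makes event-level
truth comparison exact.

**Genotype calls.** Depth is Poisson (10x founders/F4, 20x F2/F5);
heterozygous allele depths are Binomial(depth, 1/2); homozygous sites
read the other allele at `base_error_rate` = 0.001 per read.  Artifact
modes exercise the filters: spurious hets with 1-2 minor reads at
`false_het_rate` = 5e-5 and spurious homozygotes (all reads one allele)
at `false_hom_rate` = 5e-5.  `exact_genotypes` replaces the sampling
with deterministic depths and even het splits; this is the noise-free
mode under which the recovery invariants hold exactly (a depth-1
heterozygote cannot display both alleles under any read-sampling model,
so "noise-free" has to mean deterministic reads).

**ChIP counts.** H3K4me3 totals are Poisson(alpha * heat) with the B6
count Binomial in x; DMC1 totals are Poisson(beta * heat * delay), where
delay rises linearly from 1 at symmetry 1 to `dmc1_delay_factor` = 2 at
symmetry 0 — the repair-delay signature of asymmetric hotspots.  The
DMC1 allele fraction is optionally shifted toward the less-bound
homologue (`dmc1_shift`, 0 disables); the underlying relation is only
qualitative, so both knobs are exposed rather than fixed.

## Background inference and event calling

Three background states (BB, BC, CC).  Emissions give the concordant
call probability 1-eps and split eps over the discordant calls; missing
calls are uninformative.  Transitions over a gap of d bp keep the state
with probability e^(-r d) and otherwise jump through a matrix that
forbids direct BB <-> CC moves.  Defaults eps = 0.002, r = 1e-7/bp; the
initial distribution is uniform.  Decoding is by forward-backward
posteriors with a per-SNP argmax (a state is assigned per SNP, which is
what the downstream conflict rule needs); the forward-backward scan is
numba-compiled with a pure-Python fallback.

Short segments (<= 10 SNPs) flanked by one identical state are dissolved
into their flanks before CO calling: a BB -> BC -> BB double switch over
a few SNPs is a conversion-scale signal, not two crossovers, and after
dissolution its SNPs surface as NCO candidates through the ordinary
conflict rule.  Short segments between two *different* states are kept
(genuine transitions).

The filter cascade, in order: (1) drop sites heterozygous or discordant
in the founders; (2) heterozygous candidates need a two-sided exact
binomial allele-balance p >= 0.01 **and** >= 2 reads supporting the
minor allele (the second clause removes the characteristic one-stray-
read artifact); (3) homozygous candidates need depth >= 5 and >= 5 reads
supporting the called allele; (4) configured exclusion regions; (5) an
optional guard distance around CO breakpoints (off by default);
(6) surviving candidates within 2,000 bp merge into one NCO call.  The
exact thresholds of the original pipeline are not published; these are
documented defaults, all configurable, and the FilterReport conserves
counts (input = sum removed + surviving).

**Recipient homologue.** The recipient is the homologue whose allele was
replaced: a het call in a BB segment means a DSB on a B6 haplotype
(donor CAST); a hom-B6 call in a BC segment means the CAST-ancestry
haplotype lost its allele (recipient CAST).  Per-site labels are
combined into an event-level consensus; disagreement yields "unknown".

**Inheritance and parent of origin.**  An F5 event is inherited iff a
parent carries an identical event — same converted SNP set (NCO) or same
breakpoint interval (CO); this is the strictest reading of "identical",
and sibling-shared inherited events collapse to one distinct event.  De
novo NCOs are assigned to the parent that is heterozygous at every
converted site when the other parent is homozygous there.  De novo COs
use a rule-based haplotype tracer: the decomposed state change fixes the
recombinant haplotype's ancestry on each flank, and an assignment
(mother = recombinant, father = static, or vice versa) is feasible only
if each parent's own background can supply the required ancestry on both
flanks; exactly one feasible assignment gives the label, otherwise
unknown.  Assignments never contradict truth in simulation, but on the
scaled genome the strict-identity rule mislabels a substantial share of
inherited events as de novo when the parent's call merged differently —
at study scale, with ~40 observable events per sample instead of
hundreds, this is a much smaller effect.

## Tract length and total DSBs

For each converted (focal) site, every other SNP within a 1,000-bp
window contributes a pair (d, x): distance and co-conversion indicator
within the same event.  Neighbour SNPs converted by a *different* event
of the same sample are dropped rather than scored 0 — they are neither
evidence for nor against the focal tract.  The composite log-likelihood
sum x(-lambda d) + (1-x) log(1 - e^(-lambda d)) is maximised over the
mean 1/lambda in [1, 1000] bp, step 0.1, ties toward the smaller mean,
boundary maxima flagged.  The window default matters little: virtually
all co-conversion signal for 30-40-bp tracts lies below ~200 bp.
Uncertainty comes from a percentile bootstrap (not BCa; simplest
consistent choice) over non-overlapping genomic blocks resampled with
length-proportional probability; 10-Mb blocks match the scale used on
the full genome, and smaller blocks are appropriate for the scaled
synthetic genome (the CI needs tens of blocks to be meaningful).

Cohort fits exclude complex events and events with an inconsistent
recipient: on a scaled genome, two conversions at one hotspot from the
two parental meioses can merge into one called event whose spurious
long-distance co-conversions have outsized leverage on lambda; these
merged events are overwhelmingly complex or recipient-inconsistent,
so the two exclusions remove the contamination without touching clean
single-tract events.

The total-DSB estimator scales observed counts:
total = [N_NCO / (power x p_snp) + N_CO / co_detect] / n_meioses, with
every component recorded for audit.  `p_snp` is the Monte-Carlo
probability that an exponential tract placed at a heat-weighted hotspot
(motif centre + displacement) contains >= 1 SNP; `power` comes from the
spliced-genotype simulation below.  CIs resample meioses when
per-meiosis counts are given, else events via a Poisson approximation.

## Power simulation

Tracts are simulated at hotspots sampled proportional to H3K4me3
enrichment, centres from the motif-displacement distribution, lengths
exponential over the grid 10-100 bp (step 10) and 150-300 bp (step 50).
Tracts with zero SNPs never enter the denominator.  For each tract a
recipient animal is chosen; a donor whose calls at the tract SNPs equal
the post-conversion genotype (het on homozygous backgrounds; the donor
allele's homozygote on heterozygous backgrounds) is selected uniformly
among eligible animals, and its call-level information (GT/DP/AD) is
spliced onto the recipient — all spliced information is downstream of
variant calling, which is sufficient for every implemented filter.  The
per-site filter cascade is then applied; power = surviving / (>= 1 SNP).
Detection weights per hotspot are the Monte-Carlo P(tract contains >= 1
SNP) under the fitted tract model times a global filter-survival factor,
normalised to mean 1, and feed the power-corrected (rejection-resampled)
GLM and symmetry analyses.

## Rate correlations and end-distance profiles

Counts per genome-tiling bin are modelled as Poisson around latent rates
W, giving Var(W) = Var(N) - E(N) and Cor(W_j, W_k) =
Cov(N_j, N_k) / sqrt[(Var N_j - E N_j)(Var N_k - E N_k)] with ordinary
(n-1)-denominator sample moments.  Estimates with non-positive variance
excess are flagged invalid rather than reported; raw estimates outside
[-1, 1] (possible in finite samples) are clipped for reporting with the
raw value retained.  Bootstrap CIs resample bins (multinomial weights);
invalid resamples are dropped and their fraction reported.  Bins are
unweighted; terminal partial bins keep their true lengths in the
intervals table.  The correlation recovery experiments generate
correlated rate fields as shared + independent Gamma components, which
fixes the field correlation exactly at alpha_shared / alpha_total.

End-distance profiles bin each event's distance to the nearer chromosome
end; the null scrambles positions uniformly per chromosome, preserving
per-chromosome counts exactly; 90% bands are percentile intervals
(bootstrap over events; scramble replicates for the null).

## Hotspot symmetry

x = B6 reads / informative reads, defined only at >= 10 informative
reads (no silent zeros); the H3K4me3 variant subtracts a configurable
linear input-chromatin estimate first (the full background correction is
outside scope).  Symmetry = 4x(1-x).  Homologous heat follows the
template convention: a DSB on the CAST chromosome repairs off the B6
homologue, so homologous heat is x*h, and (1-x)*h for a DSB on B6 — the
source description assigns both expressions to the same homologue, an
evident slip, and the template reading is the one under which
"homologous heat captures how well the homologous chromosome is bound".
Average homologous heat 2hx(1-x) is the initiation-weighted mean of the
two.  Symmetry bins cut the cumulative enrichment-predicted event mass
into equal thirds (asymmetric / intermediate / symmetric), ties kept
together; observed event fractions per class are tested against the
(optionally power-weighted) expected fractions by chi-square without
continuity correction, with Wilson CIs on the observed fractions.  The
binomial GLM (logit link, IRLS via statsmodels) regresses per-hotspot
event occurrence on DMC1 symmetry, log(H3K4me3 + 1e-4) and SNP
densities at +/-100/500/800 bp; separation is flagged and falls back to
a ridge-regularised fit.  Event-to-motif distances are computed two
ways (nearest converted marker, zero inside the motif; and
minimal-tract midpoint) and the histogram is SNP-density normalised.

## GC-biased gene conversion

Converted sites carry recipient/donor bases (recipient = the replaced
allele) collapsed over strand-equivalent pairs.  Records with unknown
recipient homologue still carry well-defined S/W classes at W<->S SNPs
(phase-free there) and are kept; S<->S and W<->W sites with unknown
recipient are dropped.  Bias fractions use exact (Clopper-Pearson) CIs
and exact two-sided binomial tests by the minimum-likelihood convention
(equal to the doubled tail at p0 = 1/2, reproducing p = 7.6e-5 for 18 of
19); Fisher tests use the same convention, cross-checked against full
hypergeometric enumeration in the tests.  The two-pathway model is the
closed form 1/(2-p) with exact inverse p = 2 - 1/bias, plus a direct
simulator used for the distance-stratified and proportion checks.  The
strand-aware vs strand-unaware DSB requirement is exposed only as the
generic ratio observed/observable-fraction; the specific observable
fractions behind any particular total are inputs, not outputs.

## Problem sizes and numerical choices

Tests and the acceptance script run on scaled genomes chosen per
experiment: recovery and filter tests use 8-14 Mb across 1-2 autosomes
with 300-600 hotspots; the total-DSB recovery uses 70 Mb with 6,000
hotspots, a configuration whose *per-hotspot event load* is close to the
study's (the quantity that controls same-hotspot event collisions and
hence merging losses; on a compact genome with few hotspots those
collisions, a pure scaling artifact, dominate the error budget).  The
tract-length recoveries use the study's own event counts (409 and 815)
at 1 SNP / 170 bp; the acceptance script averages a few independent
replicates to report the estimator's recovery rather than one draw's
Monte-Carlo noise.  Grid evaluation of the composite likelihood is
vectorised over compressed (distance, indicator) counts; log(1 - e^x)
terms are clamped at the smallest-double floor with a warning for
degenerate zero-distance unconverted pairs.

Truth-recovery metrics define recoverability at the information level of
the diploid data: a conversion cancelled by the other parental meiosis,
or a CO pair cancelling within one inter-SNP gap, carries no signal and
is excluded from recall denominators; conversions within 2 kb of a
crossover breakpoint of the same sample are indistinguishable from a
shifted breakpoint and are excluded symmetrically from recall and
precision when an interaction window is set.  Breakpoint matching allows
one SNP of slack on each side: posterior decoding localises a background
switch to within one inter-SNP gap, and with extremely skewed adjacent
gap lengths the MAP interval can sit one SNP off the generating one.

## What passing tests do and do not show

The generator produces clean exponential tracts, exact founder
inbreeding, error-free SNP maps, no structural variation, no alignment
artifacts, and artifact modes far simpler than real sequencing
pathology.  Perfect noise-free recovery therefore validates the calling
logic, not robustness to real data; the noisy-mode tests (default error
and artifact rates) probe the filter cascade but only against the
artifact families modelled here.  Real-data concerns that are out of
scope: read alignment and variant calling, SSDS processing, peak
calling, motif discovery, X-chromosome inheritance, crossover
interference, and the human replication analyses.
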
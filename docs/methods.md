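# Methods

This note documents the models behind `parbseq`: what the synthetic-data
generators emulate, how each analysis defines its quantities, the
numerical choices made where the design was genuinely open, and what the
package's tests do and do not demonstrate about real data.

## The system being emulated

A bacterial ParA–ParB–*parS* chromosome-partitioning system: short
(16 bp) palindromic *parS* sites clustered a few kb from the replication
origin are bound ("nucleated") by the ParB protein, which then associates
non-specifically with flanking DNA ("spreading") to build the partition
complex. The package provides the computational side of four assays used
to characterise such a system:

1. **Affinity capture with sequencing (IDAP-type)** — purified protein is
   mixed with fragmented genomic DNA; only fragments carrying an intact
   site are retained. Strand-sorted fragment 5′-end counts delimit the
   binding site at nucleotide resolution.
2. **ChIP-seq** — in vivo occupancy, revealing spreading as broad
   enrichment around the nucleation sites.
3. **Tn-seq** — comparative transposon mutagenesis (*parS*-carrying vs
   empty transposon) mapping the chromosomal zone in which an ectopic
   *parS* cluster is tolerated.
4. **SPR titrations** — equilibrium binding isotherms yielding per-site
   dissociation constants.

## Coordinates and geometry

All coordinates are 0-based and half-open internally (binding calls
additionally report their inclusive summit pair, whose span is
`site_end - site_start + 1`). Genomes may be circular; every interval
operation — occupancy footprints, fragment coverage, end counts, region
calling, zone calling — wraps modulo the genome length, and wrapped
regions are reported unwrapped (`end > genome_length`, `start` in
`[0, L)`).

The default toy genome is 1 Mb, circular, ori at 0, with seven planted
sites centred ~7.5 kb from ori: five strong sites (Kd 30–60 nM) at 1-kb
spacing inside a 5-kb window, flanked by two weak sites (Kd ≥ 1 µM)
1.5 kb outside. The site 16-mers are synthetic palindromes assembled as
`revcomp(half) + spacer + half` around the conserved half-site GTGAAA;
they are placeholders with the right structure and affinity split, not
published sequences. A chromosome-scale configuration is obtained by
passing a larger length (the Tn-seq workflow uses 4 Mb).

## Synthetic-data generators

All generators are deterministic given an integer seed, and every raw
sample is drawn by vectorised rejection sampling so that retained
libraries follow the stated models exactly rather than approximately.
Each fragment sample records `n_proposed`, the exact number of uniform
template proposals consumed up to the last retained fragment — an
unbiased measure of pull-down yield used for yield-preserving
normalisation (below).

**Occupancy model.** Relative occupancy equals the site amplitude over
each site interval and decays linearly to background over a configurable
per-side extent, reaching background one base beyond it, so an isolated
site's above-background support is exactly `width + 2 * extent` bases.
Overlapping footprints combine by maximum. The linear decay is a
modelling choice: the assays constrain only the extent of spreading, not
its shape, and a linear ramp makes the support width an exact, testable
function of the parameters.

**ChIP fragments.** Proposals have uniform start and sampled length
(default truncated normal, mean 150 bp, sd 50, bounded 50–900 bp,
matching sheared chromatin averaging ~150 bp and below 1 kb) and are
retained with probability given by the occupancy over the fragment:

* `retention="mean"` (default) — mean occupancy over the fragment.
  Appropriate when the protein is spread over spans comparable to or
  larger than the fragment length, as for a spreading wild type.
* `retention="max"` — maximum occupancy over the fragment. Appropriate
  for crosslink-then-shear capture of a point-like nucleation complex:
  binding happens on the intact chromosome, so after shearing the
  complex travels with *any* fragment overlapping its footprint, and a
  16-bp footprint should not be diluted by the ~10× longer fragment.
  This mode recomputes window maxima per distinct fragment length and is
  intended for fixed or few-valued length samplers.

**Affinity-capture fragments.** Lengths default to uniform 200–500 bp
(size-selected sonication). A proposal is retained only if it fully
contains at least one planted site, with probability
`θ = [P] / (Kd + [P])` for the strongest contained site (1:1 isotherm at
the capture concentration, default 320 nM); site-free proposals are
retained with a configurable background probability (default 0 —
perfect washing). Workflow fixtures use a small background (10⁻³)
because real captures carry nonspecific fragments and the caller's
automatic threshold is defined against that background.

**Tn5 insertion libraries.** Insertion positions are drawn independently
and proportionally to a per-base fitness landscape (inverse-CDF
categorical sampling), emulating colonies surviving selection; counts
are aggregated per position.

**SPR titrations.** Responses follow `Rmax · c / (Kd + c)` with additive
zero-mean Gaussian noise, on a default nine-point concentration grid of
6.25–800 nM.

## Coverage and normalisation

Coverage counts whole double-stranded fragments (the template molecules);
single-end reads are an upstream detail folded into the fragment
abstraction, and the BED strand field is ignored for fragments. Tracks
are normalised as RPBPM (`raw / (total_mapped / 10⁶)`, reads per base
pair per million mapped) or summed into bins for the per-kb variant
(RPKPM); both are linear, and binning commutes with normalisation.
Fold enrichment over a control uses a pseudocount (default 0.1 RPBPM) to
stabilise zero-control bases.

Two choices of `total_mapped` are meaningful:

* **per retained fragment** (standard): comparisons within one library,
  or against its own input control;
* **per proposed template** (`n_proposed`, yield-preserving): comparisons
  *between* pull-downs made from equal input material, where the amount
  of recovered DNA — hence effective sequencing yield — is itself the
  signal. Under per-retained normalisation, rejection sampling cancels
  any overall occupancy amplitude; yield-preserving normalisation keeps
  it.

## Nucleotide-resolution site calling

Every retained capture fragment contains the whole site, so no
upper-strand 5′ end (fragment start) can lie right of the site's first
base and no lower-strand 5′ end (rightmost base) can lie left of its
last base. Each strand's end-count profile is therefore a plateau ending
in an abrupt cliff exactly at a site edge, and the sequence between the
upper-strand and lower-strand summits is the minimal binding site.

`find_summits` implements the plain rule: local-maximum runs above a
height threshold, greedy suppression within a separation radius
(default 500 bp in the caller, wider than any single site's end-count
footprint at the default fragment lengths), and *directional*
tie-breaking on plateaus — rightmost maximal position for the upper
strand, leftmost for the lower — which pins summits to the site edges
on noiseless data.

On sampled libraries the plateau is flat only in expectation (with
minimum fragment length 200 bp the upper-strand counts are exactly flat
over the ~185 bases left of the site start), so the realised argmax
wanders uniformly over the plateau while the *cliff* stays fixed.
`call_sites` therefore refines each summit to the cliff edge: from the
raw summit it walks in the summit's direction as long as another
above-threshold position exists within a 10-bp lookahead (tolerating
short Poisson dips inside the plateau), stopping at the drop to
background. On noiseless plateaus the refinement is a no-op, and it
reduces to the directional tie-break rule.

Remaining choices: control end counts are scaled by the sample/control
fragment-count ratio and subtracted with flooring at zero (subtraction
is switchable); the default height threshold is 5× the genome-wide
median positive end count, capped at half the tallest count so that
background-free fixtures — where every positive count comes from the
site plateaus — remain callable; summit pairs form a call when the
inclusive span lies in [8, 40] bp, bracketing the 16-bp site against
end-count jitter, and unpaired summits are reported rather than dropped.
Calls carry the genomic sequence and an inverted-repeat match count
(positions where base i equals the complement of base n−1−i).

## ChIP quantification

* **Enriched regions**: maximal runs of signal at or above a threshold
  (default 2-fold enrichment over input), merged across gaps ≤ 500 bp,
  discarding runs < 200 bp. The 2-fold default is a choice; the assays
  describe "significant enrichment above background" without quantifying
  it, so the threshold is exposed in the API and CLI.
* **Spreading extent**: total length of the called regions containing an
  anchor (site or cluster centre). An anchor covered by no region raises
  a distinct error — extent is undefined, not zero.
* **Peak width** is support width above background, not FWHM: for pure
  nucleation coverage built from fragments of fixed length L fully
  containing a site of width w, the support is exactly `2L − w`
  (e.g. 400 bp for L = 208, w = 16), which ties the observed width of
  non-spreading mutant peaks to the fragment-length distribution.
* **Asymmetry**: ratio of above-background signal area over symmetric
  flank windows (default 5 kb) left vs right of the site.
* **Enrichment ratio**: ratio of mean signal over a region between two
  identically normalised tracks.

The wild-type vs spreading-deficient-mutant workflow compares a
spreading simulation (amplitude 1.0, mean-occupancy retention) against a
nucleation-only simulation (amplitude 0.2, max-occupancy retention —
the crosslink model above), both with 150-bp fragments, normalised per
proposed template, and takes the ratio of mean signal over the parS
site intervals. Each track's site-interval signal is then proportional
to its occupancy amplitude, so the ratio recovers amplitude ratios
(5-fold for 1.0 vs 0.2). Under per-retained normalisation this ratio
would be ~1 by construction (the amplitude cancels), and under
mean-occupancy retention the mutant's 16-bp footprint would be diluted
by roughly w/L ≈ 0.1; both alternatives measure properties of the
sampling scheme rather than of the protein, which is why the workflow
fixes these two choices.

## Tn-seq ratio track and zones

Insertion counts are binned (default 10 kb, half-open bins, partial
final bin kept), converted to frequencies (count/total, so sequencing
depths cancel) with a pseudocount of one insertion per bin, and compared
as `log10(parS⁺ freq / parS⁻ freq)` — *parS⁺* in the numerator. The
track is exactly antisymmetric under swapping the libraries.

Permissive zones are maximal runs of bins with log-ratio ≥ 0 (the
*parS*⁺ transposon inserts at least as frequently as the control),
merged across single below-threshold bins, at least 3 bins long;
disfavoured zones are the mirror image. The 0 threshold is the natural
reading of "tolerated" on a frequency-ratio scale; published zone
boundaries drawn by eye will differ at the bin level. Hotspots are bins
exceeding `median + 4 × 1.4826·MAD`; a constant track has degenerate
scale and is flagged (warning, no hotspots) rather than producing
spurious calls. Inversion remapping reflects positions inside
`[left, right)` to `left + right − 1 − position`; it is an involution
and preserves adjacency inside the segment.

## SPR fitting

The model is the 1:1 Langmuir steady-state isotherm
`R(c) = Rmax·c/(Kd + c)`; Hill or two-site models are out of scope, and
no kinetic sensorgram analysis is attempted. Fitting is unweighted
nonlinear least squares over (Kd, Rmax), both bounded positive, with
Kd₀ = the concentration whose response is nearest half the observed
maximum and Rmax₀ = 1.1× the observed maximum. The trust-region solver
runs with Jacobian-based parameter scaling and tight tolerances
(10⁻¹³), making fits equivariant under unit conversion (nM → µM divides
Kd by 10³) and response rescaling to ~10⁻⁸ relative. Non-convergence is
reported as `converged=False` with the solver message, never as a
silent bad fit; the Kd standard error is the asymptotic value from the
fit covariance.

## Problem sizes

The packaged workflows use desk-scale problem sizes chosen so that
sampling noise is a small fraction of each tolerance: the exhaustive
fixture enumerates all 16,610 containing fragments on a 10-kb genome;
site calling uses 200,000 retained fragments on the 1-Mb genome;
spreading-extent workflows use 100,000–200,000 fragments on 100–300-kb
genomes (the analyses are local to the parS neighbourhood, so shrinking
the uninvolved background only deepens per-base coverage); the Tn-seq
workflow uses 200,000 insertions per library on a 4-Mb chromosome.

## What the synthetic data do not capture

The generators emulate the statistical structure the analyses assume —
not sequencing itself. There is no read-error or base-quality model, no
alignment ambiguity or mappability variation, no GC or PCR bias, no
fragment-end sequence bias, and chromatin accessibility is uniform.
Occupancy is stationary (no cell-cycle mixture) and spreading is
strictly local and unidirectionally parameterised, whereas real
spreading is asymmetric and shaped by transcription. Consequently,
passing the recovery tests shows that the analyses invert the stated
generative models at realistic depths and geometries; it does not show
robustness to artefacts absent from those models. The weak-site height
ranking and the zone boundaries, in particular, would degrade first on
real data with nonuniform background.

## Known limitations

* Summit refinement assumes the site-free background is sparse relative
  to the height threshold; a structured background (e.g. copy-number
  variation) could shift a cliff edge by a few bases.
* Zone calling quantises to whole bins; a plateau misaligned with the
  bin grid is recovered to within one bin by construction.
* `retention="max"` recomputes sliding-window maxima per distinct
  fragment length and is impractical for broad length distributions.
* The default site calling threshold is heuristic; for libraries with
  atypical background levels it should be set explicitly.
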
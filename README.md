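# parbseq

Analysis toolkit for bacterial centromere biology: mapping *parS* sites
and ParB spreading from sequencing assays, and measuring ParB–*parS*
affinities from SPR titrations.

In many bacteria, chromosome segregation starts at *parS* — a short
(16 bp) palindromic, centromere-like sequence near the replication
origin. The ParB protein nucleates on *parS*, spreads onto flanking DNA
to form the partition complex, and is pulled to the opposite cell pole
by the ParA ATPase. `parbseq` implements the computational side of the
assays used to characterise such a system, for microbiologists and
bioinformaticians working with ParAB–*parS* (or similar nucleate-and-
spread) systems:

* **Nucleotide-resolution site calling** from in vitro affinity-capture
  sequencing (IDAP-type). Retained fragments must fully contain the
  binding site, so strand-sorted fragment 5′-end counts form plateaus
  that end in cliffs exactly at the site edges; the caller pairs the
  upper-strand summit *u* with the lower-strand summit *l* (rightmost-
  max / leftmost-max tie-breaks, cliff-edge refinement on noisy data)
  and reports the minimal site `[u, l]` with its sequence and
  inverted-repeat score.
* **ChIP-seq occupancy and spreading**: per-base coverage, RPBPM /
  RPKPM depth normalisation (`raw / (total_mapped / 10⁶)`),
  fold-enrichment over input, enriched-region calling, spreading
  extent, peak support width (`2L − w` for nucleation-only peaks built
  from length-L fragments), asymmetry and between-sample enrichment
  ratios.
* **Tn-seq permissive-zone mapping**: binned insertion frequencies of a
  *parS*-carrying vs an empty transposon compared as
  `log10(f⁺ / f⁻)` per 10-kb bin; permissive/disfavoured zone and
  hotspot calling; coordinate remapping across chromosomal inversions.
* **SPR affinity fitting**: equilibrium Kd from the 1:1 Langmuir
  isotherm `R(c) = Rmax·c/(Kd + c)` by bounded nonlinear least squares.
* **A synthetic-data generator** that plants palindromic 16-bp sites on
  toy circular genomes and draws ChIP, affinity-capture, Tn5 and SPR
  data with the statistical structure the analyses assume — the
  package's test bed and a convenient source of ground-truthed data.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

Call binding sites on the default 1-Mb toy genome (seven planted sites:
five strong, Kd 30–60 nM, and two weak, Kd ≥ 1 µM) from a simulated
200,000-fragment capture library, then fit a Kd from a noise-free
titration:

```python
import parbseq as pb

genome = pb.default_genome(seed=1)
library = pb.simulate_idap_fragments(
    genome, protein_conc=320.0, n=200_000, seed=7, background_prob=0.001
)
calls = pb.call_sites(library, None, genome)
print(f"{'start':>6} {'end':>6} {'len':>3} {'height':>6}  sequence         palindrome")
for c in calls:
    print(f"{c.site_start:>6} {c.site_end:>6} {c.length:>3} {c.height:>6.0f}"
          f"  {c.sequence}  {c.palindrome_hits}/16")

fit = pb.fit_kd(pb.simulate_spr_titration(kd=30.0, rmax=100.0))
print(f"\nKd = {fit.kd:.2f} nM  (Rmax = {fit.rmax:.1f} RU, converged = {fit.converged})")
```

Output:

```
 start    end len height  sequence         palindrome
  7492   7507  16     72  TTTCACAGGTGTGAAA  14/16
  6492   6507  16     69  TTTCACCCGTGTGAAA  14/16
  5492   5507  16     60  TTTCACACGTGTGAAA  16/16
  9492   9507  16     60  TTTCACTCGTGTGAAA  14/16
  8492   8507  16     57  TTTCACACGGGTGAAA  14/16
 10992  11007  16     14  TTTCACTCTAGTGAAA  14/16
  3992   4007  16      7  TTTCACACTAGTGAAA  12/16

Kd = 30.00 nM  (Rmax = 100.0 RU, converged = True)
```

All seven planted sites are recovered at exact nucleotide resolution
(every call is 16 bp and coincides with a planted interval), calls are
ranked by summit height, and the five strong sites rank above the two
weak ones — the same qualitative picture the assays give on real
chromosomes. The fitted Kd reproduces the generator's 30 nM exactly on
noise-free data.

A command-line interface mirrors the library for shell pipelines
(BED/bedGraph/FASTA/CSV in and out):

```bash
parbseq simulate --config experiment.yaml --outdir data/
parbseq idap call --sample data/idap.bed --genome data/genome.fasta --out calls.bed
parbseq coverage make-track --bed data/chip.bed --genome-length 1000000 \
    --normalize rpbpm --out chip.bedgraph
parbseq tnseq zones --plus plus.bed --minus minus.bed --genome-length 4000000 \
    --out zones.bed
parbseq spr fit --in titrations.csv --out fits.csv
```

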
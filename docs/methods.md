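# Methods

## Model and analysis chain

`polyhex` analyses a segmental allotetraploid whose four chromosome copies
divide between two parental subgenomes (labelled 9311 and Nipponbare
throughout, after the rice *indica*/*japonica* system the package is
modelled on). All inference starts from per-site homoeolog-specific read
counts at diagnostic SNPs — sites where the two parents are fixed for
alternative states, so every read can be attributed to one subgenome.

The chain is: (1) site filtering against balanced controls; (2) depth
painting and copy-number calling; (3) dosage genotyping and HE calling on
euploid individuals; (4) feature and recombination-rate tracks; (5)
correlation reports.

### Site filtering

Balanced control samples (reciprocal F1s, a 1:1 parental mix) have a true
1:1 read ratio at every site. A site is excluded genome-wide when, in any
control, the larger count is at least twice the smaller (the two-fold
boundary is inclusive: 20 vs 10 masks), or one side is 0 while the other
has ≥ 4 reads, or the control's total depth is below 2 (`low_coverage`).
The zero-side floor of 4 avoids masking on sampling noise at low depth: a
(0, 3) control site is compatible with 1:1 at depth 3, whereas (0, 4) has
one-sided probability 2⁻⁴. Masking is monotone — adding a control can only
remove sites — because all three rules are per-control disjunctions.

### Depth karyotyping

Per-site depth (both parents' counts summed) is averaged in fixed
[k·10⁶, (k+1)·10⁶) windows; windows with fewer than five contributing SNP
sites are excluded. Each window's depth relative to the genome-wide
per-site mean is assigned to the **nearest** rung of
{0.5, 0.75, 1.0, 1.25, 1.5} ↦ {−2, −1, 0, +1, +2}. Nearest-rung assignment
(rather than a one-sided threshold ladder) matters because the global mean
itself is inflated by an aberrant chromosome: a +2 chromosome among 12
sits near 1.44× the observed global mean, which is nearest 1.5 and must
not be mistaken for +1. Equidistant ties resolve toward the less extreme
state. The `delta` parameter (default 0.05) only annotates whether a
window lies within ±δ of its rung (`in_band`); it is reported, not used for
classification.

A chromosome's state is the modal window state when it covers ≥ 80 % of
classified windows, else 0; segmental events are maximal runs of ≥ 3
consecutive windows sharing a non-zero state different from the chromosome
call. The 80 %/3-window rules are this package's reproducible automation
of what is, in practice, often a manual depth-plot inspection; both are
configurable. Confidence is the fraction of classified windows agreeing
with the chromosome call. Events ≥ 3 Mb are always detectable under these
rules: a 3 Mb event misaligned to the window grid yields at least two full
windows plus one partial window whose mean depth still rounds to the event
rung whenever the overlap exceeds ~0.6 of the window.

### Dosage genotyping and HE calling

Kept sites are grouped per chromosome into bins of 10 consecutive SNPs;
a trailing remainder of ≥ 5 sites stands as its own bin, smaller remainders
merge into the previous bin. Pooled bin counts (a, b) are scored against
the five dosage hypotheses with expected 9311-read fraction
p ∈ {ε, ¼, ½, ¾, 1−ε} by the G statistic
G = 2[a ln(a/np) + b ln(b/n(1−p))] with 0·ln 0 = 0; the dosage minimising G
wins. Minimising G is identical to maximising the binomial log-likelihood
(they differ by a dosage-independent transform), so "lowest G, highest
p-value" is a single criterion at 1 df. Exact ties — measure-zero in
practice — resolve deterministically toward 2:2, then the smaller |d−2|,
then the lower d. ε (default 0.005, the scale of short-read
error/mismapping) keeps the 0:4 and 4:0 expectations away from the
degenerate 0/1 where G is undefined for any discordant read; ε must stay
below 0.25 for 0:4 to remain separable from 1:3.

Runs of equal genotype merge into fragments; fragments spanning fewer than
5 bins are removed; when removal leaves equal-genotype flanks adjacent they
re-merge and absorb the removed bins; the remove/re-merge pass iterates to
a fixpoint, the only order-independent reading of a single removal rule.
Each junction between surviving fragments of different genotype is one HE
region, spanning from the last SNP of the left fragment to the first SNP of
the right — an uncertainty interval that contains the true exchange point;
validation therefore checks containment of the true breakpoint in the
called region extended by one bin (the boundary bin can legitimately
genotype to either flank). Removed bins between different-genotype
survivors are absorbed into that interval. HE calling is restricted to
euploid individuals, because copy-number offsets move the expected allelic
fractions off the five-hypothesis lattice.

Window-scale HE frequency assigns each region one event to the window
containing its interval midpoint (keeping per-individual counts integral)
and divides by the number of individuals. Chromosome-scale HE burden is
the mean HE count per euploid individual.

### Feature tracks

Covered-base fractions merge overlapping intervals before summing, so they
are invariant to interval splitting. TE insertions are classified from
per-parent population frequencies: > 0.95 present, < 0.05 absent;
present/present is a shared TE, presence in exactly one parent a TIP, and
anything indeterminate is excluded. Indels of 1–99 bp are small and
≥ 100 bp large, so the two classes partition all lengths (the boundary
value 100 is assigned to the large class; the descriptive ">100 bp" and
operational "≥100 bp" conventions conflict in common usage and the
partitioning one is implemented).

### Marey map

Markers are curated per chromosome by collapsing duplicate physical
positions to their median cM and then retaining a longest non-decreasing
subsequence of cM values — the minimal removal achieving the monotonicity a
genetic map implies. A tricube-weighted local polynomial regression
(span 0.2, degree 2 by default, matching the smoothing used for the
profile figures) of cM on bp is evaluated at 1 Mb window midpoints; the
local polynomial's analytic first derivative — not a finite difference —
is the rate, clipped below at 0. Windows outside the marker span get no
value. On dense maps the integrated window rates reproduce the map length
to within a few percent (validated at ≤ 5 %); the residual is smoothing
bias at the rate profile's curvature extremes. Degenerate local fits
(duplicate abscissae after weighting) widen the bandwidth geometrically
before falling back to the nearest marker value with a warning.

### Association statistics

Pearson correlations use the exact t transform at n−2 df; pairs with a
missing value are dropped. The chromosome-scale report correlates mean HE
count per euploid individual against chromosome features across the 12
chromosomes (n = 12, small-sample t approximation, as is conventional for
such figures). The window-scale report correlates local HE frequency with
SNP/indel densities and TIP/shared-TE counts by class, in a fixed row
order, with two-tier significance stars (* p < 0.05, ** p < 0.01) and no
multiple-testing correction (deliberately mirroring the descriptive use of
these tables). The aneuploidy contrasts use a Yates-corrected 2×2
chi-square for proportions (equivalent to R's `prop.test`) and the exact
two-sided Fisher test; the two agree within 0.02 when all margins are
large.

## The synthetic-data generator

`simulate` draws, per chromosome of a 12 × 30 Mb rice-like genome:

- **SNP panel** — homogeneous Poisson process, default 1 SNP/kbp (the
  scale of *japonica*–*indica* divergence in syntenic regions).
- **Feature tracks** — genes, retrotransposons, DNA transposons and MITEs
  placed with radial density profiles (retrotransposons enriched around
  the chromosome-middle centromere proxy, genes and MITEs distally),
  reproducing the canonical rice layout and yielding ~22 % gene and ~29 %
  TE bases. Each TE carries per-parent frequencies (55 % shared, 20 % per
  TIP direction, 5 % intermediate).
- **Genetic map** — markers every ~200 kb on a monotone cM(x) whose rate
  is centrally suppressed (profile 0.05 + 0.95·t^1.5), mean 4 cM/Mb.
- **Individuals** — HE breakpoint count ~ Poisson(`mean_he_per_chrom`,
  default 3, an S2-like burden; ~7.5 matches a later-generation burden),
  positions sampled ∝ a per-window intensity track (uniform by default;
  an all-zero track falls back to uniform with a warning). Each breakpoint
  steps the 9311 dosage by ±1 — a single reciprocal crossover; multi-step
  transitions only arise from adjacent breakpoints — reflected at 0 and 4.
  Whole-chromosome gains/losses are drawn at `p_chrom_gain`/`p_chrom_loss`
  (default 0.04 each, matching ~19 events per 240 chromosome sets) and
  applied to one homoeolog chosen uniformly, shifting depth and allelic
  ratio jointly; segmental events (default p = 0.015, 3–10 Mb) likewise.
  When the chosen homoeolog has no copies in some segment of a mosaic
  chromosome, the copy-count clip effectively transfers the event to the
  other parent there — a simplification of duplicating one physical
  chromosome, which the generator does not track.
- **Counts** — at each site with local copy number c and effective 9311
  copies d: total ~ Poisson(depth · c/4), 9311 reads ~ Binomial(total, p)
  with p = (d/c)(1−ε) + (1−d/c)ε, ε default 0.005. `expected=True`
  replaces draws by rounded expectations (the infinite-depth limit used
  for round-trip checks).

Everything is driven by one `numpy` Generator seeded from `SimConfig.seed`,
so identical configs give byte-identical outputs.

What the generator does **not** emulate: read sequences and mapping (no
FASTQ), explicit meiosis across generations (generation labels only set
rates), GC/mappability depth waves, linked-read correlation between
neighbouring sites beyond the segment structure, and reference bias beyond
the symmetric ε. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness to
alignment artefacts — which is exactly what the control-based site filter
exists to absorb on real data.

## Validation problem sizes

The validation runs use: a 60 × 60 count grid for exact likelihood
equivalence; 10,000 bins per dosage class at 200 reads/bin for genotype
accuracy; 100 single-breakpoint 10 Mb chromosomes at 20× for HE recovery;
1,000 exchange-free 200-bin chromosomes for the false-positive rate; 20
individuals on the full 12 × 30 Mb genome (SNP density 0.5/kbp) for
karyotype recovery; and 20 individuals at 12 × 30 Mb, 1 SNP/kbp, 5
HEs/chromosome for the generative association check. These sizes give
standard errors comfortably inside every asserted margin while keeping a
full run in the order of a minute.

## Known limitations

- The karyotyper's 80 %-modal and 3-window rules are automation choices;
  heavily rearranged chromosomes (many large events) can defeat the modal
  logic.
- The HE caller reports every genotype transition as one exchange; gene
  conversion and double crossovers within a fragment are not distinguished.
- Aneuploid individuals are excluded from HE analysis rather than modelled
  with five-copy hypotheses.
- Marey rates inherit loess edge bias in the outermost windows; the
  curation step assumes errors are sparse enough that the longest
  non-decreasing subsequence is the signal.
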
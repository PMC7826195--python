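# Methods

## Scope and data model

The package analyses gene decay in a set of protein-coding genes from a
query lineage aligned to functional reference CDS. Internally coordinates
are 0-based half-open; GFF3 I/O converts to/from that format's 1-based
inclusive convention. Gene models (exon lengths, intron count, splice
dinucleotides) come from GFF3 + FASTA via gffutils/Biopython; minus-strand
CDS are reverse-complemented so every stored CDS reads 5'→3'. Aligned query
CDS use `-` for gaps; `N` is ambiguity, not gap.

## LoF mutation calling

Five classes are called on COMPLETE genes only: premature STOP, START loss,
STOP loss, frameshifting indel, splice-site disruption. Conventions that the
underlying data do not dictate, and that we therefore fixed:

- **Completeness**: a gene is INCOMPLETE (and excluded, with zero events
  reported) if any exon is wholly missing or more than 10% of aligned
  query columns are gapped/ambiguous. Discarding incomplete genes avoids
  conflating assembly gaps with true deletions; the 10% cut-off is our
  choice.
- **Frame convention**: query codons are read in reference-aligned
  coordinates. Premature stops downstream of the first frameshift are
  consequences of the shifted frame, not independent lesions, and are not
  counted — this prevents double counting in the total mutation count m.
- **Indels**: adjacent gap columns merge into one event; the net length
  (insertions minus deletions) decides frameshift status. In-frame indels
  are tallied separately and are not LoF.
- **Stop-to-stop** substitutions in the terminal codon are not events.
- **GC donors** are logged but not called (minor spliceosome splices them).

Events identical in gene, class, position and alleles across ≥2 species are
flagged as shared (candidate ancestral mutations).

## LoF rate estimation

Point-mutation class rates come from exhaustive enumeration of all 3L
single-nucleotide changes of a CDS under a two-parameter mutation model:
each site mutates at total rate μ split κ:1:1 across its three
alternatives, i.e. transition weight κ/(κ+2) and transversion weight
1/(κ+2) each, so per-site weights sum to one. Summed class weights divided
by L give per-site rates in units of μ. The splice-site rate is 4·introns/L
(2-bp canonical donor + acceptor per intron, every change disruptive). The
frameshift rate cannot be derived from point-mutation enumeration — it
reflects the indel spectrum — so it is an input (default 0.0143 μ per
coding site, a cavefish estimate); `calibrate_indel_rate_ratio` converts a
target frameshift rate into the simulator's per-site indel rate given the
indel length distribution. The per-gene rate is
μ_LoF,g = (Σ class rates) · L_g · μ.

Defaults follow the study conditions this package was built around:
κ = 4.57, μ = 10⁻⁸ per site per generation, mean CDS 1,091 bp, ≈5.8 introns
per gene — jointly giving μ_LoF ≈ 0.78×10⁻⁶ per gene per generation.

## Neutral-gene-count fit

The analytic per-gene distribution (README) assumes equal rates; the
simulation mode draws V genes uniformly without replacement and scatters m
mutations multinomially in proportion to per-gene LoF weights (10,000
replicates by default, 2.5/97.5% envelopes). The fit statistic is a
multinomial log-likelihood over the observed mutation-count classes
x = 0..K (K = largest observed count), with x > K pooled into a tail bin
that carries no observations. The original analysis judged fit visually, so
the statistic is our convention; because the likelihood typically plateaus,
results report the full profile and a 2-log-likelihood plateau range, not
just the argmax. With m = 0 the fit is flagged indeterminate.

## Dating

- **Pseudogene counts**: exact binomial pmf via log-gamma; closed-form MLE
  t̂ = ln(T/(T−D))/μ_LoF cross-checked against the grid argmax; the
  "probability > threshold" range (default 0.05) is found by bisection to
  relative precision 10⁻⁶ on each flank. D = T yields an unbounded result;
  D = 0 dates to zero. Generation-to-year conversion is a reporting option.
  Note that this range is a likelihood region, not a calibrated confidence
  interval: at T=76, D=19 its frequentist coverage of the true time is
  ≈77% (the sum of binomial probabilities of the D values whose pmf at the
  truth exceeds 0.05), which the test suite verifies against simulation.
- **Simulated dating curve**: genes mutate independently at their own
  μ_LoF,g; the curve is the fraction of replicates with exactly D observed
  pseudogenes per candidate t. An optional crude fixation lag treats a
  mutation as fixed only once it is older than 4·N_e generations,
  reproducing the expected insensitivity to N_e in the 100–1,000 range
  without a full Wright–Fisher engine (the substitution-clock approximation
  is valid because N_e ≪ 1/μ_LoF in the intended regime).
- **ω routes**: the mixed-branch interpolation and the mixture-proportion
  equation (README) are closed forms; both are invariant to the time unit.
  ω values themselves are inputs — estimating them from alignments (codeml,
  RELAX) is out of scope.

## Score mixtures

Neutral nonsynonymous substitutions are simulated by drawing sites uniformly
across the concatenated CDS (equivalently genes in proportion to length),
alternative bases with the κ weights, and rejecting synonymous and LoF
changes. The bundled scorer is Grantham's physicochemical distance: the
published integer table is authoritative, with the
composition/polarity/volume formula (α=1.833, β=0.1018, γ=0.000399,
ρ=50.723) kept as a cross-check — the printed table deviates from the
formula by more than rounding for two pairs (Trp–Asp, Glu–Asn), a known
quirk of the original publication. Machine-learning scores (e.g.
MutPred2-style, in [0,1]) can be supplied as per-substitution TSV tables;
the downstream statistics depend only on score samples.

Distributions are compared with the two-sample KS test (scipy; asymptotic
p-values, which are approximate for small samples). The mixture fit forms
the candidate ECDF as the p_s-weighted average of the selected and neutral
pool ECDFs — an analytic weighting rather than stochastic pooling, removing
one Monte-Carlo layer — and minimises the KS sup-distance over a p_s grid
(default step 0.01). Parametric resampling from the best mixture yields a
95% band on p_s.

## Synthetic data

The generator emulates a vision-gene-like set: CDS lengths gamma-distributed
in whole codons (default mean 1,091 bp, CV 0.45), intron counts Poisson
(mean 5.8), uniform sense-codon usage unless a table is supplied, ATG start,
single stop, canonical GT/AG splice sites, fixed 90-bp synthetic introns.
Evolution is a substitution clock: per-site Poisson substitutions at μ·t
with κ-weighted alternatives; indels at `indel_rate_ratio`·μ per coding site
with truncated-geometric lengths (mean 2 bp, support 1–12; in-frame indels
are generated but are not LoF). Under PURIFYING, LoF-creating candidates are
rejected and other nonsynonymous candidates accepted with probability ω;
under NEUTRAL everything fixes. Substitutions are applied before indels when
building the alignment, so at high indel rates a substitution can be erased
by an overlapping deletion; the ground-truth log classifies point lesions
from the final sequence state and skips codons overlapping indels, matching
the scanner's conventions.

What the simulator does *not* model — and hence what passing tests do not
demonstrate about real data: population-genetic drift trajectories and
segregating polymorphism (fixation is instantaneous or crudely lagged),
context-dependent mutation (CpG), rate heterogeneity along branches, gene
duplication/WGD, alignment error, and assembly artifacts beyond the
completeness filter.

## Numerical choices and reproducibility

All randomised operations take an explicit seed (NumPy `default_rng`); the
CLI defaults to seed 1 and echoes it. Binomial and multinomial pmfs are
evaluated in log space. Every CLI run writes a JSON manifest (inputs,
parameters, seed, package version) beside its outputs. Test-suite
simulation sizes (e.g. 10,000-replicate profiles, 200-replicate coverage
runs, ~850-gene rate calibrations) were chosen as the smallest sizes at
which the Monte-Carlo error is comfortably below the tolerance being
asserted.

## Known limitations

- Zygosity is not called; heterozygous LoF detection needs read-level data.
- Large deletions, promoter/regulatory lesions and in-frame indel effects
  are not classified as LoF.
- The frameshift class rate is an input, not an estimate.
- KS p-values are asymptotic.
- The pmf>5% dating range understates frequentist uncertainty (see above);
  treat it as the likelihood region it is.
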
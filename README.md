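# genedecay

Tools for quantifying and dating the decay of protein-coding genes after an
environmental shift relaxes purifying selection — the situation of
eye-specific, circadian-clock and pigmentation genes in cave vertebrates,
where loss-of-function (LoF) mutations accumulate by drift once a gene
becomes dispensable.

The package is aimed at molecular evolutionary biologists who have aligned
coding sequences of a candidate-gene set from a (possibly regressed) query
lineage and want to:

1. **call LoF mutations** per gene — premature STOP codons, START/STOP codon
   losses, frameshifting indels, disrupted GT/AG splice sites — with
   incomplete genes excluded;
2. **estimate the LoF mutation rate** μ_LoF per gene per generation from the
   sequence composition, the Ts/Tv ratio κ, and the exon/intron structure;
3. **infer how many genes evolve neutrally** from the distribution of LoF
   mutations per gene;
4. **date the relaxation of selection** by three independent routes;
5. **compare deleteriousness-score distributions** (Grantham distances
   bundled; external score tables pluggable) and fit the fraction of
   substitutions that accumulated under purifying selection.

A forward simulator (`genedecay.simulate`) generates gene sets with
realistic length/intron distributions and evolves them under neutral or
purifying regimes with a ground-truth mutation log, so every stage can be
validated against known inputs.

## The models

**LoF-per-gene distribution.** With `V` of `T` genes free to accumulate LoF
mutations and `m` mutations observed in total, the probability a gene
carries `X` mutations is

    p(X=0) = (V/T)(1 − 1/V)^m + (T − V)/T
    p(X=i) = (V/T) C(m,i) (1/V)^i (1 − 1/V)^(m−i),  i ≥ 1.

`NeutralGeneCountModel.fit()` profiles a multinomial log-likelihood over
candidate `V`; a simulation mode weights genes by their individual LoF rates
(CDS length, intron count).

**Pseudogene-count dating.** Under free accumulation, a gene fixes ≥1 LoF
mutation within `t` generations with probability `p(t) = 1 − exp(−μ_LoF t)`
(valid while N_e ≪ 1/μ_LoF), so `D` pseudogenes among `T` neutral genes is
Binomial(T, p(t)) and the maximum-likelihood time is

    t̂ = ln(T / (T − D)) / μ_LoF.

`PseudogeneDatingModel.fit()` returns the likelihood profile, the
closed-form MLE and the range of `t` with P(X=D) above a threshold
(default 5%).

**ω-shift dating.** A branch spanning a functional period then a neutral one
shows a duration-weighted dN/dS, so t_n/T_d = (ω_mixed − ω_f)/(ω_n − ω_f).
Alternatively, from the fitted fractions p_n/p_s of neutral/selected
nonsynonymous substitutions: t_n = T_d ω_s p_n / (ω_n p_s + ω_s p_n).

## Worked example

Dating relaxation from 19 vision pseudogenes among 76 genes, with μ_LoF
built from per-class rates of 0.031, 0.0143, 0.0212, 0.0028 and 0.0023 μ
per coding site, a 1,091-bp mean CDS and μ = 10⁻⁸:

```bash
genedecay date-pseudogenes --T 76 --D 19 --mu-lof 7.81e-7 --generation-time 4
```

prints

```
Pseudogene-count dating of relaxed selection
==============================================
T=76 neutral genes, D=19 pseudogenes, mu_LoF=7.81e-07 per gene per generation
MLE of time since relaxation: 368,351 generations
P(X=19) > 0.05 for t in (274,429; 481,748) generations
at 4 yr/generation: 1,473,404 years
```

i.e. selection on this gene set was fully relaxed roughly 370k generations
ago, with times between ~274k and ~482k generations keeping the observed
pseudogene count reasonably probable. The ω routes agree on the same
scenario:

```bash
genedecay date-omega --omega-functional 0.27 --omega-mixed 0.50 --Td 4.1 \
                     --ps 0.34 --pn 0.66
```

```
mixed-branch omega interpolation: neutral period t_n = 1.292 (t_n/T_d = 0.3151)
score-mixture proportion dating: neutral period t_n = 1.41 (t_n/T_d = 0.3439)
```

Both place the shift to neutrality at ~1.3–1.4 My of the 4.1 My since the
two lineages diverged — consistent with the generation-based estimate if a
generation takes ~4 years. The same computations are available as library
calls (`PseudogeneDatingModel`, `mixed_branch_time`,
`mixture_proportion_time`); `fit-neutral`, `scan`, `rates`, `simulate` and
`scores` cover the remaining stages.

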
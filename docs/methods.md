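# Methods

## Data model

Genotypes are an additive dose matrix: `dose[i, j]` = copies (0/1/2, NaN
missing) of the **minor** allele of marker *j* in sample *i*. The minor
allele is defined per marker from the in-sample frequency among non-missing
genotypes; an exact 0.5 tie designates the alphabetically first allele as
minor. This marker-indexed model carries no genomic coordinates — none of
the analyses need them — and VCF input is consumed for its GT field only
(multi-allelic records are skipped with a warning).

The APOE ε4 dose is derived from the two coding SNPs: ε4 requires
rs429358-C together with rs7412-C on the same chromosome, so with minor
dose nC (C at rs429358) and nT (T at rs7412) the ε4 dose is
min(nC, 2 − nT). The phase-ambiguous double heterozygote (nC = nT = 1) is
assigned ε2/ε4 (dose 1) by the standard convention; the alternative ε1/ε3
reading (dose 0) is available via a flag. In the default simulated cohorts
the ε4 dose is generated directly as a composite marker, since only the
haplotype dose enters any analysis; the two-SNP derivation is exercised by
its own unit tests.

## Marker QC

Call rate strictly > 0.80, MAF ≥ 0.01 (inclusive), Hardy–Weinberg exact
p strictly > 0.001 — strict versus inclusive follows the wording of the
inclusion criteria being modelled. The HWE test is the Levene–Haldane
conditional exact test: given the allele counts, the two-sided p is the
sum of probabilities of all heterozygote counts no more probable than the
observed one (computed in log space via `gammaln`; the test suite checks
it against full enumeration in exact rational arithmetic to 1e-12 for
n ≤ 200). Monomorphic markers return p = 1 and fail on MAF instead.

Whether the original analysis tested HWE in all subjects or controls only
is unknown, so both are provided. The bare QC interface defaults to all
samples (it has no phenotype information); the pipeline stages, which do
know the groups, restrict the HWE test to controls. The reason is a
Wahlund-style artifact the simulations make vivid: under the additive
retrospective model, case genotypes are themselves HWE at a shifted allele
frequency, so the case/control *mixture* carries a homozygote excess
exactly at strong risk loci — a pooled HWE filter can reject the one
marker the analysis is about (the planted OR-4.3 ε4 marker is rejected in
a nontrivial fraction of simulated cohorts). Controls-only testing is the
standard case-control practice for this reason. Call rate and MAF always
use all samples.

## Association scan

Per-marker logistic regression (intercept + dose), complete-case per
marker, no covariates — the modelled analysis names only "logistic
regression under an additive model". Fitting is delegated to
`statsmodels.Logit`; the Wald z uses the observed-information SE and the
p-value the two-sided normal tail, matching the STAT/P pairing convention
of standard association tooling (z = 4.83 ↔ p = 1.36e-6). An
independently hand-coded Newton/IRLS oracle in the test suite checks the
slope to 1e-6 on random fixtures, and the 2×2 closed form (Woolf SE) is
checked exactly on binary doses. Complete separation yields a flagged
result (p = NaN) that ranks last and is excluded from scoring; a constant
dose is an error. Ranking is ascending p, ties broken by |z| descending
then marker id, so score-set construction is fully deterministic.

## Risk scoring

- **LD**: squared Pearson correlation of doses over pairwise-complete
  samples (composite LD). This is phase-free and deterministic; at the
  r² > 0.8 cutoff it is an adequate stand-in for haplotype-EM r², which is
  a documented deviation risk for data where phase matters.
- **Pruning**: greedy scan in rank order; a marker is kept iff its r² with
  every already-kept marker is ≤ 0.8. This formalizes "keep the single
  most strongly associated marker of a linked set", which the source
  description does not define algorithmically.
- **Orientation**: risk allele = minor if OR ≥ 1 else major (OR = 1 keeps
  minor by convention), with the estimated OR recorded unchanged.
- **Scores**: unit weights (allele counting) by default; the score is
  Σ d′ / (2m) where d′ is the risk-allele dose and m the set size, i.e.
  the mean risk-allele fraction in [0, 1]. Missing genotypes contribute
  2 × in-sample risk-allele frequency (mean imputation, mirroring the
  classic SNP-scoring default); a complete-marker variant that shrinks the
  denominator instead is available. |log OR| weighting is an option, but
  unit weights are the default because the flipping rule is chiefly
  meaningful for unweighted counting; whether the original analysis
  weighted at all is not stated.

## ROC analysis

AUC by pair counting (ties half), computed via midranks; the standard
error and the paired set-vs-set comparisons use DeLong structural
components (per-case and per-control win rates; var = S10/m + S01/n).
The paired comparison is assumed — the samples are identical across nested
sets — and a degenerate variance returns z = 0, p = 1. The stopping rule
selects the first set whose two successors have consecutively lower AUCs
(AUC_{i+1} < AUC_i and AUC_{i+2} < AUC_{i+1}), falling back to the
maximum when it never fires; full-precision AUCs are used, since
two-decimal rounding makes the rule ambiguous. A literal variant
(AUC_i > AUC_{i+1} and AUC_i > AUC_{i+2}) is kept behind a flag: on the
reference increment series it would stop at 11 markers rather than the
selected 17, which is why the consecutive-decrease reading is the default.
Classification metrics use predicted-positive = score ≥ threshold.

## Decision trees

Predictors are binary (sex, cut ≥ 1), dose (cuts ≥ 1 and ≥ 2) and
continuous (age, one cut per distinct observed value; the minimum is
degenerate and dropped — observed-value cuts are used because nothing
restricts the original cuts to integers). The test-positive side of a
split is the side with the higher case fraction at fit time. Split quality
defaults to r·Se + (1−r)·Sp with kappa weight r = 0.5, the plain reading
of "a user-set weight of sensitivity and specificity"; the Kraemer
weighted-kappa quality index (ad − bc) / (r(a+b)(b+d) + (1−r)(a+c)(c+d))
is provided because the software family being modelled derives from that
methodology, and at r = 0.5 it equals Cohen's kappa.

Admissibility requires both prospective children ≥ 10 samples (missing
values joining the larger child, which is also where they are routed when
descending). The winning split must pass Pearson χ² (1 df, no continuity
correction) at α = 0.01 after Bonferroni correction over the predictors
evaluated at the node (default; per-cut correction selectable — the source
says only "multiple-testing-corrected"). Ties in quality break by
predictor manifest order then lower cut. The depth cap defaults to 4
successive splits because the modelled all-AD tree shows four split
variables on a path; 3 matches the literal "three-way interaction" wording
and is configurable. Node metrics are membership-based: treating node
membership as test-positive against the root sample, Se = cases-in-node /
all cases, Sp = controls-outside / all controls, PVP/PVN = case/control
fraction within the node. Whether the original software reported
membership-based or cumulative-classifier metrics is unknown; membership
metrics are what the exports carry.

Implementation equivalence with plain-loop exhaustive oracles (every
predictor × cut, and full recursive growth) is asserted on randomized
fixtures up to 50 rows and 6 predictors.

## Synthetic cohorts

The generator emulates the study conditions: 75 biallelic markers (the 20
published panel members with their MAFs, four named decision-tree markers,
and null fillers with MAFs evenly spread over [0.05, 0.45]); group sizes
283 controls / 126 AmnAD / 39 AtAD (global preset; stage presets also
carried); ages truncated-normal in [65, 101]; ~2% missingness. Controls
draw genotypes at HWE; cases of subtype s draw from HWE tilted by
exp(g·β_s), the genotype law implied by retrospective sampling under the
additive logit model — this matches the case/control design and avoids
simulating prevalence.

Planted effects are the study-calibrated per-allele ORs: APOE ε4 4.3 in
AmnAD, HFE rs1799945 2.83 in AtAD, all else null. Control-population MAFs
for the two effect markers (0.12 and 0.145) are set so that the pooled
cohort MAFs reproduce the published panel values (0.20, 0.15) under those
ORs; the APOE value also implies a control ε4 carrier rate of 22.6%,
matching the observed 22.3%. Demographics are *not* causal by default:
every group draws age and sex from the control distributions, so the
trees' genetic recovery is not confounded; per-group demographic shifts
(the published means/fractions) switch on with `demographic_effects=True`.
LD is absent by default; `plant_ld_proxy` appends proxies that copy a
parent marker with per-genotype resampling probability 1 − fidelity
(fidelity 0.95 gives r² ≈ 0.9).

What passing tests on these cohorts do **not** show: robustness to real
LD structure, population stratification, genotyping batch effects,
haplotype-level effects, or age/sex confounding — none of which the
generator produces.

## Experiment sizes

The replication experiments use 100 replicates each: parameter recovery at
the study's 185 cases / 283 controls; structure recovery at 150 cases vs
283 controls per subtype (a case count chosen so the experiment measures
architecture recovery rather than small-sample power — at the atypical
stratum's n = 39 the corrected-χ² root test itself is under-powered);
two-stage overfitting at the full default cohort with a 192:276 stage
split. The full test suite runs in about a minute on one CPU.

## Known limitations

- The composite-LD r², unit-weight scoring and membership-based node
  metrics are documented interpretations of under-specified steps; each
  has a configurable alternative.
- Separation-flagged markers are dropped from scoring rather than
  penalized-regression rescued (out of scope).
- The Bonferroni denominator for the association scan is an explicit
  input (defaulting to the panel size), since the number of markers
  surviving QC in the original analysis is not printed.
- Validation-stage score imputation uses validation in-sample risk-allele
  frequencies; the scoring file (markers, alleles, weights) is frozen, the
  imputation frequencies are not part of it.
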
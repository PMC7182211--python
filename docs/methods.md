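# Methods

This note documents the models implemented in `sccoalsim`, the defaults and
numerical choices, what the simulator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Time scale and genealogy

Internal coalescent times are in units of `N0` generations (Kingman
scaling): with `k` ancestral lineages the constant-size waiting time is
exponential with rate `k(k−1)/2`, so `E[TMRCA] = 2(1−1/n)` and
`E[total length] = 2·Σ_{i<n} 1/i` hold exactly and serve as analytic test
oracles. Conversion to generations multiplies by `N0`.

**Variable population size** is handled by the cumulative-intensity
transformation. Exponential growth uses the backward size
`N(t) = N0·e^{−G t}` with `G = g·N0` (`g` is the per-generation rate, flag
`-g`), giving the closed forms `Λ(t) = (e^{Gt}−1)/G` and
`Λ⁻¹(u) = log(1+Gu)/G`. Multi-period demographies compose per-period
closed-form intensities piecewise; periods are `(start, end, size, growth)`
tuples going backward from the present, contiguous from 0, with the last
regime extended to infinity at its final size.

**Cancer parameterization.** The coalescent for an exponentially expanding
tumor with overlapping generations is implemented as the exponential-growth
coalescent with `g = birth − death` on a continuous-time scale. Only the
difference of the rates affects the genealogy here; exposing birth and
death separately keeps the epidemiological interpretation while the
distribution matches the growth coalescent (checked by two-sample KS tests).
This is an approximation of the full birth–death sampling process: near
`birth ≈ death` second-order effects of the death rate on the time scale
are not modeled.

**Root and outgroup.** The root branch (sMRCA→oMRCA) has length
`root_ratio × depth(sMRCA)` and the outgroup branch (oMRCA→outgroup tip)
`outgroup_ratio × depth(sMRCA)`; a ratio of 0 suppresses the element. The
outgroup tip's age is set so branch lengths stay consistent with node ages,
so it generally does not sit at age 0 — the decorated tree is not
ultrametric, which is intentional (the outgroup is a reference device, not
a contemporaneous sample). Whether lineage rate multipliers apply to the
root/outgroup branches was open; they do (every branch gets an independent
mean-1 gamma multiplier with shape `alpha`, variance `1/alpha`), which
preserves expected tree length and treats all branches uniformly.

## Mutation models

The ancestral genome at the root is homozygous, drawn iid from π (or a user
FASTA used verbatim for both haplotypes). Germline variants make each site
heterozygous independently with the given rate; the altered haplotype is
uniform and the target allele follows the relative-rate row of the current
allele. Somatic SNVs are allowed to hit germline-variant sites (the event
log flags them), and cnLOH may overwrite a site carrying a somatic SNV —
both cases are biologically possible and the simpler bookkeeping.

**Placement.** SNV counts per branch are multinomial ∝ branch length for a
fixed total `j`, or Poisson(rate × length) in rate mode. The configuration
flag `-u` is a per-site per-generation rate `u`; the genome-wide rate per
unit branch length used internally is `u·l·N0`, which makes Watterson's
`E[S] = u·l·N0·2Σ1/i` the test oracle. The outgroup branch never receives
somatic events (every event must be visible in at least one sampled cell);
the root branch does.

**Diploid ISM.** Each mutation hits a uniformly chosen previously unmutated
site on a uniformly chosen haplotype; requesting more mutations than sites
raises an explicit exhaustion error. Binary ISM flips 0→1 only.

**Trinucleotide signatures.** Channels follow the standard 96-way layout
(six pyrimidine substitution types × 5′ × 3′ flank). Contexts are read off
the maternal ancestral haplotype; purine sites are reverse-complemented so
mutations are recorded by the pyrimidine of the Watson–Crick pair. Terminal
sites (no 5′ or 3′ neighbor) are excluded. Context availability is
maintained against the ancestral genome and sites are consumed as they
mutate (consistent with ISM: each site mutates once); each event's channel
is drawn from the signature restricted and renormalized to contexts with
unmutated sites remaining. The bundled catalogue
(`data/signatures_synthetic_96.tsv`) is a **synthetic** stand-in with the
structure of published single-base-substitution catalogues (30 signatures ×
96 channels, rows summing to 1); any real catalogue in the same TSV layout
can be passed to the loader.

**Finite-site models.** `Q` is built as `q_ij = r_ij π_j` for reversible
models (JC/HKY/GTR/Mk2 as special cases) or from the raw 12-parameter rate
matrix for the nonreversible model, whose π is computed as the stationary
left null vector. `Q` is normalized to mean rate 1 so branch lengths are
expected substitutions per site. Simulation uses one eigendecomposition of
`Q` and vectorizes `exp(Qt)` over per-site times (branch length × gamma
site-rate multiplier); rows are clipped at 0 and renormalized to absorb
eigen-solver noise (~1e−15). This is exact, unlike Gillespie-style event
simulation, and fast enough to evolve 10⁵ sites per branch. The public
`fsm_transition_matrix` uses `scipy.linalg.expm` directly.

**cnLOH and deletions** are placed like SNVs with their own counts/rates
under a haploid ISM (a (site, haplotype) slot is used at most once per
event type, capacity `2l`). Events apply during a single pre-order
traversal in the order SNV → cnLOH → deletion per branch, so a deletion
silences the haplotype regardless of earlier events, and a cnLOH copies the
allele state *at the ancestor where it occurs* (later SNVs on the source
haplotype in descendant branches are not retro-copied). An SNV targeting an
already-deleted allele is skipped.

## Noise model

Beta-distributed quantities (varying ADO, allelic imbalance, amplification
error, doublet mixing) are parameterized by mean and variance and converted
to shape parameters internally; `variance = 0` means a degenerate constant,
and `var ≥ mean(1−mean)` is rejected. The `per_cell_and_site` ADO mode
draws an independent δ per cell-site pair.

Coverage is Poisson(mean) or NB(size = dispersion, mean), so
`variance = mean + mean²/dispersion` and infinite dispersion recovers the
Poisson. Sites with exactly one amplifiable allele — whether by dropout
*or by deletion*, the physical cause is the same single template — have
their mean multiplied by `haploid_reduction` (default 0.5); sites with no
amplifiable allele get depth 0 (nothing to amplify).

Amplification error γ is drawn once per cell-site from its beta and shared
by all reads of that site (the error propagates through the template pool);
sequencing error ε is per read. In the four-template model each read's
template is an independent draw from the γ-mixture over all four bases; in
the two-template model the identity of the single wrong template is drawn
once per cell-site-allele from the direction matrix `e`, and each read
comes from it with probability γ. Read-level marginals match the
closed-form `p(b|A)` of the likelihood module in both modes — the central
cross-module consistency property, verified on ~10⁶ simulated reads.

Doublets keep the original cell's total depth (a doublet library is
sequenced to one depth): at each site each read stays the cell's own with
beta-binomial probability and is otherwise redrawn from the partner's base
distribution. Partners are uniform among the other cells, with replacement
across doublets.

## Likelihoods and calling

All computation is in log space from base counts (reads are exchangeable).
Per-base probabilities are floored at 1e−300 purely to keep logs finite
when ε = 0 meets an impossible read; this never changes an argmax at
realistic parameters. Ties (log-likelihoods within 1e−9 of the maximum) and
zero-depth sites are reported as no-calls with distinct status flags rather
than resolved arbitrarily, so error metrics cannot depend on enumeration
order. The δ used for calling is a user constant defaulting to the
simulation's mean ADO — the caller does not know the per-site truth. The
ADO mixture is implemented exactly as stated (the haploid terms are not
renormalized for the haploid coverage reduction). The binary alphabet uses
3 genotypes and 2×2 direction matrices; `ε/3` generalizes to `ε·e[A,b]`.

## Outputs

The VCF (4.2) has one record per variant site (all sites with `-x`); REF is
the ancestral oMRCA allele, ALT lists every allele seen in reads, truth or
calls at the site. Observed data go in standard fields (GT/DP/RC/GL, GL in
log10); truth is namespaced (TG true genotype, ZA ADO flags, ZD doublet
flag) so it never contaminates standard fields. Missing calls are `./.`;
sites haploid by deletion keep a diploid-coded GT with the deletion visible
in TG. The binary alphabet is encoded as A(0)/C(1) to keep the VCF valid.
Genotype matrices use IUPAC codes (lowercase for a haploid site, `-` for
both-deleted, `?` for no-call). Floats print with 6 significant digits for
byte stability; every run writes a `run_log.txt` with the full effective
parameter set, and replicate `i` uses the RNG stream seeded by
`(seed, i)`, so any replicate is reproducible in isolation.

The paper-style usage flag `-p` is accepted and stored but has no effect
(its meaning is undocumented); germline variants use `--germline-rate`.

## Benchmark metrics

`CallMetrics` reports, per replicate: `genotype_error` — the fraction of
*called* genotypes whose unordered allele pair differs from truth (NaN if
nothing is called); `proportion_called`; `recovery_error` — the fraction of
all cell-site entries whose true genotype is not correctly called (a
missing genotype counts as not recovered); and true/called SNV counts,
where a site counts as a called SNV when at least one cell's called
genotype carries a non-ancestral allele (truth analogously). The outgroup
is excluded from all metrics.

The two error definitions diverge at low depth: heterogeneous coverage
(small NB dispersion) leaves more entries uncalled but concentrates the
called ones at higher depth, so at 1× the *called-only* error can decrease
with heterogeneity while genotype *recovery* monotonically worsens. The
coverage-heterogeneity trend checks therefore use `recovery_error`; the
called-only error remains the headline per-call accuracy.

## Problem sizes used in the checks

The quantitative test suite uses 10⁴ genealogy replicates for coalescent
expectations, ~10⁶ simulated reads for the read-model closed forms, 100
replicates of the 100-cell × 100-site experiment for ISM conservation, and
50 replicates per scenario for the 12-scenario grid comparisons — sizes at
which the 3-SE Monte-Carlo bands are decisive while the whole suite runs in
well under a minute per check.

## Known limitations

No copy-number gains, multi-base indels or structural variants; no
selection, population structure or recombination; no spatial correlation of
coverage along the genome (sites are independent); no read-level FASTQ or
base-quality simulation; no posterior genotype calling with population
priors. The synthetic-signature fixture reproduces the format, not the
biology, of real mutational-signature catalogues, so signature-model tests
demonstrate the sampling machinery rather than any real mutational process.
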
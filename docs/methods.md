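# Methods

## Splicing quantification

Coordinates are 0-based half-open throughout (BED convention); SAM's
1-based `POS` is converted on ingest. CIGAR strings reduce to aligned
reference blocks: `M/=/X` extend the current block, `D` is merged into it
(a deletion does not break contiguous reference coverage), `N` splits
blocks, and `I/S/H/P` consume no reference.

For an intron `[s, e)` a read is **spliced** when one of its block gaps is
exactly `(s, e)` and both flanking blocks align at least `min_overhang`
bases (default 6, common junction-counting practice; exact boundary match,
no ±2 fuzz, so the rule is conservative and directly testable). A read is
**unspliced** when a contiguous block covers `s` or `e` with
`min_overhang` bases on each side, or lies entirely inside the intron; both
unspliced sub-rules are counted by default and each is switchable, since
conventions differ between pipelines. A read counts at most once per
intron, spliced taking precedence; reads on other chromosomes are skipped.
Counting is unstranded by default. Reads under a mapping-quality threshold
(default 10) are excluded on ingest as a multi-mapper proxy.

Cassette exons are quantified from three junctions (upstream-inclusion,
downstream-inclusion, skipping) with the same gap rule, and
PSI = 100·mean(incl_up, incl_down)/(mean + skip); the mean of the two
inclusion junctions is the symmetric, standard choice. PSI is undefined
(raises) on all-zero input.

## Differential testing

Counts for one event — spliced and unspliced across replicates of two
conditions — are modelled as negative binomial with mean–dispersion
parameterisation Var = μ + αμ² (α = 0 is Poisson) and log link:

    log μ = β₀ + β₁·read_class + β₂·condition + β₃·read_class·condition

β₃ is the change in log spliced:unspliced odds between conditions
(reported as log2). α is estimated per event by pooled method of moments
across the four design cells, floored at 1e-8. The full model is saturated
in the four cell means, so its maximum likelihood is closed-form; the
reduced (no-interaction) model is fitted by IRLS (convergence: relative
log-likelihood change < 1e-12, max 100 iterations; numerically-zero LR
statistics below 1e-8 are clamped to 0 so identical groups give p = 1
exactly).

**Small-sample reference distribution.** With α known, the likelihood-ratio
statistic is well calibrated against χ²₁ (empirical type-I 0.049 at nominal
0.05 in a 3v3 null simulation). With α estimated from the same 12
observations it is anti-conservative (0.084). The statistic is therefore
referred to F(1, d), d the residual degrees of freedom behind the
dispersion estimate (Σ per-cell (n−1); 8 for 3v3), in the spirit of
quasi-likelihood F-tests; this restores calibration (0.047, and the null
p-value distribution passes a Kolmogorov–Smirnov uniformity check) and
converges to the χ² test as replication grows.

Gene-level testing uses median-of-ratios size factors (geometric-mean
reference over genes positive in all samples, factors rescaled to
geometric mean 1 — note this makes factors invariant, not equivariant, to
global count rescaling) and a per-gene NB Wald test with the size factors
as offsets. With few replicates the Wald p-values are slightly
conservative because the per-gene dispersion estimate is noisy and floored;
tests assert exactness for degenerate (duplicated-column) input and
non-anticonservativity under the null rather than exact uniformity.

Multiple testing uses Benjamini–Hochberg step-up (delegated to
statsmodels; validated against a brute-force O(m²) implementation of the
definition). The two comparisons (knockdown vs control, rescue vs
knockdown) are combined by Fisher's method — X = −2(ln p₁ + ln p₂) against
χ² with 4 df; zero p-values are clamped to the smallest positive float. A
Stouffer alternative was considered and rejected to keep one canonical
path; combined evidence (not both-significant) is the meta criterion, with
the knockdown padj threshold enforcing marginal significance where it
matters (see below).

**Rescue classification.** Events are ranked by meta p (ties broken by
|knockdown effect| descending, then event id). Among the top N (default
1000), an event is *rescued* when its knockdown change is significant
(padj < α, default 0.05), its rescue-comparison change is significant, and
the two effects have opposite signs — i.e. any significant reversion
counts; full restoration to control levels is not required. Direction is
the sign of the knockdown effect for significant events, so down + up
equals the significant count.

## Autoregulation bookkeeping

Percent inclusion is 100·incl/(incl + skip); optional molar correction
divides each signal by its amplicon length first (off by default, as gel
densitometry is typically reported uncorrected). The NMD degraded fraction
assumes steady state and complete inhibition: if inhibition multiplies the
observable pool by f ≥ 1, the fraction degraded under normal conditions is
(1 − 1/f)·100 — exactly 66.7% at f = 3 (commonly rounded to "about 66%").
ΔΔCt uses replicate-averaged Cts and PCR efficiency 2 by default
(configurable). Welch's t test uses the Welch–Satterthwaite degrees of
freedom and is intended for natural-log-transformed spliced:unspliced
ratios, whose variances typically differ between conditions.

## Binding thermodynamics

The one-site isotherm is the standard closed form above; its bound-ligand
concentration is the stable root of Kd·B = (nM_t − B)(X_t − B) and is
validated against an independent numeric root-finder to 1e-10 relative.
Injection heats track dilution with the displaced-volume bookkeeping
M_t = M₀(1 − v/2V₀)/(1 + v/2V₀), X_t = X₀(v/V₀)/(1 + v/2V₀) (v =
cumulative injected volume) and ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2,
normalised per mole of injectant by default. Default geometry: 1.4 mL
cell, 40 × 6 μL injections, 10 μM macromolecule in the cell, 250 μM
titrant in the syringe, T = 313 K.

Fitting is nonlinear least squares over (log K_d, ΔH, n) — log space
enforces positivity and conditions the optimisation. The first injection
is excluded by default (syringe-diffusion convention; simulation keeps
it). Auto-initialisation takes n from the molar ratio at the steepest heat
change, ΔH from the earliest retained injection, and K_d at c ≈ 10.
Isotherms with no heat signal are returned flagged unidentifiable rather
than fitted; a c-value (n·M₀/K_d) outside [1, 1000] triggers a warning
that K_d is poorly constrained. Standard errors come from the Jacobian at
the optimum (delta method for K_d).

ΔG = RT·ln K_d with R = 1.987×10⁻³ kcal/(mol·K) and −TΔS = ΔG − ΔH, so
ΔG = ΔH + (−TΔS) holds identically. Published decompositions are not
always self-consistent with their K_d; `check_thermo_consistency` flags
triples violating the identity beyond a tolerance (default 1 kcal/mol)
instead of propagating them — K_d is treated as the ground truth.

Combined CSPs: amide √(Δδ_H² + (α_N·Δδ_N)²) with α_N = 0.15; carbonyl
α_C·|Δδ_C′| with α_C = 0.25 (common normalisations; both configurable).
Titration fits use the ligand-depletion quadratic for the bound fraction,
f_b = ((P+L+K_d) − √((P+L+K_d)² − 4PL))/(2P), with a shared K_d and
residue-specific saturation amplitudes; for fixed K_d the amplitudes are
the exact linear least-squares solution, so only log K_d is profiled
numerically (bounded scalar minimisation over 1 nM–100 mM). A final point
below 50% saturation downgrades the fitted K_d to an upper bound
(warning). At the default design (200 μM protein, K_d ≈ 9 μM), 1.5-fold
ligand excess gives ~93% saturation — the regime where such titrations are
typically stopped.

## Synthetic data

The generator emulates the three-condition knockdown–rescue design: ctrl,
kd, and rescue, each with 3 replicates. Counts are NB(μ, α) via the
mean–dispersion convention; effects are injected on the logit of the
spliced (or inclusion) fraction so that depth and splicing-efficiency
changes stay orthogonal, and the rescue condition reverts a fixed fraction
of the knockdown effect multiplicatively (rescue effect =
−rescue_efficiency × knockdown effect). Baseline intron spliced:unspliced
log-odds vary across events as N(1.5, 0.5) (≈80% spliced — mostly
efficient constitutive splicing).

Defaults, chosen once as a realistic bulk RNA-seq regime and held fixed:
mean depth 100 reads/event, dispersion α = 0.05, 30% truly dependent
events, knockdown effect |log2 odds change| ~ |N(2.0, 0.5)|, 85% of
dependent intron-retention events losing splicing efficiency (the
knockdown-dominant direction observed for this class of factor),
rescue efficiency 0.9. Library depth and dispersion are free parameters of
the design — no published per-event values exist to pin them.

Simulated reads are coordinate skeletons only (no bases or qualities):
two-block alignments excising the intron exactly for spliced reads,
contiguous boundary-crossing or fully-intronic blocks for unspliced reads;
by construction they round-trip through the counter. ITC and CSP
simulators share the forward models above, adding Gaussian noise.

What passing tests show — and what they do not: the synthetic data carry
no mapping ambiguity, no GC or fragment-length bias, no correlated
replicates, no isoform complexity, and injected effects follow the model
family being fitted. Recovery results therefore validate the statistical
machinery and its calibration, not robustness to real-library artefacts.
On real data the NB-with-moment-dispersion assumption and the exact-match
junction rule are the two places to scrutinise first.

## Problem sizes and determinism

Monte-Carlo checks use 2000 null events for calibration, 1000–4000 events
for rescue recovery, and 25–50 replicate fits for noisy-isotherm and
titration recovery; all are sized to make the binomial/median criteria
sharp while keeping the full suite fast. All randomness flows from
explicit integer seeds (one generator stream per dataset); identical
configuration and seed reproduce tables bit-identically, and every output
table carries the run-manifest hash in a comment header.
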
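# splicerescue

Analysis toolkit for knockdown–rescue splicing experiments, built around the
biology of splicing-factor autoregulation through a poison exon: a factor
(here modelled on RBM39) promotes inclusion of a premature-termination-codon
exon in its own pre-mRNA, routing the transcript to nonsense-mediated decay
(NMD) and closing a negative feedback loop. The package covers the full
quantitative chain of such a study:

- **Splicing quantification** — per-intron spliced/unspliced read counts
  from spliced alignments (SAM, CIGAR `N` gaps), splice ratios, and
  cassette-exon percent spliced in (PSI) from the three event junctions.
- **Differential testing** — a negative-binomial interaction GLM on
  (read class × condition) counts whose interaction term is the change in
  log spliced:unspliced odds, tested by a likelihood-ratio statistic with a
  small-sample F correction; Benjamini–Hochberg adjustment; Fisher meta
  p-values combining the knockdown-vs-control and rescue-vs-knockdown
  comparisons; rescue and directionality classification among the most
  significant events.
- **Autoregulation arithmetic** — percent poison-exon inclusion, the NMD
  steady-state relation `degraded fraction = 1 − 1/fold`, ΔΔCt relative
  quantification, and Welch's unequal-variance t test on log ratios.
- **Binding thermodynamics** — the closed-form one-site (1:1) ITC isotherm
  `Q = nM_tΔHV_0·(b − √(b² − 4X_t/nM_t))/2` with `b = 1 + X_t/nM_t +
  K_d/nM_t`, displaced-volume injection heats, nonlinear (log K_d, ΔH, n)
  fitting with c-value diagnostics, ΔG = RT·ln K_d decomposition, combined
  NMR chemical-shift perturbations `√(Δδ_H² + (0.15·Δδ_N)²)`, and global
  fast-exchange titration K_d fits under ligand depletion.
- **Synthetic data** — a generator for all of the above with known ground
  truth (NB counts with effects injected on the spliced:unspliced log-odds,
  partial rescue reversion, simplified SAM alignments, noisy isotherms and
  titrations), so every stage is testable end to end.

Intended users: computational biologists quantifying intron retention or
cassette-exon regulation in perturbation–rescue designs, and structural
biologists fitting ITC/NMR titrations alongside.

## Worked example

Run the end-to-end pipeline on a simulated knockdown–rescue experiment
(1000 intron-retention events, 3 conditions × 3 replicates):

```bash
splicerescue run --seed 42 --out demo
```

```json
{
  "n_events": 1000,
  "top_n": 1000,
  "n_significant": 205,
  "frac_rescued": 0.151,
  "frac_down": 0.8731707317073171,
  "frac_up": 0.12682926829268293,
  "manifest": "64afc8ede641"
}
```

205 of 1000 events change significantly upon knockdown (the generator's
default makes 30% truly dependent, many with effects too small to detect at
depth 100); 87% of the significant changes are losses of splicing
efficiency, matching the generator's 85% down-direction setting, and 15.1%
of all events are both significant and significantly reverted in the rescue
condition. All outputs carry the manifest hash for provenance.

The NMD bookkeeping and a one-site ITC fit from the command line:

```bash
$ splicerescue autoreg nmd --fold 3
66.7
$ splicerescue simulate itc --seed 1 --out demo-itc
$ splicerescue itc-fit --isotherm demo-itc/isotherm.csv
{"kd_um": 9.0, "dh_kcal_mol": -8.0, "n": 1.0, "dg_kcal_mol": -7.226,
 "minus_tds_kcal_mol": 0.774, "c_value": 1.11, "identifiable": true}
```

A 3-fold transcript increase upon NMD inhibition implies two thirds of
transcripts are degraded at steady state; the noiseless simulated isotherm
(K_d = 9 μM, ΔH = −8 kcal/mol) is recovered exactly and decomposed into
ΔG = −7.23 kcal/mol and −TΔS = +0.77 kcal/mol at 313 K.

Library use mirrors the CLI:

```python
from splicerescue import SimConfig, simulate_ir_counts, ir_difftest, classify_rescue

counts, truth = simulate_ir_counts(SimConfig(n_events=500, seed=1))
kd = ir_difftest(counts, "ctrl", "kd")
rescue = ir_difftest(counts, "kd", "rescue")
calls, summary = classify_rescue(kd, rescue, top_n=500)
```

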
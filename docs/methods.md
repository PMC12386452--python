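# Methods

## The model

The network treats H₂O₂ as the central state variable, fed by a constant
influx `H2O2_IN` (a surrogate for steady mitochondrial/peroxisomal
production) and drained by three parallel systems: catalase
(bimolecular, kCAT·H2O2·CAT), glutathione peroxidase (trimolecular,
kGPX·H2O2·GSH·GPX) and peroxiredoxin (bimolecular, kPRDX·H2O2·PRDX).
The enzymes CAT, GPX, GSR and TXNRD are constant pools; the redox
couples GSH/GSSG, PRDX/PRDXox and TXN/TXNox evolve but are conserved
(reduced + oxidized = total). Recycling is mass action: GSR reduces
GSSG, TXN reduces PRDXox, TXNRD reduces TXNox. The model is
deliberately minimal: no compartments, no Fenton chemistry or
superoxide, no PRDX hyperoxidation, no feedback of H₂O₂ on enzyme
expression, and no stochasticity — it represents an average redox state
of a cell type, not single-cell dynamics.

Because the published couple equations give only the oxidized-side
balances explicitly, the reduced-PRDX balance is taken as the exact
negative of the PRDXox equation — the only choice consistent with the
stated conservation of the PRDX pool.

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| kCAT | catalase rate constant | 0.034 | mM⁻¹ ms⁻¹ |
| kPRDX | PRDX oxidation | 0.26 | mM⁻¹ ms⁻¹ |
| kTXN | PRDXox reduction by TXN | 0.23 | mM⁻¹ ms⁻¹ |
| kTXNRD | TXNox reduction by TXNRD | 0.31 | mM⁻¹ ms⁻¹ |
| kGSR | GSSG reduction by GSR | 0.08 | mM⁻¹ ms⁻¹ |
| kGPX | GPX peroxidase (trimolecular) | 67 | mM⁻² ms⁻¹ |
| CAT, GPX, GSR, TXNRD | enzyme pools | 0.001, 0.05, 0.05, 0.025 | mM |
| PRDX_total, TXN_total, GSH_total | couple totals | 0.15, 0.025, 3.0 | mM |
| H2O2_IN | influx | 1e-5 | mM ms⁻¹ |

The default set is the literature-derived parameterization the scaling
refers back to (the reference cell line has all scaling factors equal
to 1). The symbol printed `kTXN_ox` in the source parameter table is
the kTXN of the couple equations; the same quantity under two names.
At these defaults the GPX/GSH system dominates: its initial removal
slope (kGPX·GPX·GSH_total ≈ 10 ms⁻¹) exceeds the PRDX slope
(kPRDX·PRDX_total ≈ 0.039 ms⁻¹) by ~260× and the CAT slope
(3.4e-5 ms⁻¹) by ~3e5×, which is why knockout pairs containing GPX are
numerically indistinguishable (≤0.4% at defaults) from GPX alone. The
2% band used in the dominance test is a deliberate, a-priori bound on
that slope ratio across moderately perturbed profiles.

### Knockout semantics

"Switching off" a pathway zeroes its H₂O₂-consumption term *and* its
couple's entire turnover (both oxidation and recycling legs). Starting
from the fully reduced default state this is algebraically identical to
zeroing the pathway's peroxidase rate constant; the couple simply stays
at its initial composition.

## Numerics

* **Integration.** The stiff system (rates span 3.4e-5–10 ms⁻¹) is
  integrated with `scipy.integrate.solve_ivp(method="LSODA")`,
  rtol 1e-8, atol 1e-12 mM, over the four free variables (H2O2, GSSG,
  PRDXox, TXNox); reduced forms are recovered from the totals so the
  conservation sums are exact by construction. Output concentrations
  are clamped at 0; an excursion below −1e-12 mM is treated as an
  integrator failure. The default initial condition is the pre-stress
  state: zero H₂O₂, all couples fully reduced (the source tabulates
  only total initial concentrations; fully reduced is the natural
  unstressed choice).
* **Numeric steady state.** Relaxation is declared when every field's
  |d/dt| falls below `rel_tol` × max(field, 1e-12 mM) per ms
  (default rel_tol 1e-9; "steady state" is not defined operationally in
  the source, so this criterion is a package choice). Integration
  proceeds in geometrically growing windows (1e3 ms, ×4) up to `t_max`
  (default 1e8 ms); non-convergence returns the last state flagged.
  Cross-validation against the analytic route uses rel_tol 1e-11 and a
  longer horizon, which empirically bounds the relative disagreement
  below 1e-5 even for the slowest randomized parameterizations
  (catalase-only with both rate and pool scaled down, relaxation time
  ≈ 7e5 ms).
* **Analytic steady state.** At fixed H, the couples' quasi-equilibria
  are closed-form: GSH*(H) = kGSR·GSR·GSH_T/(kGPX·GPX·H + kGSR·GSR);
  PRDX*(H) is the smaller root of a·c·P² − (a·c·P_T + b·c·T_T + a·b)·P
  + b·c·T_T·P_T = 0 (a = kPRDX·H, b = kTXNRD·TXNRD, c = kTXN),
  evaluated in the stable 2C/(B+√disc) form; the residual
  influx − Σ fluxes(H) is strictly decreasing, so `brentq` on a
  geometrically grown bracket finds the unique root. Degenerate pools
  (zero expression) short-circuit to fully reduced / fully oxidized
  limits. The recycling legs cap the sustainable flux at
  kGSR·GSR·GSH_T (GPX) and c·P_T·b·T_T/(c·P_T + b) (PRDX, the series
  combination of its two legs); with catalase inactive an influx at or
  above the summed active capacities raises a "no steady state" error.

## Expression scaling

The six enzyme quantities are scaled per line by the ratio of
aggregated transcript abundance to the reference line (factors exactly
1 there). The default gene map sums family members — CAT; GPX1–4; GSR;
TXNRD1–3; PRDX1–6; TXN+TXN2 — and is overridable via YAML because the
isoform choice is genuinely open; summing weights isoforms by
abundance, which is the least-assumption aggregation when kinetic
differences between isoforms are ignored anyway. Zero expression
propagates to a zero pool (no pseudocount — the scaling is a plain
ratio), which the steady-state code handles as a degenerate pathway.
GSH_total stays at 3.0 mM for every line. Scaling is invariant to any
global rescaling of the matrix, so the abundance unit (TPM, RPKM,
counts) is irrelevant.

## Synthetic data

The generator emulates what the pipeline consumes from a CCLE-style
RNA-seq matrix, not genome-wide structure: per-gene baselines drawn
log-normally (log-mean 4.0, log-sd 1.0 across genes — a right-skewed,
positive abundance scale whose absolute level cancels in the ratios),
line-to-line log-normal noise (sd 0.2), tissue groupings with a fixed
RR fraction (first half of each tissue's lines, deterministically), an
optional reference line placed exactly at baseline (so its factors are
exactly 1), and a multiplicative RR effect applied to the member genes
of chosen enzymes before noise. All draws flow from one
`numpy.random.default_rng(seed)`, making output bit-reproducible.
What it does *not* emulate: gene–gene correlation, batch effects,
isoform-specific regulation, and any real mRNA–protein decoupling — so
a passing benchmark shows the pipeline recovers group differences it
was fed under its own proportionality assumption, not that transcript
ratios faithfully parameterize real cells.

The benchmark conditions are 20 lines per label group with noise 0.2: a
2× protective effect on GPX+GSR must drive mean RR steady-state H₂O₂
below RS in ≥48/50 seeds, and under the null the Welch test at α=0.05
must flag 2–8% of 400 seeds (binomial ±2.75σ around the nominal rate).

## Statistics

Group comparison uses Welch's unequal-variance two-sided t-test
(`scipy.stats.ttest_ind(equal_var=False)`); the source marks
significance at p < 0.05 without naming a test, and Welch is the safer
default for small groups of unequal spread. A Mann–Whitney switch and
an off-by-default Benjamini–Hochberg correction across the
tissue × condition grid are provided; per-cell significance without
correction mirrors the per-panel asterisk convention of the source
figures. Tissue summaries report arithmetic mean ± sample SD (n−1);
single-line groups report SD 0 with a warning flag.

## Problem sizes

The test suite uses 200 randomized parameterizations for the
cross-method check, 30 profiles for grid monotonicity, and 50 (power) +
400 (null) seeds of a 40-line single-tissue pipeline for the benchmark;
the whole suite runs in well under a minute since the analytic
steady-state route solves each line in fractions of a millisecond.

## Known limitations

* Catalase is unsaturable and H₂O₂-independent enzyme inactivation is
  absent, so steady states exist for any influx whenever CAT is active.
* The GSH pool is generous (3 mM fully available to GPX); in real cells
  much of it is committed elsewhere, inflating the dominance of the
  GPX/GSH system here.
* Transcript-to-protein proportionality is assumed outright; the
  arbitrary-units reporting of steady-state H₂O₂ reflects that.
* One radiosensitive breast entry of the packaged classification is a
  reconstructed stand-in (see the fixture docstring); tissue counts and
  all documented spot labels are unaffected.
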
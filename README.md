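# psapet

In-vivo quantification of GABA_A/central-benzodiazepine receptor density and
affinity from flumazenil PET in the rat.

Flumazenil (FMZ) is a benzodiazepine-site antagonist; with an ¹⁸F label its
PET signal reports GABA_A/cBZR binding, the inhibitory receptor system whose
loss is implicated in temporal lobe epilepsy. Classical quantification needs
arterial blood sampling and multi-injection protocols. The *partial
saturation approach* (PSA) avoids both: a single injection sized to occupy
50–70% of receptors drives the tissue through a dynamic "Scatchard-like
equilibrium" in which the bound (B) and free (F) concentrations trace the
saturation law

    B = Bmax · F / (F + KdVr)

so a nonlinear fit of B against F over an equilibrium window yields the
receptor density **Bmax** (pmol/ml) and apparent affinity **1/KdVr**
(ml/pmol) from one scan, with the free concentration taken from a reference
region devoid of specific binding (the olive nucleus).

`psapet` implements, in Python:

- the saturable two-tissue-compartment model (hot + cold ligand competing
  for one receptor pool) and the one-tissue reference model, with
  frame-averaged time-activity curve (TAC) simulation
  (`psapet.kinetics`);
- a synthetic-study generator — injection schedules, a calibrated parametric
  plasma input function, seeded frame noise, and two-group (control vs
  post-status-epilepticus) cohorts (`psapet.synthetic`);
- full five-parameter identification (Bmax, K1, k2, kon/Vr, koff) from
  multi-injection TACs (`psapet.identification`);
- the PSA estimator: (F, B) extraction and the Scatchard fit
  (`psapet.scatchard`), plus the simulation-validation experiment and
  equilibrium diagnostics (`psapet.validation`);
- arterial blood-sample corrections and input-function assembly
  (`psapet.blood`);
- the epilepsy-study statistics: unpaired t-tests, Spearman rank
  correlation with exact small-n p-values, and the summed hippocampal
  cell-loss score (`psapet.stats`);
- CSV/JSON/YAML round-trip I/O and a config-driven pipeline with a CLI
  (`psapet.io`, `psapet.cli`).

## Worked example

Validate the PSA estimator on a simulated 4.5 nmol scan generated from the
rat-A hippocampal kinetics (Bmax 27.26 pmol/ml, KdVr 3.23 pmol/ml):

```python
from psapet.synthetic import RAT_PARAMS
from psapet.validation import run_psa_validation

report = run_psa_validation(RAT_PARAMS["A"], dose=4.5)
tf, rm = report.true_free, report.reference_mode
print(f"peak occupancy        : {report.peak_occupancy:.2f}")
print(f"true-free  Bmax       : {tf.fit.b_max:.2f} pmol/ml "
      f"(error {tf.err_b_max:.2f}%)")
print(f"true-free  1/KdVr     : {tf.fit.inv_kd_vr:.3f} ml/pmol "
      f"(KdVr error {tf.err_kd_vr:.2f}%)")
print(f"reference  Bmax       : {rm.fit.b_max:.2f} pmol/ml "
      f"(error {rm.err_b_max:.2f}%)")
print(f"reference  KdVr error : {rm.err_kd_vr:.2f}%")
```

prints

```
peak occupancy        : 0.54
true-free  Bmax       : 27.31 pmol/ml (error 0.20%)
true-free  1/KdVr     : 0.310 ml/pmol (KdVr error 0.08%)
reference  Bmax       : 27.40 pmol/ml (error 0.50%)
reference  KdVr error : 7.90%
```

With the true free concentration the estimator recovers both constants to
well under 1%; estimating the free concentration from a DV-matched reference
region leaves the density nearly unbiased but shifts the dissociation
constant by a few percent — the method's characteristic bias. The same run
is available from the shell as `psapet validate --rat A --dose 4.5`, and
`psapet cohort --seed 1 --out run/` executes the two-group synthetic cohort
arm (per-animal Scatchard fits plus group comparison; the hippocampal
density difference comes out significant, the cortical one does not).

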
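# drainknee

Antibiotic washout and elution kinetics in an in vitro **draining-knee**
flow reactor, in silico.

After revision surgery for periprosthetic joint infection (PJI), surgeons
deliver antibiotics locally — mixed into a PMMA bone-cement spacer, loaded
into absorbable calcium sulfate beads (CSB), or poured directly into the
joint as vancomycin powder (VP). The joint space is not a closed beaker: it
drains, fast at first and slowly later, so the local concentration is set by
the *balance* of depot release against washout. `drainknee` models that
balance and reproduces the downstream exposure analysis used to compare the
three administration methods.

## Model

The joint space is a constant-volume, well-mixed compartment (V = 75 mL)
flushed at the clinically derived drainage rate. For each antibiotic the
dissolved mass obeys

```
V dC/dt = R(t) − Q(t) C(t),        C(0) = Σ M_bolus / V
```

where `R(t)` (mg/h) is the summed depot release rate and `Q(t)` (mL/min) the
drainage flow. `Q(t)` follows the power-law trendline fitted to published
post-revision drainage observations, `Q = 3.1269 t^(−1.019)` (t in hours),
discretized into pump-programmable steps at the effluent sampling times and
capped at the back-extrapolated initial flow of 3.5 mL/min. Depots use the
standard release-kinetics repertoire (bolus, zero-order, first-order,
Higuchi √t, and biphasic burst + sustained forms); the reference
parameterization loads the spacer with 2000 mg each of vancomycin and
tobramycin, the beads with 1000 mg vancomycin + 240 mg tobramycin, and the
powder bolus with 1000 mg vancomycin.

Downstream of the simulator:

- **synthetic effluent measurement** at the clinical sampling schedule
  (5–55 min every 5 min, then 1–8, 12, 18, 24, 48 h) with multiplicative
  lognormal assay noise and censoring at the 0.98 µg/mL detection limit;
- **exposure analysis**: geometric means as means of log10 values,
  per-timepoint log differences between arms, trapezoidal AUC over the
  2/12/24/48 h windows, time above the 100–750 µg/mL biofilm-eradication
  band, and unpaired equal-variance two-tailed t-tests;
- **potency prediction**: Kirby–Bauer zone-of-inhibition diameters from a
  log-linear concentration→diameter calibration against *S. aureus* UAMS-1
  and *P. aeruginosa* PAO1 reference MICs (7 mm disc floor).

## Worked example

```python
>>> import drainknee as dk

>>> res = dk.simulate_arm("vp_bolus")          # 1000 mg powder bolus
>>> round(dk.washout_half_time(res, dk.VANCOMYCIN))
15
```

Fifteen minutes to lose half the bolus: drainage alone erases a powder bolus
on the time scale of the first hour (closed form `75·ln2/3.5 = 14.85 min`
while the initial flow cap binds).

```python
>>> ds = dk.generate_arm_fixtures(seed=1)      # 3 arms x 3 replicates
>>> summ = dk.exposure_summary(ds)
>>> summ.log_diff.query("antibiotic == 'vancomycin' and time_h == 48.0")
    antibiotic  time_h  log10_difference  log10_se            arm_a        arm_b
22  vancomycin    48.0          0.734348  0.108725  csb_plus_spacer  spacer_only

>>> summ.tests.query("antibiotic == 'vancomycin' and time_h == 48.0")
    antibiotic  time_h    t_stat   p_value  n_a  n_b
22  vancomycin    48.0  6.754154  0.002506    3    3

>>> summ.threshold.groupby("arm")["satisfied"].all()
arm
csb_plus_spacer     True
spacer_only        False
vp_bolus           False
```

At 48 h the beads-plus-spacer arm holds a 0.73-log (≈5×) vancomycin
advantage over the spacer alone (p = 0.0025 on this synthetic dataset), and
it is the only arm that keeps the combined vancomycin + tobramycin
concentration above 100 µg/mL continuously for 24 h — the exposure pattern
that motivates combining an absorbable depot with the cement spacer.

A full run (schedule, per-arm simulations, measurements, exposure tables,
ZOI summaries, manifest) is one command:

```sh
drainknee run --seed 1 --out results/
```

## Limitations

The reactor is ideally mixed; the physical system it mirrors shows
incomplete mixing, which steepens the observed powder-bolus washout (a
roughly linear decline reaching the detection limit within ~2 h, versus the
exponential tail of the well-mixed model). See `docs/methods.md` for this
and other modelling choices.
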
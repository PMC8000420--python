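# Methods

## The compartment model

The draining joint space is modelled as a continuously stirred tank reactor
(CSTR) at constant volume: inflow and outflow rates are equal, mixing is
instantaneous, and the outflow concentration equals the compartment
concentration. For each antibiotic the dissolved mass balance is

    V dC/dt = R(t) − Q(t) C(t)

with V the eluant volume (75 mL default, the scale of a knee joint space
holding a full-size spacer), R(t) the summed release rate of all depots
(mg/h) and Q(t) the drainage flow (mL/min, converted internally). Boluses
and burst fractions enter as the initial condition `C(0) = Σ M_inst / V`
rather than as rates. Antibiotic degradation, tissue absorption/desorption
and the 2.5 mL manual sample withdrawals are neglected; the withdrawals
amount to ~57 mL over 48 h against ~1 L pumped through, and constant volume
is maintained by the pump regardless.

**Assumptions that matter.** Ideal mixing is the consequential one. The
physical reactor this model mirrors contains a spacer and beads that
obstruct flow; its observed powder-bolus washout was roughly linear and
reached the 0.98 µg/mL detection limit within ~2 h. The well-mixed model
cannot reproduce that: with a 13,333 µg/mL starting concentration, falling
below 0.98 µg/mL requires ~9.5 reactor volumes of outflow, which the
clinical drainage schedule only delivers by ~18 h. The exponential-tail
divergence is therefore an expected property of the idealization, not a
defect; both profiles share the same initial half-time (~15 min). Tests of
the generator assert the dip-and-recover structure of the spacer arms and
the dominance ordering between arms, which the idealization does reproduce;
the sub-LOD-by-2-h behaviour of the powder arm is a documented divergence.

## Drainage flow

Published post-revision drainage observations follow a power law,
`Q = a t^b` with a = 3.1269 mL/min at t = 1 h and b = −1.019. The time unit
is taken as hours: that choice yields ~0.9 L of total 48 h drainage, the
clinically plausible order, whereas minutes would imply a few tens of mL.
The curve diverges at t → 0, so the programmed schedule caps flow at the
back-extrapolated initial rate of 3.5 mL/min.

A pump cannot follow a continuous function, so the curve is discretized
into piecewise-constant steps. Step boundaries default to the effluent
sampling times (the published protocol does not state the true pump steps;
the sampling grid is the natural candidate and is configurable). Each step
takes `min(cap, Q(step start))`; start-of-step evaluation reproduces the
back-extrapolated cap as t → 0 and makes step flows automatically
non-increasing. Being a left-endpoint rule on a decreasing curve it
overestimates cumulative volume by a bounded amount (~20% over 48 h,
concentrated in the long late steps); the tests carry the exact left-rule
error bound. Intervals are half-open `[start, end)` so boundary lookups are
unambiguous. Fitting a trendline to drainage observations uses ordinary
least squares on log(flow) vs log(time) — the standard estimator under
multiplicative error.

## Depot release laws

The study reports concentrations, not release kinetics, so the release
laws are model choices, stated here and marked as such:

| depot | form | defaults |
| --- | --- | --- |
| PMMA spacer (2000 mg VAN + 2000 mg TOB) | biphasic: 5% burst + Higuchi | k_H = 20 mg/√h per agent |
| Calcium sulfate beads (1000 mg VAN + 240 mg TOB) | biphasic: 15% burst + first-order | k₁ = 0.05 /h |
| Vancomycin powder (1000 mg) | bolus | — |

Rationale: cement releases only a surface-accessible fraction
(diffusion-limited, √t kinetics; ~12% of the load over 48 h under these
defaults), while the absorbable beads release nearly everything (≥90% by
48 h is a design constraint on k₁; the default gives ~92%). Burst fractions
represent surface drug dissolving in the interval between adding eluant and
the first sample. The constants were chosen once so that the simulated arms
show the qualitative effluent structure of the in vitro system — an initial
burst peak, a concentration minimum while drainage is fast (the reference
parameterization puts it at the 2 h sampling time for both spacer arms),
then a sustained rise as drainage declines — and were not revisited
afterwards. Salt masses (sulfate, hydrochloride) are treated as active-drug
mass, matching how loadings are reported. Bead and spacer geometry are
carried on the spec for surface-area-scaled extensions but unused by the
default laws.

## Numerics

The ODE is integrated on a fixed grid (0.1 min default) whose nodes include
every pump-step boundary, so Q is exactly constant within each interval.
Each interval uses the exact exponential-integrator update for constant R
and Q:

    C⁺ = C e^(−QΔt/V) + (R̄/Q)(1 − e^(−QΔt/V)),   R̄ = ΔM_released / Δt

with the interval release mass ΔM taken from the cumulative release law, so
the integrable √t rate singularity at t = 0 is handled in integral form and
constant-flow cases (exponential washout, elution/flow steady state) are
reproduced to floating point. Washed-out mass is integrated independently
as the trapezoid of Q·C on the same grid, which makes the mass audit
(released − in-reactor − washed out) a meaningful consistency check rather
than an identity; residuals are ~10⁻⁵ % of load at the default step and
shrink under refinement. The inverse operation estimates release as
`R̂ = V dC/dt + Q C` with central differences, flooring (and counting)
negative estimates.

The washout half-time is the first time C reaches C(0)/2, by linear
interpolation on the solver grid, reported in minutes and rounded only
where a nearest-minute figure is wanted.

## Synthetic measurement model

Effluent is "measured" at the 23 clinical sampling times by interpolating
the simulated series and applying independent multiplicative lognormal
noise, `measured = true · 10^(σz)` with σ = 0.15 on the log10 scale —
a generic assay-noise magnitude for LC-MS concentration data; replicate
variability in the physical system (sampling-timing jitter, flow-change
synchronization) is not separately modelled. Values below the 0.98 µg/mL
detection limit are censored and recorded *at* the LOD, matching the
convention of reporting censored points as −0.01 on the log10 scale;
zero-substitution is available (`censor_to="zero"`) as a sensitivity
option. Three replicates per arm by default. Replicates and arms draw from
`SeedSequence` substreams of one master seed, so datasets are reproducible
and adding an arm does not reshuffle the others.

What passing tests show, and what they do not: the generator reproduces the
deterministic simulation at σ = 0 (consistency), is unbiased in log space,
and carries the qualitative arm structure described above. It does not
emulate incomplete mixing, assay drift, or timing jitter, so agreement on
synthetic data does not by itself validate the model against the physical
reactor.

## Exposure analysis

Geometric means are computed as means of log10 values after flooring at the
LOD. AUC uses the trapezoidal rule on linear-scale recorded values, per
replicate, over windows ending at 2, 12, 24 and 48 h; windows start at the
first sampling time (5 min) since no measurement exists at t = 0. On the
clinical sampling grid the trapezoid tracks a fine-grid integral of the
underlying smooth curves within ~7%. Time-above-threshold treats the series
as piecewise linear, counts partial segments via interpolated crossings,
and is evaluated on the *summed* vancomycin + tobramycin concentration
because the reference eradication band (100–750 µg/mL for ≥24 h) is defined
for the 1:1 combination; the satisfaction flag demands continuous coverage
from the first sample through the duration requirement. Between-arm
comparisons use the unpaired two-tailed equal-variance Student's t-test on
log10 values, per timepoint, with no multiplicity correction by default
(mirroring the per-timepoint convention of the source analysis); a
Holm-adjusted column can be requested and is flagged in the table metadata.

## Zone-of-inhibition calibration

The disc-diffusion assay is replaced by a calibration model: per agent,
diameter = 7 mm (the disc) + 2 mm per doubling of C/MIC above the MIC, zero
slope below it. Disc-diffusion theory gives diameters roughly linear in log
concentration; the 2 mm/doubling slope is a model default, not a fitted
calibration, so predicted time courses are comparable to plate data in
shape and ordering only. The combined zone is the maximum single-agent zone
(independent action; synergy out of scope). The vancomycin MIC of PAO1 is
known only as "> 64 µg/mL" and is read conservatively: no zone unless
C > 64, with 64 standing in for the unknown MIC above the bound.

## Pipeline and reproducibility

`run_pipeline` executes schedule → simulate → measure → analyze → ZOI for
the configured arms and writes CSVs (units embedded in column names), a
plain-text report and a JSON manifest (seed, version, full config echo).
Identical config + seed gives byte-identical outputs. A three-arm default
run completes in a few seconds on one CPU at the 0.1 min solver step.

## Known limitations

- Ideal mixing (see above): powder-bolus late-time behaviour diverges from
  the poorly mixed physical reactor by design.
- Release laws and the ZOI slope are reference parameterizations, not
  fitted to measured elution or plate data; conclusions about *orderings*
  between arms are robust to linear rescaling (the ODE is linear in the
  loadings), absolute concentrations are not calibrated.
- No tissue compartment, no chemical degradation, no bead-count or
  surface-area effects, no chromatogram-level assay simulation.
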
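# Methods

## Model structure

Two cell lineages share one marrow. Each lineage is an ordered chain of
compartments, most primitive first. A dividing compartment $i$ divides at
rate $p_i$ per cell per day; each division produces two daughters that stay
in the compartment with probability $a_i$ (self-renewal) or advance with
probability $1-a_i$ (differentiation). Hence the per-compartment balance

$$\dot c_1 = (2a_1-1)p_1c_1,\qquad
  \dot c_i = 2(1-a_{i-1})p_{i-1}c_{i-1} + (2a_i-1)p_ic_i,$$

and a non-dividing terminal pool $\dot c = \text{influx} - d\,c$. The
normal lineage is LT-HSC → ST-HSC → MPP → CPC → precursor → mature blood
cells (terminal, peripheral blood). The malignant (MDS) baseline lineage
runs through analogous stages but terminates in dysplastic precursors that
die inside the marrow. Death rates appear only on terminal pools; dividing
cells do not die in this model.

Effective rates are feedback-scaled maxima, $a_i = a_{\max,i} s_a$,
$p_i = p_{\max,i} s_p$, with two scalar signals shared by both lineages:

* $s_p = 1/(1+k_pM)$, $M$ = total mature peripheral-blood cells. Cytopenia
  (low $M$) pushes $s_p\to1$ and speeds up every division in both lineages.
* $s_a = 1/(1+k_aW)$, $W$ = total cells of the `niche_depth` (default 3)
  most primitive compartments of *every* lineage. Niche crowding lowers
  self-renewal everywhere — this is the only channel through which the
  clone suppresses its competitor; the lineages never touch otherwise.

The reciprocal-saturation (Hill-1) form is the simplest monotone map from
pool size onto $(0,1]$ with $s=1$ at an empty pool; only this
monotonicity, not the exact shape, drives the qualitative results.

## Analytic anchors

**Healthy fixed point.** Stem balance requires $a_{\max,1}s_a^*=1/2$, so
$s_a^*=1/(2a_{\max,1})$ and $W^*=(2a_{\max,1}-1)/k_a$; no positive
equilibrium exists for $a_{\max,1}\le1/2$. Downstream dividing compartments
follow from flux balance (the common factor $s_p$ cancels), which requires
every downstream compartment to be strictly subcritical,
$a_{\max,i}s_a^*<1/2$, i.e. $a_{\max,i}<a_{\max,1}$. The mature pool solves
$d\,c\,(1+k_pc)=\text{influx}$ (Brent root finding on the bracketing
interval $[0, \text{influx}/d]$).

**Takeover law.** A clone seeded at the healthy equilibrium has stem growth
rate $(2a_{\max}^{\mathrm{MDS}}s_a^*-1)p^{\mathrm{MDS}}$, positive iff
$a_{\max}^{\mathrm{MDS}}>a_{\max}^{\mathrm{N}}$ — the division rate scales
the pace, never the sign. Ties ($a$ exactly equal) are neutral to leading
order: the deterministic system shows no drift, and classification reports
them as marginal.

## Default parameterization and its provenance

Fixed by the modeled biology: normal LT-HSC $a_{\max}=0.7$,
$p_{\max}=1/50\,\mathrm d^{-1}$; MDS stem $a_{\max}=0.9$,
$p_{\max}=1/100\,\mathrm d^{-1}$; dysplastic precursor lifespan 10 d
($d=0.1\,\mathrm d^{-1}$); niche depth 3; apoptotic cells visible for 24 h.
Death-rate conventions: "lifespan $T$" → $d=1/T$; "half-life $T$" →
$d=\ln2/T$ (the 16-h half-life variant gives $d\approx1.04\,\mathrm
d^{-1}$).

The intermediate compartments are not individually observable, so the
defaults encode two monotone hierarchies — $a_{\max}$ decreasing
(0.70…0.66 for the normal lineage) and $p_{\max}$ increasing (0.02…1.0
d⁻¹, i.e. division times from 50 d for stem cells down to 1 d for
precursors) — and the normal mature death rate is $2\,\mathrm d^{-1}$
(half-day mean lifespan, granulocyte-like). These follow the conventions
of feedback models of the transplantation-regeneration literature and are
exposed, per compartment, in the preset YAML.

The remaining free values — the MDS intermediate hierarchy
($a_{\max}$ = 0.7565, 0.6120, 0.5972; $p_{\max}$ = 0.08, 0.1563, 0.1808)
and the gains $k_a=1.596\times10^{-11}$, $k_p=2.108\times10^{-12}$ — were
fitted once (`scratch/calibrate.py`, least squares over seven targets) so
that the default scenario reproduces the reported disease course:
manifestation at ~17 years, the year-17 marrow composition, and the ~5.6 %
apoptotic plateau. They are marked `calibrated` in the preset files and
were not revisited afterwards.

Two structural consequences of that calibration are worth making explicit:

* The year-17 composition has ~2×10⁵ MDS-ST-HSCs per MDS-LT-HSC. A chain
  of purely subcritical downstream compartments slaved to the stem's
  growth cannot amplify that much (its gain is bounded by flux/growth-rate
  ratios of order 10). The inverted pyramid therefore requires elevated
  self-renewal *within* the clone's hierarchy: the MDS-ST-HSC is itself
  supercritical at the healthy signal ($0.7565 \times 5/7 > 1/2$) and is
  the clone's true engine of expansion, consistent with the observation
  that a malignant ST compartment must self-renew above 50 % to expand.
* Because the clone carries this internal hierarchy, the competition
  sweep's self-renewal axis rescales the *whole* MDS $a_{\max}$ vector
  proportionally (the axis value is the stem compartment's $a_{\max}$, and
  the stem remains the clone's maximum). Under that convention the
  simulated takeover boundary coincides exactly with the analytic law;
  varying the stem alone while leaving a supercritical ST compartment in
  place would test a different, biologically inconsistent clone.

The absolute scale follows from the gains: healthy marrow ≈ 1.7×10¹²
cells, niche ≈ 2.5×10¹⁰, and a primitive (CD34⁺-proxy) marrow fraction of
1.4 % — all in the physiological range, so that the default seed of one
single malignant cell is meaningful. The composition dynamics are
scale-free: multiplying both gains by $\lambda$ and dividing all counts
(including the seed) by $\lambda$ leaves signals, percentages and timing
unchanged, which the test suite checks.

## Observables

* **Marrow composition**: percentages over all compartments with
  `in_pb = false` (compartments 1–5 of each lineage); mature pools are
  peripheral blood and excluded on both sides of the ratio.
* **Apoptotic fraction**: dying cells are not a state variable; the
  apoptotic pool is the instantaneous marrow death flux times the
  visibility window, $A=\tau_{\mathrm{vis}}\sum d_ic_i$, reported as
  $100A/(BM+A)$. Including $A$ in the denominator is the default (the
  alternative convention differs by <6 % at the reported level and is a
  flag). In the baseline variant only dysplastic precursors die in the
  marrow, so the healthy fraction is exactly 0.
* **Primitive fraction**: niche compartments of both lineages over total
  marrow — the model's CD34⁺ proxy. It is a model *output* only; measured
  CD34⁺ percentages were never fitting targets.
* **Manifestation**: first time the normal mature pool falls below 50 %
  (configurable) of its analytic healthy baseline, linearly interpolated
  between output samples — adequate at decade scales, where root polishing
  below the 30-day output grid is meaningless.

## Outcome classification and sweeps

Horizon 100 years (configurable). *Takeover*: normal mature output < 10 %
of baseline and MDS marrow share > 50 %. *No takeover*: the clone is back
at seed level — within one order of magnitude of its initial marrow share,
since a dying stem seed still populates a handful of downstream cells —
with normal output ≥ 90 %. Everything else is *marginal*; in practice these
are clones just above the boundary whose expansion has not finished within
the horizon (with a one-cell seed, a supercritical clone needs ~24 e-folds
to matter, so clones with net stem growth below ~$7\times10^{-4}\,\mathrm
d^{-1}$ remain latent past 100 years — a physiologically meaningful
latency, not a numerical artifact). Concordance with the analytic takeover
law is reported over the decided cells and is 1.0 on the shipped grids.
All thresholds are artifact conventions, exposed as arguments.

## Numerics

* Integration: scipy `solve_ivp`, LSODA (stiffness-switching; terminal
  death rates of order 1 d⁻¹ against stem divisions of order 10⁻² d⁻¹),
  rtol = atol = 10⁻⁸ by default. A 55-year default run costs ~4×10³ RHS
  evaluations (~0.2 s).
* Nonnegativity: the flow is inward on the boundary ($\dot c_i\ge0$
  whenever $c_i=0$), so the exact solution stays nonnegative; integrator
  undershoot is clipped only within 10×(atol + rtol·max count), anything
  larger raises.
* The fixed-step explicit-Euler oracle is first-order and used in tests
  for Richardson order checks and cross-validation of the adaptive
  solution; it rejects steps that drive counts negative (heuristic:
  step × fastest rate < 1).
* Events are detected on the output grid (default 30 d) by linear
  interpolation.
* Toy fixtures use gains of 10⁻³⁰⁰ where an exactly linear chain is wanted:
  the gain is positive (respecting the parameter invariant) but the signal
  is 1.0 to machine precision for any realistic count.

## Limitations

The model is a deliberate conceptual reduction: one mutation, one clone, no
clonal hierarchy; no lineage splitting (erythroid/myeloid/lymphoid); no
stochastic extinction of the first malignant cell (a one-cell seed is
treated deterministically); discrete compartments stand in for a continuum
of maturation states; and the feedback signals are effective laws, not
identified molecules. Quantitative outputs (the 17-year latency, the
composition percentages) are calibration-dependent illustrations of the
dynamics, not patient-level predictions; the robust, calibration-free
results are the steady-state balance and the self-renewal takeover law.
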
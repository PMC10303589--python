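# Methods

## Transport model

In-body sensors are assumed to drift passively with the blood, so their speed
equals the bulk blood velocity `v = Q / (π r²)` with `Q` the volumetric flow
(mL/s) and `r` the vessel radius (cm). The circulatory system is collapsed to
a single effective loop traversed in `T_C` seconds; there is no vascular-tree
topology, pulsatility, or per-organ branching. The loop length is the time
integral of velocity, discretized on a 1-second grid as a left Riemann sum —
`T_C` is treated as an integer count of 1-s steps, matching the per-second
update of the selection procedure.

Two parameterizations exist:

* **velocity mode** (primary): per-second velocity uniform on
  `[v_min, v_max]` cm/s. The case studies state these ranges directly.
* **flow mode**: per-second `Q ~ U[q_min, q_max]`, `r ~ U[r_min, r_max]`
  drawn independently, `v = Q/(π r²)`.

Two evaluation modes exist:

* **expectation mode** (default for design): `L = ((v_min+v_max)/2) · T_C`.
  Deterministic; this is the mode all reported design numbers use. It exists
  only for velocity mode — the flow-mode mean `E[Q/(π r²)]` has no elementary
  closed form (the reciprocal-square of a uniform variate), so flow-mode
  expectations must be estimated by averaging sampled path lengths.
* **stochastic mode**: one seeded draw of the per-second velocity series,
  representing a single patient realization. The sample mean of stochastic
  path lengths converges to the expectation-mode value (tested at 1000
  seeded draws, 3-standard-error gate).

## Readout model

With loop length `L` and collector length `w` (requiring `w < L`), a sensor
occupies the collector window at any instant with probability `P_C = w/L` —
an occupancy fraction, independent across sensors and across transmission
opportunities. A readout is collected at an opportunity iff **exactly one**
of the `n` sensors is in the window; two or more collide and zero transmit
nothing. Hence the per-sensor success probability
`P_S = P_C (1 − P_C)^(n−1)` and the session expectation

```
S(n) = n P_C (1 − P_C)^(n−1) · K,    K = duration_minutes · 60 · opportunity_rate.
```

`opportunity_rate` defaults to one transmission opportunity per second; the
monitoring duration in minutes is converted internally so that a 10-minute
session offers 600 opportunities. The rate is an explicit parameter of
`MonitoringSpec` rather than a constant because it is a property of the radio
duty cycle, not of the physiology.

The ratio `S(n+1)/S(n) = ((n+1)/n)(1 − P_C)` crosses 1 exactly once, so
`S(n)` is unimodal with integer argmax `⌊1/P_C⌋`. When `(1 − P_C)/P_C` is an
integer the two adjacent counts tie exactly; the closed form returns the
larger of the pair, and the tie is exercised in the tests at `P_C = 1/36`
where `S(35) = S(36)`. Unimodality also makes the feasible set
`{n : S(n) ≥ S_min}` a contiguous interval; its edges are found by an upward
scan to the peak and a downward scan along the decreasing tail (capped at a
large search bound that raises rather than silently truncating).

### Reporting conventions

Readouts are counts, so displayed values floor the real expectation
(`⌊S(n)⌋`); feasibility comparisons always use the unfloored value, so
flooring affects reporting only. Both values are carried in every
`DesignPoint` and in curve exports (`n, p_s, s, s_floor`).

## Smart sensor selection

The design search computes `L` (expectation mode, or one seeded stochastic
draw per invocation), derives `P_C`, and tries `n = 1, 2, …` until
`S(n) ≥ S_min`, returning the first adequate count — by unimodality this is
also the lower edge of the feasible interval (asserted as an invariant test).
The search as literally specified has no stopping rule for unattainable
requirements; since `S(n)` only decreases past `⌊1/P_C⌋`, the implementation
stops there and returns `feasible=False` together with the best achievable
floored count. Increasing the monitoring time never increases the selected
count (tested).

For several sites monitored in one session by the same circulating pool, the
pool must satisfy every site individually, so the multi-site minimum is the
maximum of the per-site minima; an unattainable site raises an error naming
it.

## Monte Carlo validation

The simulator implements the collision mechanism directly: per opportunity
the number of in-window sensors is drawn as `Binomial(n, P_C)` (equivalent to
`n` independent Bernoulli indicators) and a readout is scored iff that number
is exactly 1. Sensors never defer and there is no capture effect — two
simultaneous transmitters always destroy the readout — which is the minimal
mechanism consistent with the success probability above. Replicates derive
independent streams from one `numpy` `SeedSequence`, so a single seed
reproduces the full experiment. Agreement with the analytic expectation is
judged by a z-test over replicate means at a 3-sigma gate; with zero
replicate variance the verdict is pass only on exact equality (a mean of
all-zero replicates against a tiny positive expectation fails honestly).
The z-test presumes the session expectation is resolvable; grid checks
therefore sample the operating regime (expected readouts well above zero)
rather than degenerate corners where every replicate is zero and a normal
approximation is meaningless.

## Physiological plausibility checks

`validate_physiology` flags, without raising:

* circulation time outside 45–60 s (warning — typical human whole-body
  bounds; out-of-range cases stay explorable),
* vessel radii outside 4 µm–12.5 mm (error — capillary-to-aorta anatomical
  limits),
* monitoring shorter than 10 circulations (warning — the occupancy picture
  behind `P_C` needs many loops to average over; "much longer" is made
  concrete as a factor of 10).

## Bundled scenarios and units

Seven scenarios ship with the package: tennis elbow (`T_C = 50` s,
`v ∈ [1.5, 19]` cm/s, `w = 20` cm), runner's knee, shin splints and heel
inflammation (`T_C = 60` s, `v ∈ [3, 15]` cm/s, `w = 15/50/10` cm), all with
10-minute sessions and a 100-readout requirement, plus shin-splints variants
at 10, 12 and 14 minutes with a 250-readout requirement. Config files
(YAML/JSON) use fixed units — `t_c` seconds, velocities cm/s, `w` cm,
monitoring minutes — to avoid implicit unit mixing; loaders report every
offending field at once. Curve sweeps default to three times the analytic
peak so the post-peak decline is always visible in exports.

## Design choices and numerical notes

* Expectation mode is the default because the design numbers of interest are
  properties of the mean transport, and it is deterministic and
  seed-invariant (tested). Stochastic mode exists for realization-level
  studies; across many seeds its selected counts bracket and center on the
  expectation-mode choice (tested at 200 seeds).
* `⌊1/P_C⌋` vs enumeration: the closed-form argmax is cross-checked against
  brute-force enumeration for 1000 random `P_C` values in the tests; the two
  routes are kept independent (the enumeration never calls the closed form).
* Feasible-range edges are sharp by construction (first/last adequate `n`);
  sharpness (`n_min − 1` and `n_max + 1` fail) is asserted for every bundled
  scenario.
* Degenerate inputs: `w ≥ L` raises an infeasible-geometry error (the
  occupancy probability would leave `(0,1)`); probabilities are validated to
  lie strictly in `(0,1)`; sensor counts must be positive integers; empty
  velocity series are rejected.

## Known limitations

The single-loop, uniform-velocity transport is a deliberate idealization:
real circulatory transport has branching, recirculation heterogeneity and
pulsatile velocity profiles, none of which are modeled. Independence of
sensor positions across opportunities ignores the fact that a sensor near
the collector now is likely near it one second later; the analytic model and
the simulator share this assumption, so their agreement validates the
algebra, not the physiological realism. Expectation-mode results reproduce
deterministic design arithmetic; realization-level variation (stochastic
mode) shifts minimal counts by roughly ±1–2 sensors in the bundled
scenarios. Energy budgets, signal attenuation and MAC-layer behaviour are
out of scope.
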
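# Methods

## Model and assumptions

Each membranous chamber is treated as a thin shell of revolution under a
uniform transmural pressure `p` (endolymph minus perilymph/surrounding
fluid). "Thin" means membrane theory: the wall carries in-plane tension
only, with no bending resistance. The engineering criterion is a thinness
ratio `r/w ≥ 5`; the report labels ratios in `[4, 5)` as "approaches",
because the analysis is still a usable first approximation there but the
reader should see that the assumption is borderline (the toadfish anterior
canal, at 4.4, is exactly such a case). All chambers are assumed to
communicate, so they share one `p`; since its magnitude is unknown (only
assumed slightly positive, enough to keep the labyrinth inflated), every
comparative result is reported per unit pressure and the headline
quantities are pressure-free ratios.

For a shell of revolution with principal radii of curvature `r1`
(meridional) and `r2` (normal) at a point, membrane equilibrium gives

    meridional stress = p · r2 / (2 w)
    hoop stress       = (p · r2 / w) · (1 − r2 / (2 r1))

For an ellipsoid of revolution with equatorial radius `a` and polar
semi-axis `b`, parametrizing the meridian as `(a cos t, b sin t)`:

    r1 = (a² sin²t + b² cos²t)^{3/2} / (a b)
    r2 = (a / b) · √(a² sin²t + b² cos²t)

At the equator (`t = 0`) the hoop stress reduces to the closed form
`s · (a/w) · p` with shape coefficient `s = 1 − a²/(2b²)`. That
specialization is verified in the tests against the general profile to
1e-9 relative over randomized geometries, and the principal-radii formulas
are cross-checked against an independent finite-difference curvature oracle
on the parametrized meridian. Consequences worth remembering: a sphere
(`s = 0.5`) is isotropic — hoop = meridional = `p·a/(2w)` at every latitude
— and a cylinder (`s = 1`) carries an axial stress exactly half its hoop
stress.

Conventions: radii are luminal (inner-surface) radii as measured in
surgery; no midwall correction is applied. Latitude is 0 at the equator
(the peak-stress parallel), positive toward the pole. The cylinder limit is
represented by an exact sentinel (`b = math.inf`), not a large finite
number, so `s = 1.0` holds exactly. Oblate ellipsoids (`b < a`) fall outside
the sphere→prolate→cylinder continuum the labyrinth occupies and are
rejected unless explicitly overridden.

## Torus extension

A semicircular canal is really a toroidal loop, not a straight tube. For
tube radius `r` and loop (centerline) radius `R`, the membrane hoop factors
at the two equatorial circles are

    inner = (r/w) · (2R − r) / (2(R − r))      (anticlastic side, > r/w)
    outer = (r/w) · (2R + r) / (2(R + r))      (< r/w)

Both approach the straight-cylinder value `r/w` as `R/r` grows; the inner
factor does so monotonically from above. At `R = 11 r` the inner correction
is exactly +5%. No toadfish loop radius is published, so the torus is an
exposed operation with documented geometry, not part of the default
per-chamber summary; the `R = 11 r` figure is an illustrative slender-loop
case, not a measured value. General anticlastic (hourglass) chambers with
`s > 1` are not modeled, as no dimensions exist for them; the torus inner
equator is the only anticlastic surface reachable.

## Pipeline conventions

**Per-statistic pairing.** Measurements arrive as mean/max/min for `w` and
`r` separately; per-individual `(w, r)` pairs are not published. The "max"
statistic therefore pairs `r_max` with `w_min` (stress-maximizing) and the
"min" statistic pairs `r_min` with `w_max`: the widest envelope consistent
with the recorded ranges. This is an envelope, not an observed individual —
the true individual extremes lie inside it unless radius and thickness
extremes co-occurred in one fish.

**Reference choice.** Normalization divides every chamber's GSF by a
reference chamber's *mean* GSF. `auto` picks the chamber with the smallest
mean GSF, which guarantees every mean `t_n ≥ 1` and makes the reference's
`t_n` exactly 1.0.

**Display rounding.** Internally everything is full precision. The
one-decimal display values divide the unrounded GSF by the reference GSF
*rounded to one decimal* and then round half-up — the convention under
which the classic summary table's normalized values (ampulla 1.4, utricle
3.9) are recovered; rounding the fully unrounded utricle ratio (3.9617)
would instead print 4.0. Both numbers are exposed (`t_n_mean` vs
`t_n_mean_display`), so no precision is lost to the convention.

**Disparity anchors.** The largest individual normalized stress depends on
the denominator: anchored at the reference chamber's mean GSF the utricle
envelope reaches ≈7.5; anchored at the reference minimum it reaches ≈10.4.
Neither convention is canonical, so the extremes report prints both with
their assumptions rather than asserting a single "n-fold" figure.

## Synthetic cohorts

The generator emulates the structure of the bundled data: per chamber, a
thickness range and radius range in microns, sampled independently per
individual. Defaults are the toadfish chambers' recorded min/max ranges,
uniform sampling, and 20 individuals (the published means reflect 12–25
measurements from 3–5 fish). A truncated normal (location defaulting to the
range midpoint, scale to a quarter of the range width) is available for
sensitivity checks. One integer seed governs the whole cohort; per-chamber
substreams are spawned from it, so cohorts are bit-reproducible and adding
a chamber never perturbs another's draws.

What the generator does *not* emulate: covariance between `w` and `r`
within an individual (no such data exist), left/right asymmetry, growth, or
measurement error structure. Passing tests on synthetic cohorts therefore
demonstrate pipeline correctness and invariance properties, not biological
realism of the variability model.

Summarizing a cohort back to mean-plus-extremes and then computing GSF
yields `s · mean(r) / mean(w)` — a ratio of means. This matches how the
published table was reduced, but differs from the mean per-individual
factor `s · mean(r/w)`, which is strictly larger whenever thickness varies
(Jensen's inequality; verified by Monte Carlo in the tests). Users comparing
against individually-resolved data should be aware of the distinction.

## Numerical choices

- Exact integer inputs (microns) flow through double precision; the
  analysis is three divisions and three multiplications, so no conditioning
  issues arise.
- Display rounding uses decimal half-up (not banker's rounding) for
  deterministic, convention-stable printing.
- CSV round trips write shortest-repr floats and read with round-trip float
  parsing, so measurement sets survive save/load bit-exactly.
- Degenerate inputs: zero-width ranges produce constant draws; a
  single-individual cohort summarizes to mean = max = min; zero wall
  thickness raises rather than returning infinity.

## Limitations

- Absolute stresses are unavailable: the transmural pressure is unknown, so
  results are per unit pressure or normalized.
- No bending/flexural shell theory; chambers below the thin-membrane
  criterion are flagged, not corrected.
- No material constitutive model: the analysis says which chamber carries
  the most stress, not how much it strains or when it fails.
- The extreme-pairing envelope overstates individual splay if radius and
  thickness extremes never co-occur in one animal.
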
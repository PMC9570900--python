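# Methods

## Scope and architecture

The package closes the physical↔virtual loop of a grow-bed digital twin
entirely in software. The simulator (`simulate.py`) plays the physical
environment: it produces sensor streams, grows plants, and renders camera
views. The analysis stack (morphometrics → fresh weight/growth/stage →
status → control → record store) plays the virtual environment. The two
meet in `closed_loop_run`, where controller commands feed back into the
humidity dynamics — the virtual-to-physical connection — and sensor and
image records flow the other way.

Deliberately out of scope: the learned instance segmenter and camera
undistortion used on real photographs (a threshold-and-label segmenter
stands in for synthetic images only), the aquaculture side of an
aquaponic system (fish tanks, biofilters, nitrogen chemistry), GUI
dashboards (CLI reports and CSV exports instead), e-mail notification
(a structured event log instead), and any physical hardware I/O.

## Morphometrics

Masks are row-major boolean grids, origin top-left, 0-based indices.
Area is the foreground pixel count times scale² — interior holes are not
filled. Height/width/depth are bounding-box extents (a single pixel spans
1 px); the convex hull or maximum chord would be defensible alternatives,
but the bounding box is the simplest reading of "height, width and depth"
and is what the renderer targets. The centroid is the mean foreground
pixel index, reported as (x = column, y = row) in cm. The top view's
depth axis defaults to image rows (the axis perpendicular to the side
camera's width axis) and is configurable, since the assignment of image
axes to bed axes is a camera-mounting convention.

The pixel→cm scale is a per-camera configuration value (default
0.05 cm/px); no lens model is applied.

## Fresh weight, growth rate, stage

The fresh-weight model is the fixed linear form given in the README; the
package does not refit it. Inputs are validated non-negative. The model's
response units are inherited from the original fit and deliberately left
as "model units".

The daily growth rate first averages record-level areas per calendar day
(mirroring the accumulative daily aggregation in the store) and then
takes the mean of day-over-day relative changes. A day following a
zero-area day has an undefined rate; that step is skipped and flagged
rather than raising. The overall rate of a plant is the arithmetic mean
of its per-view rates; this combination rule reproduces the reference
plants' reported overall values from their side/top values (exactly for
plant #2), which is the evidence — not proof — that it is the intended
rule. Combining per-view *areas* before rating is the rejected
alternative; it does not reproduce those numbers.

Stage boundaries divide [0, final_area] into `n_stages` (default 12)
equal half-open intervals [c_{k−1}, c_k); areas at or above the top cut
clamp to stage 12, and area 0 is stage 1. The default reference final
area is 12 cm², which makes stage 1 the interval [0, 1) cm².

## Status classification

"Within 15 % of the limits" is read as 15 % of the range *width*,
measured inward from each limit; values outside the range are red, not
yellow. A %-of-limit-value reading is also plausible; the width reading
was chosen because it behaves sensibly for ranges that do not start near
zero (e.g. water temperature). Band edges are inclusive on the yellow
side. The one-sided light range has no width, so its yellow band is 15 %
of the threshold itself, i.e. [450, 517.5] lux. The band fraction, day
window and all ranges are configurable.

The default EC range (100–2000 µS/cm) and the default simulated EC levels
(2500/2550 µS/cm) are both kept as given by their sources, although they
are mutually inconsistent — default runs therefore classify EC red
throughout. This inconsistency is reproduced, not reconciled.

## Control

The humidifier is a two-threshold relay: off at RH ≥ 80 %, on at
RH ≤ 50 %, hold in between. "Reaches the limit" is interpreted as
inclusive comparisons. Only the upper trigger and the lower re-engage
point are specified by the source material; the symmetric form (no
minimum dwell time, no additional margins) is the simplest machine with
those two switching points, and the dead band alone already prevents
chattering: on any monotone RH trajectory the relay switches at most
once.

The grow light combines a photoperiod gate (hard off outside 06:00–18:00)
with lux hysteresis inside it: on below 450 lux, off at or above a
configurable satisfaction level (default 600 lux). Only the on/off
capability of the light is given; this policy is the package's own
design, chosen so the light controller is testable with the same
hysteresis properties as the humidifier.

Manual overrides pin an actuator (automatic rules skip it) until an
explicit release; every override is logged even when it does not change
state, whereas automatic events are logged exactly once per state change.

## The simulator

**Sensor streams.** Each parameter follows a two-level day/night square
wave plus independent per-sample Gaussian noise, with a dedicated seeded
generator per parameter stream (`default_rng([seed, stream_index])`), so
runs are bit-reproducible and streams are independent. The square wave is
the simplest profile consistent with reporting a single day mean and a
single night mean; defaults are pH 6.9/7.05, EC 2500/2550 µS/cm, with
water/air temperature and light levels set to plausible mid-range values.
Real sensor noise magnitudes are not reported anywhere; the default noise
is zero and the config comment marks the values as placeholders.

**Humidity.** RH instead obeys first-order relaxation stepped per
simulated minute: toward a humidifier ceiling (90 %, τ = 20 min) while
on, toward the ambient diurnal profile (45 % day / 53 % night, τ = 45
min) while off. The ambient day level sits below the 50 % re-engage
threshold so that the closed loop exhibits the full limit cycle
(rise → 80 % → off → decay → 50 % → on), and the night level is ~18 %
higher than the day level, matching the observed higher night-time
humidity. Because the controller acts at the 5-minute record cadence
while RH evolves per minute, the trajectory overshoots each threshold by
a bounded lag (≈2–3 % at the default time constants) before the command
lands — the same overshoot-and-correct shape seen in the physical trace.

**Plants.** Per view, area grows geometrically,
`A(t) = A₀ (1 + r/100)^{t/1 day}`, sampled continuously (not stepped
daily), with optional multiplicative log-normal noise per imaging epoch.
Extents scale as √area at a fixed per-view aspect ratio (side
height/width 0.8, top depth/width 1.0), so silhouettes stay
geometrically consistent as they grow. The three default plants carry
the reference side/top rates (14.7/15.6, 10.25/18.67, 22.73/23.16 %/day) with initial areas of 2.0 cm² (side) and 2.5 cm² (top) — small
seedling-scale starting silhouettes chosen so the day-14 sizes remain
within the camera frame.

**Rendering.** Each plant is rasterised as a filled ellipse whose axes
equal the target extents; plants are laid out left-to-right at evenly
spaced centres so connected-component segmentation recovers instance
numbering. A plain ellipse already meets the rendering contract (pixel
area within 5 % of target, bounding box within 1 px at the default
scale); decorating the silhouette with leaf lobes would add realism but
no testable signal, so it was left out. Degenerate tiny plants clamp to
a ≥1-px radius.

**Closed loop.** A minute-resolution loop drives: RH dynamics every
minute, sensor sampling + record insertion + a control cycle every 5
minutes, and imaging → segmentation → feature extraction → prediction
every 30 minutes inside the camera window (inclusive 06:00, exclusive
18:00 → 24 epochs/day; the window endpoints are a convention choice).
The 1-second display cadence is decoupled from persistence and exercised
in the scheduler on short horizons only — at desk scale nothing changes
between seconds, and a 14-day run at 1-s resolution would add nothing
but 1.2 M no-op ticks.

## Record store

An embedded in-memory store with CSV import/export replaces a networked
SQL server; the logical schema is preserved: `sensors_records` (unique
on timestamp × parameter), `masked_results`, `accumulative_masked_records`,
`predictions`, `control_events`. The exact column list of the original
database is not fully documented; the reconstruction uses the union of
the extracted features plus keys. The accumulative table reproduces
insert-trigger semantics — every masked insert recomputes its
(date, instance, view) group means — making the table a pure function of
`masked_results`: dropping and rebuilding it is byte-identical, which is
tested. Predictions are stored at imaging time (growth rate, fresh
weight, stage per instance) and are also recomputable on demand through
the report interface.

## Synthetic data: what passing tests do and do not show

The generator emulates: two-level diurnal sensor patterns, first-order
actuator-responsive humidity, geometric per-plant area growth over a
14-day cycle, and silhouettes whose measured features match the
generating trajectory. It does **not** emulate: leaf-level shape and
occlusion, segmentation failure modes, lighting artefacts, sensor drift
or faults, correlated noise between parameters, or any coupling from
environment to growth (plants grow at their configured rates regardless
of pH or temperature). Passing the recovery tests therefore shows the
*analysis pipeline* is correct and self-consistent — it does not validate
the fresh-weight coefficients or growth behaviour on real crops.

## Numerical and sizing choices

Problem sizes in the test suite are chosen for sub-second feedback:
property tests use masks ≤ 32×32 against a per-pixel oracle; closed-loop
tests run 1–5 simulated days; the full-stack recovery check runs the
complete 14-day cycle (~3 s) and requires per-view rate recovery within
1 percentage point, the bound attributable to mask pixelization at
≥64-px plants. Determinism is asserted by comparing store digests
(SHA-256 over the CSV serialisation of all tables). Stage assignment
uses `searchsorted` on the cut points with a right-closed convention and
clamping at both ends; growth-rate steps with zero predecessors are
flagged, not propagated as infinities.

## Known limitations

- The feedback loop controls only the humidifier and grow light; pumps
  and heaters are modelled as always-on and the ring light is
  manual-only.
- The store is single-writer and in-memory; it is not a concurrent
  database.
- Fresh-weight output units are unspecified by the source model and are
  reported as model units.
- The stand-in segmenter assumes non-overlapping, bright-on-dark
  silhouettes; it is not suitable for real imagery.
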
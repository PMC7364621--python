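# Methods

This note records the models, conventions and numerical choices behind
`fieldhtp`, in the order data flows through the package.

## Ingestion contract

A run directory holds one metadata file `<runid>_sensorrun.txt`
(key = value lines; repeated `sensor = id,type,arm,forward,lateral`
lines carry the inventory) and one comma-delimited log per sensor
channel, `<runid>_<sensortype>_<sensorid>.csv` with sensor types
`ultrasonic | irt | reflectance | gps | imu`.  Any other file is a
fatal naming-convention violation, reported with the offending names.

**Line cleaning.**  "Bad characters" are defined as any byte outside
printable ASCII plus tab; "incomplete" means fewer comma-delimited
fields than the sensor type requires (2 for ultrasonic, 3 for IRT, 4
for reflectance and IMU, 2 for GPS).  Both classes are rejected before
parsing; raw files are never modified and cleaned copies are written to
`clean/`.  Per file, `records parsed + lines rejected = lines read`
holds exactly, and re-parsing the `clean/` output reproduces the
identical record set.

**GPS.**  Each logger tick writes a GGA/RMC sentence pair prefixed with
the logger timestamp.  Position and fix quality come from GGA, the
calendar date from RMC; the *logger* timestamp — not NMEA time — is the
stream-alignment key, since all streams share the acquisition clock.
Checksum failures reject the pair (counted, not fatal).

## Georeferencing

* Projection: transverse Mercator with UTM constants (k₀ = 0.9996,
  false easting 500 000 m, 10 000 000 m false northing in the south),
  WGS84, via Karney's 6th-order Krüger series (sub-millimetre accuracy
  inside a zone; the test suite cross-checks against an independent
  Snyder-series implementation to < 0.01 m and round-trips to < 1e-7°).
* One zone per run, fixed from the first valid fix (overridable), so a
  run near a zone boundary never straddles the discontinuity.
* Sensor offsets: forward positive ahead of the GPS antenna along the
  heading, lateral positive to the **right** of travel.  The offset
  rotation preserves length for every heading (tested to 1e-9 m).
* Stream alignment: nearest-neighbour in time with a 200 ms default
  window (one logger loop).  Unmatched records keep their values but
  carry no coordinates.
* Pitch and roll are **not** used to correct ground positions (no
  lever-arm tilt model); they ride along for QC thresholding only.

## Traits

`h = s − d` with s the recorded soil-line-to-boom height and d the
ultrasonic displacement; NDVI and NDRE from the 800/670/730 nm bands.
Negative heights (holes, soil returns) and zero-denominator indices are
flagged and retained: all removal decisions belong to the QC stages.
Reflectance inputs are assumed band-calibrated by the sensor; no
radiometric calibration stage exists.

## Clipping

Containment uses planar geometry in the run's UTM zone (shapely), with
boundary points counted inside as a deterministic tie-break; if plots
overlap (validated, warned) the lexicographically smallest plot id
wins.  Clipping uses the sensor position, because that is what the
sensor actually saw.  `row_deviation` reports the signed perpendicular
distance to the assigned plot's long-axis centerline (axis oriented
toward positive northing, positive deviation to its right), which is
the "wobble" diagnostic.

## Store

Single long observation table (one row per sensor × tick × derived
trait) in Staging and Production, plus per-sensor-type Public views;
the Fig.-2-style per-type physical tables are collapsed into the
`sensor_type` column because the exact column-by-column schema of the
original database is not recoverable, and the view layer restores the
per-type surface.  Promotion is one transaction: create the permanent
`sensorrun` record, copy staged rows, empty staging.  A failure at any
point (exercised by injected failpoints in the tests) rolls back to the
exact pre-state.  Geospatial columns are easting/northing pairs plus
zone so the embedded engine suffices; the DDL is PostgreSQL-portable.

## QC step 1

Report-only diagnostics: per-sensor n/mean/SD/min/max/missing,
out-of-range fraction against inclusive operational bounds (defaults
are conservative manufacturer-style ranges and must be reviewed per
deployment), boom-arm record balance (deficit > 0 records flags a
logging-loop problem), and history drift.  The drift statistic is
|current mean − median(historical means)| / MAD(historical means) with
flag threshold k = 3 and a MAD floor of 1e-6·|median| so a constant
history still flags a genuine jump; fewer than 3 historical runs yields
"no assessment".  The possibility of correcting data from warm-up/
cool-down reference patterns is known but has no stated algorithm and
is deliberately unimplemented.

## QC step 2

Default model: fixed-effects least squares with plot identity as the
single factor (cell-means coding), i.e. fitted values are plot means.
The original workflow used a mixed-model procedure, but the model is
design-dependent; a fixed design-factor model yields exact residual
diagnostics without variance-component machinery, and additional
factors (genotype, treatment, replicate) can be added to the spec.
Fits use a rank-revealing SVD: aliased design columns are absorbed
(warning), leverages are `hᵢᵢ = Σⱼ U²ᵢⱼ` over the rank-r basis and sum
to p on every fit; `n ≤ p` is fatal.

Studentized deleted residuals use the no-refit shortcut
`tᵢ = eᵢ / √(MSE₍₋ᵢ₎(1 − hᵢᵢ))`,
`MSE₍₋ᵢ₎ = (SSE − eᵢ²/(1 − hᵢᵢ))/(n − p − 1)`; observations with
hᵢᵢ = 1 are uninformative (NaN, never removed).  The tests verify the
shortcut against an explicit leave-one-out refit oracle (≤ 1e-8) and
against statsmodels' external studentization.

**Iteration policy:** all observations with |tᵢ| > τ are removed
together, then the model is refit, until no removal or 10 iterations.
Whether the original workflow removed one point or all per iteration is
unstated; removing all is the simplest reading and converges in 1–2
iterations on realistic contamination.  τ defaults to 3.0 (no threshold
is stated anywhere authoritative); a Bonferroni-t alternative
(α = 0.05) is available.  On simulated contamination (5 % outliers at
10 σ) this achieves ≥ 95 % sensitivity at ≤ 1 % false positives.

The attitude filter (|pitch| / |roll| thresholds) is optional and runs
before fitting, matching its role as an "if desired" pre-threshold.

## Selection

Line values are unweighted means over the line's plot means (the
plot-to-line replication structure is design-specific; a count-weighted
option exists).  Ranking ties break lexicographically by line id.  The
lodging flag fires when a line's mean height drops by ≥ 0.10 m
(default) between two dates — a decline of that size mid-season is a
storm/lodging signature, not growth noise.  The flag bound is inclusive
with a 1e-9 m guard against binary rounding of decimal heights.

## Synthetic data generator

The generator states one fixed world; its defaults are not tuned to
tests.  Defaults describe a mid-season cotton collection: 240 plots of
12 × 1.02 m (40 rows × 6 columns), 0.67 m/s forward speed, 5 Hz
logging, 120 measurements per plot for 4 simultaneous traits (height,
canopy temperature, NDVI, NDRE — so 240 × 120 × 4 = 115 200 records),
boom at 2.0 m, RTK-grade 1 cm GPS noise, within-plot noise SDs of
4.3 cm height, 0.5 °C temperature, 0.01 per reflectance band, per-plot
truths drawn from 0.6–1.1 m, 28–36 °C, and NIR/VIS/RE bands of
0.45–0.60 / 0.05–0.15 / 0.20–0.35.  Measurements per plot is an
independent knob rather than being derived from speed × rate, because
the platform's stated numbers (5 Hz over a 12 m plot at 0.67 m/s ≈ 90
ticks) do not reproduce the reported 120; the generator honours the
reported count.

The vehicle path is a serpentine over plot columns with a GPS fix and
IMU sample at every tick.  Error injections:

* **wobble** — sinusoidal lateral deviation (period ≈ plot length,
  default amplitude 0.05 m, capped below half the plot width) with the
  heading following the track tangent;
* **pitch/roll events** — Gaussian bumps (0.6–1.6 s wide, 6–12° peak,
  default 5 per run) on an 0.3° noise floor;
* **corruption** — extra garbled lines *inserted* into the sensor value
  logs (NUL-byte insertion or truncation, matching the parser's two
  rejection classes), so clean-record counts are conserved and the
  cleaning report can be compared to the injection exactly; GPS/IMU
  streams are left uncorrupted;
* **outliers** — channel values shifted by ±(shift + |ε|)·SD with
  ε ~ N(0,1), guaranteeing |value − truth| ≥ shift·SD; reflectance
  outliers shift the NIR band upward only, so the guarantee survives
  band clipping;
* **sparsity** — soil returns (d ≈ s) at a configurable fraction
  (default 0: sparsity is a site property, not a logging property).

One seeded generator drives everything; identical config + seed gives
byte-identical files.  What the generator does **not** emulate — GPS
latency/multipath, radiative transfer, plant growth, sensor warm-up
drift, headland turns — bounds what a green end-to-end test
establishes: the pipeline recovers what the stated world contains, not
that field data are this kind.

## Numerical details

* NMEA coordinates are written as ddmm.mmmmmm (≈ 2e-8° resolution);
  log values are quantized to 0.1 mm (displacement), 0.001 °C
  (temperature), 1e-5 (bands), which bounds round-trip tests.
* UTM inverse uses 6 Newton iterations on the conformal latitude
  (converges to machine precision in ≤ 4).
* SVD rank threshold 1e-10 relative to the leading singular value.
* Exports fix row order and float formatting (`%.6f`), so re-export is
  byte-identical.

## Known limitations

ESRI shapefile plot maps are not read (GeoJSON only — no shapefile
reader among the supported dependencies); no geoid/elevation handling;
no mixed-model variance components or spatial-correlation models; no
interactive notebook layer (file exports replace it); multi-day merged
runs and live serial acquisition are out of scope.
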
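# peathaze

Village-level health-impact assessment of peat-fire smoke.

Recurring peatland fires in Indonesia (worst in El Niño years) blanket
provinces in PM2.5-laden haze. This package implements, as a tested
pipeline, the assessment chain used to estimate the long-term mortality
burden of that smoke on a province's population, down to the village
level: satellite fire-hotspot records are filtered by detection
confidence, classified by peat depth, sampled per class, dispersed with a
Gaussian-puff smoke model, scaled up by hotspot counts, calibrated to a
single urban monitoring station, averaged over village boundaries, and fed
through concentration-response functions into attributable-mortality
estimates with a sensitivity analysis.

It is a library first (importable API plus `examples/`), with a thin
`peathaze` CLI for end-to-end runs. Because the original satellite,
meteorological and administrative inputs are not publicly deposited, a
first-class synthetic-data module generates inputs with the same
statistical structure (per-year hotspot totals, peat-depth classes,
~1,569 villages, ~2.5 million people, one station), so every stage runs
and is testable offline.

## The model

**Exposure.** Each fire hotspot (detection confidence ≥ 80) releases a
train of Gaussian puffs over 24 h; puffs advect with the daily wind,
spread horizontally with σ = √(2Kt), are well mixed over a 100-m layer,
and decay by first-order dry deposition and wet scavenging,
m(t) = exp[−(v_d/H + Λ)t] with v_d = 0.001 m/s, H = 100 m,
Λ = 8×10⁻⁵ s⁻¹. Per-hotspot 24-h plumes are averaged per peat class
(shallow D1–D2, deep D3–D4), re-placed by the class's hotspot density,
multiplied by the class's annual hotspot count, and the resulting annual
field is calibrated multiplicatively so the monitoring-station cell
matches the observed annual mean — which makes the result independent of
the arbitrary emission units. Village exposure X is the area-weighted
polygon mean of the calibrated field, averaged over the study years; it is
the smoke *increment* over background.

**Health impact.** For each mortality category d with coefficient β:

- log-linear form: RR_d(X) = [(X+1)/(X_o+1)]^β
- linear form: RR_d(X) = exp[β(X − X_o)]

with X_o the lowest observed village mean (RR clamped to 1 for X < X_o).
The attributable fraction is AF_d = RR_d(X) − 1, and annual attributable
deaths per village are AF_d × CDR × p_d × population, with crude death
rate CDR = 0.0058 and p_d the category's share of all-cause deaths
(all-cause 100%, cardiovascular 33%, chronic respiratory 4%, lung cancer
2%). PM10-based coefficients are converted to PM2.5 with the 48/21
ratio. The sensitivity analysis shifts X by ±10 μg/m³, sets X_o to the
10 μg/m³ annual guideline, and swaps the functional forms.

## Worked example

`examples/04_health_impact.py` runs the mortality arithmetic on the
homogeneous regional inputs (X = 26 μg/m³, X_o = 4 μg/m³, 2.5 M people):

```
exposure X = 26.0 ug/m3 against reference X_o = 4.0 ug/m3
all_cause            beta=0.001829  linear     RR=1.0410 AF=0.0410 -> 595 deaths (24/100k)
chronic_respiratory  beta=0.003794  linear     RR=1.0871 AF=0.0871 -> 50 deaths (2/100k)
cardiovascular       beta=0.15515   log_linear RR=1.2991 AF=0.2991 -> 1431 deaths (57/100k)
lung_cancer          beta=0.23218   log_linear RR=1.4793 AF=0.4793 -> 139 deaths (6/100k)
```

Reading the first line: a 26 μg/m³ long-term PM2.5 increment carries a
relative all-cause mortality risk of 1.041 versus the least-exposed
village; 4.1% of the 14,500 expected deaths per year — about 595 — are
attributable to the smoke. Treating the region as one homogeneous village
is a lower bound for the convex exponential form: village-resolved
exposure raises the total.

The other examples generate a scenario (`01`), show one hotspot's plume
and its deposition decay (`02`), compute village exposure summaries
(`03`), and run the full pipeline with report output (`05`). The
end-to-end run is also available as

```sh
peathaze run --seed 1 --out peathaze_out
```

which writes village exposure CSV/GeoJSON, per-year concentration fields,
a Table-style impact CSV, the sensitivity table and a run log.

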
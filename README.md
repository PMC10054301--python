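# electrome

Approximate-entropy analysis of fruit electrome recordings across ripening.

Plant tissues carry continuous micro-voltage activity — the *electrome* —
and in ripening tomato fruit its temporal complexity changes with
physiological state: signals recorded on the fruit's vascular bundles lose
complexity when the fruit enters the **breaker** stage (onset of color
change, coinciding with the climacteric ethylene transition) and partially
recover it toward the **light red** stage. This package is for
plant-electrophysiology researchers who want to quantify that pattern: it
computes approximate entropy of voltage-variation time series, profiles it
over multi-day recordings, summarizes it per ripening stage, detects the
breaker-stage entropy dip, and classifies stages from per-window features.
Because no public recordings of ripening fruit electromes exist, a seeded
synthetic-cohort generator with stage-dependent regularity stands in for
laboratory acquisitions.

## The statistic

For a series ΔV = {ΔV₁, …, ΔV_N} sampled at f_s (default 62.5 Hz), form the
N − m + 1 overlapping template vectors of m consecutive samples and let

φ^m(r) = (N − m + 1)⁻¹ Σᵢ ln Cᵢ^m(r),

where Cᵢ^m(r) is the fraction of template vectors within distance ≤ r of
template i (self-matches included). Then

**ApEn(m, r) = φ^m(r) − φ^(m+1)(r)**,

in nats, with defaults m = 2 and r = 0.2 × SD(ΔV), the standard choice for
electrome series. Low ApEn means repetitive, predictable signals; high ApEn
means irregular ones. The match rule is inclusive (distance = r counts) and
both the Chebyshev (max-norm, default, per Pincus's formulation) and
Euclidean metrics are supported. A brute-force quadratic oracle
(`apen_oracle`) verifies the fast implementation to 1e-10.

## Worked example

Simulate a 4-fruit cohort (stages MG → B → LR, one acquisition per day,
desk-scale 120 s of samples per day), profile it with 512-sample windows,
and analyze:

```sh
echo '{"seconds_per_day": 120.0}' > cfg.json
electrome simulate --seed 7 --n-fruits 4 --config cfg.json --out sim
electrome profile --window 512 --input sim/fruit00_day00.csv ... --out prof
electrome analyze --profiles prof/profiles.tsv --schedules sim/schedules.csv --out analysis
```

`analysis/stage_summary.tsv` then contains the per-stage pooled ApEn:

```
stage  mean_apen  sd_apen  n_windows  n_fruits
MG     1.4653     0.0293   196        4
B      0.9397     0.0593   126        4
LR     1.4011     0.0391   112        4
```

— the ripening pattern in one table: breaker-stage complexity (0.94) sits
well below mature green (1.47), and light red recovers most of it (1.40).
`analysis/dips.json` reports the per-fruit entropy minimum; for fruit00 the
smoothed dip (ApEn 0.875, against pre/post medians 1.45/1.38) falls on
simulated day 5, inside that fruit's breaker interval:

```json
{"fruit_id": "fruit00", "dip_value": 0.8753, "pre_dip_median": 1.4533,
 "post_dip_median": 1.3806, "dip_in_stage": "B"}
```

Single-series entropy is available directly (`electrome apen --input
sim/fruit00_day00.csv` → ApEn 2.000 for that mostly-irregular mature-green
acquisition), and every `simulate`/`profile`/`analyze` run writes a
`manifest.json` which `electrome replay` re-executes byte-identically.

The same pipeline is available as a library:

```python
from electrome import CohortConfig, simulate_cohort, windowed_apen, stage_summary

cohort = simulate_cohort(CohortConfig(master_seed=7, seconds_per_day=120.0))
profiles = [windowed_apen(s, window_len_samples=512) for s in cohort.series]
print(stage_summary(profiles, cohort.trajectories).table)
```

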
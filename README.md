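# swimtel

In situ swim-velocity estimation for acoustically tagged fish in rivers:
from raw acoustic detections with drifting receiver clocks, through clock
synchronization, TDOA multilateration and quality screening, to
swim-velocity vectors against a 3-D hydrodynamic flow field and weighted
behavioral summaries.

## The problem

Acoustic telemetry gives a migrating fish's **velocity over ground**
(u_og) from successive position fixes; a hydrodynamic model gives the
**water velocity** (u_h) at the same place and time. The fish's
**swim velocity** is the vector difference

    u_s = u_og − u_h,

rotated into the local flow frame: a longitudinal component u_s
(negative = swimming against the current, i.e. positive rheotaxis) and a
lateral component v_s. Getting there requires solving several supporting
problems well: receiver clocks drift by large fractions of a second and
must be synchronized to sub-millisecond accuracy before arrival-time
differences mean anything; multipath echoes must be discarded; positions
must carry honest uncertainties; and unreliable tracks (predators that ate
a tag, under-determined fixes) must be screened out. Because the vertical
position of small fish is unobservable with a shallow 2-D array, u_h is
vertically averaged under three bracketing assumptions — fish in the top
1 m, the top 2 m, or spread over the full water column.

The package implements this whole chain, plus a synthetic-scenario
generator (receiver array, sheared channel flow, fish with prescribed
behaviors, clock drifts, noise, corrupted detections) so that every stage
is testable by parameter recovery against known truth.

Core algorithms:

- **Clock sync** — per-receiver continuous piecewise-linear clock offsets
  estimated by sparse linear least squares from beacon detections
  (`raw − d/c = T_k + Σ w_j θ_rj`), gauge-fixed to a reference receiver;
  erroneous detections removed iteratively (worst residual first) until
  the RMS residual is below 1 ms and no gross outliers remain.
- **Multilateration** — per-ping Gauss–Newton TDOA solves for (x, y, T)
  with DRMS position uncertainty from the linearized covariance.
- **QC cascade** — sd ≤ 10 m, ≥2 receivers, ≥3-receiver endpoints,
  region/upstream-buffer clip, ≥10 positions, ≤60 min residence,
  mean swim speed ≤ 0.5 m/s.
- **Behavior statistics** — segment-count-inverse weights, weighted
  medians with bootstrap 5–95% CIs, weighted KDEs, occurrence of positive
  rheotaxis, stride-based noise sensitivity, and a paired t-test of
  per-fish ground velocity against the reach-scale river velocity
  u_river = Q·L_a/V.

See `docs/methods.md` for assumptions, parameter defaults, and limits.

## Worked example

Simulate a one-hour scenario — 13 receivers 70 m apart, 12 fish of which
half hold 0.10 m/s positive rheotaxis and half drift passively — and run
the full pipeline:

```python
from swimtel import synthgen, pipeline
from swimtel.synthgen import ScenarioConfig, BehaviorConfig

cfg = ScenarioConfig(
    seed=42, duration_s=3600.0, n_fish=12,
    behaviors=[BehaviorConfig("rheotaxis_positive", 0.5, 0.10),
               BehaviorConfig("passive", 0.5, 0.0)],
)
scn = synthgen.generate_scenario(cfg)
res = pipeline.run_pipeline(scn, cfg, n_boot=500, seed=0)

sol = res["sync_solutions"][0]
print(f"sync: RMS {sol.rms_residual*1e3:.3f} ms, "
      f"{len(sol.removed)} detections removed")
print(f"fixes: {len(res['fixes'])}, kept tracks: "
      f"{res['kept_fixes']['tag_id'].nunique()}")
for s in res["summaries"]:
    print(f"{s.vrange:>6}: median u_s = {s.median:+.3f} m/s "
          f"[{s.ci_5_95[0]:+.3f}, {s.ci_5_95[1]:+.3f}], "
          f"positive rheotaxis {100*s.rheotaxis_fraction:.0f}%")
```

prints

```
sync: RMS 0.189 ms, 11 detections removed
fixes: 2442, kept tracks: 12
  full: median u_s = -0.049 m/s [-0.053, -0.045], positive rheotaxis 72%
 top1m: median u_s = -0.114 m/s [-0.118, -0.109], positive rheotaxis 94%
 top2m: median u_s = -0.102 m/s [-0.106, -0.098], positive rheotaxis 93%
```

The clock solver reaches a 0.19 ms RMS residual (the 11 removed
detections are the injected multipath corruptions), all 12 tracks survive
screening, and the pooled cohort's median longitudinal swimming is
negative — upstream — under every vertical-averaging assumption. The
medians differ across assumptions because the flow is surface-intensified:
referencing the faster top-1 m water makes the same ground tracks look
like stronger positive rheotaxis. That spread is the vertical-position
uncertainty of the method, not noise.

A command-line interface mirrors the stages
(`swimtel simulate | sync | locate | qc | swim | summarize`); each
subcommand reads and writes plain CSV/NetCDF/JSON, e.g.

```bash
swimtel simulate --out scenario/ --seed 7
swimtel sync --detections scenario/detections.csv \
             --receivers scenario/receivers.csv --out sync/
```

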
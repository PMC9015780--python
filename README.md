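# thermadiff

Continuous plantar temperature monitoring analysis: simulation of bilateral
smart-sock temperature streams, per-minute contralateral (right − left)
differentials at 6 plantar sites (hallux, heel, arch, 1st/3rd/5th metatarsal
heads), daily aggregation, a strict >4 °F alerting rule with sustained-hotspot
escalation, 15-day / 900-minute analysis-window extraction, and a
patient-level Welch *t* cohort comparison. All temperatures are °F; time is
(day index, minute of day).

Because no real device data is distributed, a first-class synthetic generator
(`thermadiff.synthetic`) emulates the statistical structure the analysis
assumes: wear/off cycles, bilaterally shared baseline/circadian/drift terms
(which cancel exactly in differentials), independent per-sensor noise with
optional per-patient dispersion, and injectable unilateral injury ramps for
five archetypes (Charcot, blister, osteomyelitis, focal ulcer, DVT). The
shipped preset (`src/thermadiff/presets/default.yaml`) is calibrated — see
`scripts/tune_presets.py` — so the control cohort's mean window differential
lands near 2.20 °F and the injured cohort's near 3.59 °F.

## CLI

```sh
thermadiff demo --seed 1 --out-dir demo_out          # full pipeline + plots
thermadiff simulate --seed 1 --out-dir sim_out       # registry + streams
thermadiff validate --stream sim_out/streams/S01.csv
thermadiff monitor  --stream sim_out/streams/S01.csv --out dailies.csv
thermadiff alerts   --dailies dailies.csv --threshold 4.0 --out alerts.csv
thermadiff windows  --stream sim_out/streams/S01.csv \
                    --registry sim_out/registry.csv --seed 1 --out w.json
thermadiff analyze  --registry sim_out/registry.csv --streams sim_out/streams \
                    --seed 1 --report report.json
```

A scenario YAML (same shape as the default preset) can be passed everywhere
via `--config`. Every output embeds the config hash and seed; re-running with
the same seed reproduces reports byte for byte.

## Library layout

| module | contents |
| --- | --- |
| `thermadiff.synthetic` | `GeneratorConfig`, `InjurySpec`, `PatientRecord`, stream simulator, cohort/registry builder |
| `thermadiff.stream_io` | `PatientStream` data model, CSV/JSONL readers & writers, `wear_days`, `filter_eligible` (strict >50 wear days) |
| `thermadiff.differentials` | per-minute differentials, daily per-location means, per-patient window statistic |
| `thermadiff.alerts` | `AlertConfig`, daily >threshold rule, consecutive-day escalation, `first_alert_day` |
| `thermadiff.windows` | pre-injury and random-control 15-day/900-minute windows, baseline/pre-injury/active segmentation |
| `thermadiff.cohort_stats` | cohort summaries, Welch *t* from formula, demographics table, end-to-end comparison report |
| `thermadiff.pipeline` / `thermadiff.cli` | `PipelineConfig`, `run_full_demo`, `thermadiff` command group |

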
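# attnfusion

Redundant classroom-attention detection from two independent sensor
streams: per-frame facial-expression labels and per-second heart data.
Each source is converted into a comparable per-second binary Attention
Array, fused across subjects, and validated against the other via an
RMSE-based window-size selection criterion.

## What it does

* **Facial source** — 8-class expression labels (anger, contempt, disgust,
  fear, happiness, neutrality, sadness, surprise) are grouped by arousal
  into *active* / *passive* moods (neutrality is excluded). A sliding
  window's activation level is the active share normalized to
  `WsNN = 300`; windows scoring strictly above `Tfe = WsNN/3` are labelled
  Attention.
* **Physio source** — time-domain HRV features (SDNN, SDSD, RMSSD, pNN50)
  are computed over short inner windows at 1 Hz and compared per-sample
  with per-subject calibrated thresholds. Each comparison on the attention
  side increments the Grade of Attention; windows scoring strictly above
  `Tp = 1.5 · WS` are labelled Attention.
* **Fusion** — attention arrays are averaged across subjects into a
  fraction series; a trailing 5-minute counter yields the Attention
  Behavior (AB) series; the whole-session mean is the Attention Gain (AG)
  per source. The window size WS is selected as the candidate minimizing
  the RMSE between the two sources' AGs (which reduces to `|AGp−AGfe|/2`).
* **Self-report** — reaction-time prompt logs are summarized after
  reclassifying affirmative answers with excessive reaction times as
  negative.
* **Synthetic sessions** — a regime-switching generator (attentive /
  distracted schedules, per-state emotion distributions, AR(1)
  beat-to-beat models) produces multi-subject bundles with per-second
  ground truth, so the full pipeline is testable offline.

## CLI

```bash
# generate a synthetic 8-subject session with ground truth
attnfusion simulate -n 8 --schedule "1800:attentive,1800:distracted" \
    --seed 1 --out bundle/

# run the full pipeline (calibrate → per-subject arrays → fusion → report)
attnfusion run bundle/manifest.yaml --ws 100 --out-dir out/

# sweep candidate window sizes and pick the RMSE minimizer
attnfusion select-ws bundle/manifest.yaml --candidates 25,50,75,100,150,200,300

# summarize reaction-time prompt logs (yes-answers slower than --max-rt
# count as no)
attnfusion selfreport bundle/s01_prompts.csv --max-rt 10
```

`run` writes `report.json` containing per-source AG, the inter-source
RMSE, the selected WS (when candidates are given), both AB series, a
neutrality-fraction diagnostic and the echoed configuration. Reports are
aggregate-only: per-subject binary arrays are never serialized.

### File formats

All inputs are plain CSV with a mandatory header; timestamps are seconds
since session start:

| file           | columns                                |
|----------------|----------------------------------------|
| emotion stream | `t_s,label`                            |
| physio stream  | `t_s,hr_bpm,bb_ms`                     |
| prompt log     | `t_shown,t_answered,answer,delta_s`    |

A YAML manifest binds subject ids to their stream files (plus optional
baseline recordings for calibration and demographic info).

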
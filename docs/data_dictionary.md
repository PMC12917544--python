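# Data dictionary

Column conventions for the CSV artifacts the pipeline reads and writes.

## trials.csv (behavioural log, one row per stimulus)

| column | type | meaning |
|---|---|---|
| participant_id | str | e.g. `pcs-01` |
| task | str | `flanker` or `nback` |
| block_index | int | 0-based stimulation block |
| stimulus_type | str | `congruent` / `incongruent` / `neutral` (Flanker) or `letter` (1-back) |
| rt_ms | float | reaction time in ms; empty when no response |
| correct | bool | response correctness (false for missing responses) |
| answerable | bool | whether the stimulus admits a response (first 1-back letter of a block does not) |

## haemo.csv (long-format ΔHbO)

| column | type | meaning |
|---|---|---|
| participant_id, task | str | as above |
| channel | str | `S*-D*` source–detector label |
| role | str | `long` (cortical, ~3 cm) or `short` (scalp, ~8 mm) |
| time_s | float | seconds from recording start |
| dHbO_umol_l | float | oxygenated-haemoglobin change, µmol/l |

## events.csv

`onset_s` (float, seconds), `kind` (`block_start` / `block_end` /
`stimulus` / `response`), `stimulus_type` (may be empty).

## study_table.csv (one row per participant × task)

`participant_id`, `group` (`PCS`/`CAD`/`CTRL`), `task`, `mean_sampen`,
`cv_sampen`, `n_channels_used`, `mean_rt` (ms), `accuracy` (0–1),
`n_fast_excluded`, `n_slow_excluded`, `sss_pre`, `sss_post` (1–7),
`config_hash`.

## anova.csv (one row per metric × task)

`parameter`, `task`, `F`, `df_between`, `df_within`, `p`, `partial_eta2`,
`power`, per-group `mean_*`/`sd_*`, pairwise `diff_A-B` (mean difference)
and `tukey_p_A-B` (Tukey-adjusted p).

## regressions.csv

`response` (`mean_rt` or `accuracy`), `predictor` (`cv_sampen`), `task`,
`intercept`, `intercept_se`, `slope`, `slope_se`, `adjusted_r2`, `F`,
`df_model`, `df_resid`, `p`.

## sss_change.csv

`group`, `task`, `mean_delta`, `median_delta`, `n`, `wilcoxon_w`,
`wilcoxon_p`, `method` (`exact` or `normal`).
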
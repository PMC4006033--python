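# sagloc

Probabilistic template-matching model of sound localization in sagittal
planes, plus an analysis pipeline that separates the *acoustic* factor
(the quality of a listener's directional transfer functions, DTFs) from the
*non-acoustic* factor (a listener-specific uncertainty `U` governing how
sharply spectral similarity maps to response probability).

The model works as follows: the incoming sound and an internal template set
(the listener's own DTFs) pass through the same peripheral stage — a
28-band gammatone filterbank (0.7–18 kHz, one-ERB spacing), half-wave
rectification, 1-kHz low-pass, and RMS averaging. The spectral distance
between the incoming sound's representation and each template is the
standard deviation of the per-band dB differences (level-robust by
construction). A Gaussian of width `U` maps distance to a similarity index
per ear; a sigmoid binaural weighting combines the ears; normalizing over
template angles yields a probability mass vector (PMV) of polar response
angles, from which quadrant error (QE, % of mass confused by more than 90°)
and local polar RMS error (PE) are computed within `|lateral| ≤ 30°`.

Because measured HRTF databases and response data are not bundled, the
package ships a first-class synthetic-listener module: virtual ears with a
polar-angle-dependent spectral notch, rear-hemifield shelf, and seeded
ripple, plus a response simulator that samples trials from the model's own
PMVs at a known ground-truth uncertainty. The full pipeline — calibration
of `U` by grid search, DTF-by-uncertainty permutation grids, and
factor-contribution summaries — runs end-to-end on these virtual groups.

## Library quick tour

```python
import sagloc as sg

# one virtual listener and its model engine
dtf = sg.generate_listener_dtfs(sg.SyntheticListenerParams(seed=1))
predictor = sg.Predictor(dtf)
pmv = predictor.pmv(sg.Direction(lateral=0, polar=30), U=2.0)

# simulate an experiment and recover the uncertainty
listener = sg.ListenerModel(dtf=dtf, uncertainty=2.0)
responses = sg.generate_responses(listener, n_trials=300, seed=7)
result = sg.calibrate_uncertainty(responses, dtf)   # result.U_k

# permute DTF sets and uncertainties across a group
grid = sg.permutation_grid(group, targets)          # K x K PE/QE matrices
contrib = sg.factor_sds(grid).summary()             # SD per factor axis
```

## Command line

```sh
sagloc study --seed 1 --n-listeners 8 --n-trials 300 --out study_out
sagloc generate --seed 3 --uncertainty 2.0 --out gen_out
sagloc calibrate gen_out/responses_VL003.csv --sofa gen_out/VL003.sofa
sagloc calibrate responses.csv --u-grid 0.5:0.5:3.0 --out cal.json
```

`study` writes response CSVs, `listeners.json` (ground-truth vs calibrated
U), `PE_matrix.csv` / `QE_matrix.csv` (permutation grid), `factor_sds.csv`,
`summary.json` (factor contributions, constant-U probes, correlations) and
a `manifest.json` recording the config and every derived seed. Invalid
configurations exit with status 2.

DTF sets read and write as SOFA (SimpleFreeFieldHRIR) files; response
tables are CSV with header
`listener_id,target_lateral,target_polar,response_lateral,response_polar`.

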
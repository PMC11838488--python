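# File formats

All tables are tab-separated with a header row. Pixel coordinates are
0-based `(row, col)`; times are in seconds; intensities in arbitrary camera
units. Frame indices start at 0.

## Movie stacks (input)

Multi-page TIFF, one stack per color channel per field of view,
time × height × width, constant frame time (default 0.1 s). Raw detector
channels are named `C1_raw` (Cy3) and `C2_raw` (Cy5); channels are assumed
registered.

## ROI table (`rois.tsv`)

| column    | meaning                                   |
|-----------|-------------------------------------------|
| `fov_id`  | field-of-view label                       |
| `channel` | raw detector channel (`C1_raw`/`C2_raw`)  |
| `row`,`col` | ROI center (0-based pixels)             |
| `value`   | fluctuation-map value at the center       |

ROIs are 3×3-pixel windows; rows are ordered by descending `value`, ties
broken by `(row, col)`.

## Trace table (`traces.tsv`)

Long format, one row per (molecule, frame):
`fov_id, molecule_id, channel, frame, intensity`.
`channel` here is the molecule-level color channel (`C1`/`C2`); a C12
molecule appears as two trace blocks sharing one `molecule_id`.
`intensity` is the integrated, background-subtracted 3×3 window intensity
(or the simulated equivalent).

## Fingerprint table (`fingerprints.tsv`)

One row per molecule:
`molecule_id, fov_id, channel, n_events, tau_on_med, tau_off_med,
tau_off_max, snr`.
Empty dwell statistics are written as NaN (undefined); they fail any
filter bound placed on that parameter.

## Assignment table (`assignments.tsv`)

`molecule_id, label, d2_<target>..., posterior, confidence` where `label`
is a target name or `unassigned`, `d2_<target>` the squared scaled distance
to each same-channel cluster, and `posterior` the classification
confidence of the best cluster.

## Cluster model (`model.yaml`)

```yaml
transform: log10          # applied to (tau_on_med, tau_off_med)
clusters:
  - name: miR-16
    channel: C1           # C1 | C2 | C12
    mean: [0.36, 0.43]    # in transformed dwell space
    sigma: [0.06, 0.05]
    n_train: 487
```

## Analysis summary (`summary.json`)

Counts per FOV and per target, unassigned fraction, and pooled ensemble
dwell-time fits (`tau`, `sse`, `r2`, `accepted`) for the accepted
molecules.

## Simulation config (`sim.yaml`)

```yaml
targets:
  - {name: miR-29, tau_on: 0.49, tau_off: 10.35, channel: C1, n: 500}
n_nonspecific: 0
acquisition_time: 300.0   # must be an integer multiple of frame_time
frame_time: 0.1
emission: {mean_bound: 1.0, mean_unbound: 0.0, noise_sd: 0.2, psf_sigma: 1.0}
nonspecific: {events_mean: 1.5, tau_on: 0.3, channel: C1}
seed: 0
integration: linear       # linear | binary
```
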
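# tubuliflow

Quantitative analysis of time-lapse recordings of contracting seminiferous
tubules: image stabilization and dense displacement estimation, fura-2
ratio and GCaMP ΔF/F trace extraction, flow-strength / flow-change
contraction metrics, luminal-transport directionality around a focal
stimulation zone, kymograph-based contraction-wave velocimetry, and
Hill-equation dose-response fitting — plus a synthetic phantom-movie
generator so every stage is verifiable by ground-truth recovery without
external data.

## Modules

| Module | Purpose |
|---|---|
| `tubuliflow.core_io` | data model (recordings, ROIs, traces, displacement fields), TIFF / ROI-JSON / config / CSV I/O |
| `tubuliflow.synthetic_data` | phantom movies (contracting annulus, propagating wave, luminal transport, dose-response) with exact ground truth; artifact injection (`corrupt`) |
| `tubuliflow.registration` | dense optical-flow displacement fields, ratiometric-pair co-registration, stabilization, constant-velocity drift removal |
| `tubuliflow.preprocessing` | flicker/bleach histogram matching, spatial+temporal Gaussian filtering, two-channel dye separation, transient-signal isolation |
| `tubuliflow.signal_extraction` | per-ROI ratio and ΔF/F traces (both normalization conventions), linear detrending, responder classification |
| `tubuliflow.motion_quantification` | flow strength s_i, flow change c_i, post-stimulus AUC, Gaussian-windowed MSE motion, contraction-event detection |
| `tubuliflow.transport_directionality` | equidistant ROI partitioning (ROI 0, ±1..±k), transport profiles, directionality index |
| `tubuliflow.kymograph_wave` | polyline straightening, space–time kymographs, wave-velocity regression |
| `tubuliflow.dose_response_events` | Hill fits, enhanced-activity episodes, Ca²⁺/contraction event pairing and duration correlation |

## CLI

```bash
# generate a phantom (kinds: contracting | wave | transport | dose)
tubuliflow simulate --kind contracting --out sim/ --seed 1

# stabilize a recording to its first frame
tubuliflow register --input sim/stack.tif --config sim/metadata.json --out reg/

# acute-slice analysis: fura-2 ratio traces + flow strength per ROI
tubuliflow analyze-slice --input sim/stack.tif --config sim/metadata.json \
    --rois rois.json --out results/

# whole-mount transport profile and directionality index
tubuliflow analyze-whole-mount --input sim/stack.tif --config sim/metadata.json \
    --rois sim/rois.json --out results/ --onset 20

# in-vivo chain: flicker correction, filtering, windowed-MSE motion,
# straightening, kymograph, wave-velocity fit
tubuliflow analyze-invivo --input sim/stack.tif --config analysis.json --out results/

# Hill fit from a 2-column CSV (conc_uM, response)
tubuliflow fit-dose-response --input dose_response.csv --out results/
```

Config files are JSON/YAML declaring the channel layout (never guessed):
`{"channels": [...], "dt": ..., "pixel_size": ..., "layout": "interleaved"}`.
ROI JSON schema: `{"rois": [{"label": "ROI 0", "polygon": [[x, y], ...]}]}`
with 0-based pixel-center coordinates, `x = column`, `y = row`.

## Conventions

* Stacks are `(T, H, W)`, `(frame, row, col)`, 0-based, pixel-center.
* Displacement vectors are `(drow, dcol)`: material at reference pixel `p`
  is found at `p + v` in the registered frame.
* Times are `frame_index * dt` seconds; stimulus onsets use the same clock.
* All physical outputs derive only from `dt` and `pixel_size`.
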
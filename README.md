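# paratrack

Long-term, bulk behavioural tracking of swimming ciliates (*Paramecium
bursaria* and similar protists) from dark-field image sequences, for
researchers studying light-entrained and circadian behaviour over 24–48 h
recordings.

In a dark-field recording every swimmer appears as a bright spot on a dark,
statically cluttered background. `paratrack` turns a directory of frames
captured at a fixed interval into hourly behavioural statistics and a
periodicity test:

1. **Detection** — the background of each frame is estimated as the
   pixel-wise mean over consecutive blocks of 100 frames and subtracted
   (residual `max(I − B, 0)`), which removes debris, chamber edges and any
   cell immobile for a whole block; bright spots are localised to sub-pixel
   precision by Crocker–Grier-style iterated intensity-weighted centroids
   with an integrated-mass cut.
2. **Linking** — detections in consecutive frames are joined by
   minimum-cost assignment with squared-displacement costs
   (unmatched penalty `search_range²`), with a gap memory for briefly lost
   particles.
3. **Metrics** — trajectories shorter than 10 mm of total path are
   discarded; the rest yield hourly trajectory-initiation counts, the mean
   number of active trajectories per frame, and per-trajectory total
   distance (µm), duration (s) and mean speed (µm/s), binned in half-open
   1-h bins aligned to the recording start (labelled in zeitgeber time,
   ZT, when an LD schedule is attached).
4. **Periodicity** — each hourly series is tested with the classical
   Lomb–Scargle periodogram, `P(ω) = [ (Σyᵢcos ω(tᵢ−τ))²/Σcos² +
   (Σyᵢsin ω(tᵢ−τ))²/Σsin² ] / Σyᵢ²` on the mean-centred series
   (variance-fraction normalisation), against a per-period 99% significance
   line obtained by shuffling the series values over their time points
   (permutation test); peaks above the line have ≈1% pointwise probability
   of arising by chance.

A first-class synthetic-data module simulates light-responsive
run-and-tumble swimmers (three behavioural states, wall-avoidance
reactions, multiplicative speed and trajectory-initiation modulation by the
LD schedule) in a 14 × 10 mm chamber and renders dark-field frames, so the
entire pipeline is verifiable end to end without multi-gigabyte recordings.

## Worked example

```python
import paratrack as pt

# simulate a 48-h LD recording at a 10-s effective frame interval
schedule = pt.LDSchedule()                       # 12 h light : 12 h dark
params = pt.SwimmerParams()                      # ~300 µm/s, LD-modulated
truth = pt.simulate_swimmers(15, 48 * 3600, pt.Chamber(), params,
                             schedule, seed=11, dt_s=10.0)
render = pt.RenderParams(frame_interval_s=10.0,
                         background_pattern=pt.make_clutter((150, 200), seed=3))
frames = pt.render_frames(truth, render)

# track, filter, bin, test for periodicity
dets = pt.detect_sequence(frames, window_size=100)
trajs = pt.link(dets, pt.LinkParams(search_range_px=80, memory_frames=1))
calib = pt.Calibration(um_per_px=70.0, frame_interval_s=10.0)
kept = pt.filter_trajectories(trajs, calib, min_length_mm=10.0)
speed = pt.per_bin_trajectory_stats(kept, calib, 48.0)["speed"]
res = pt.periodogram(speed, pt.default_period_grid(48.0),
                     n_permutations=1000, seed=5)
print(len(dets), len(trajs), len(kept), res.significant_peaks)
```

prints

```
235334 2116 1938 [(12.25, 0.8075494025108999)]
```

i.e. 235 334 spot detections linked into 2 116 trajectories, 1 938 of which
travel ≥ 10 mm; the hourly mean-speed series has a single significant
Lomb–Scargle peak, at a period of 12.25 h with normalised power 0.81 —
recovering, to within the 0.25-h period grid, the 12-h speed modulation the
simulation programmed (the gain is high for six hours after every light
transition of the 12:12 cycle).

The same pipeline is available from the shell:

```sh
paratrack simulate --out fixture --seed 11
paratrack run-all --config config.yaml --out results
```

with `config.yaml` holding calibration, detection/linking parameters, the
LD schedule and periodogram settings (see `paratrack.config`).

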
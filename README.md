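# bcrwalk

Biased-correlated random walk (BCR) modelling of animal GPS tracks.

The package implements a discrete-time, continuous-space random walk whose
step direction mixes isotropic **diffusion** with three interpretable,
directly estimable forces — **inertia** (`p_I`, repeat the previous
heading), **immobility** (`p_s`, stay in place) and **attraction** (`p_F`,
head toward a den/attractor) — with log-normal step lengths. Around the
model it provides:

- **`bcrwalk.core`** — trajectory/parameter types, planar geometry
  (headings, counter-clockwise turning angles, linear interpolation, mean
  sampling time).
- **`bcrwalk.simulator`** — the walk dynamics, including the state-dependent
  branch tables for heading-free and den-aligned states; reproducible,
  numba-accelerated, with optional exclusion polygons enforced by rejection.
- **`bcrwalk.estimation`** — closed-form inversion of the forces from
  situation proportions counted over non-conflicting states, attractor
  estimation (isobarycentre), log-normal step fit, subsampling/decimation
  and the scale-invariance study.
- **`bcrwalk.movement_stats`** — five evaluation statistics (turning-angle
  distribution, kernel home-range isopleth areas on a 210×210 grid, path
  dilation areas for disk radii 1–100, still transects with 200 m sight,
  mobile linear/rotational transects), the `e1`/`e2` error pair, and the
  fluctuation and sensitivity experiment runners.
- **`bcrwalk.voids`** — alpha-shape (60 m radius) extraction of spatial
  voids ≥ 100 m², a Monte-Carlo null of void sizes under the fitted walk,
  and anomaly flagging of voids with low null probability.
- **`bcrwalk.cli_io`** / **`bcrwalk.cli`** — CSV track reading (planar or
  lon/lat converted on ingest), the synthetic GPS fixture generator
  (jittered 10-min sampling, optional planted exclusion zones) and the
  command-line interface.

## Command line

Every subcommand reads the shipped defaults (overridable via a flat YAML
`--config`), logs its effective parameters and writes plain-text artefacts:

```sh
# synthetic 25k-fix track from given forces
bcrwalk fixture --p-i 0.01 --p-s 2.01 --p-f 0.01 --mu 2.94 --sigma 1.01 \
    --n 25000 --seed 1 --out track.csv

# estimate the forces from a track
bcrwalk estimate --track track.csv --out estimate.json

# full evaluation loop: estimate, simulate N walks, e1/e2 per statistic
bcrwalk compare --track track.csv --n-sim 100 --seed 1 --out report.json

# statistic profiles, sensitivity sweep, void detection
bcrwalk stats --track track.csv --out-dir stats/
bcrwalk sweep --track track.csv --n-sim 10 --out sweep.csv
bcrwalk voids --track track.csv --n-iter 1000 --out voids.geojson
```

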
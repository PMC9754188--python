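# parkactivity

Quantify human activity in green spaces from anonymized, grid-cell
mobility tiles. The package provides:

- **`parkactivity.synth`** — a forward simulator for the whole data
  source: synthetic landscapes (properties, trails, land-cover
  partitions, boundary roads), ground-truth visitation intensity
  surfaces, an anonymization model (sub-threshold suppression, truncated
  Gaussian noise, scalar normalization baseline) emitting activity
  tiles, plus consistent reservation and tree-survey tables. Everything
  runs offline and is bit-reproducible for a fixed seed.
- **`parkactivity.geo`** — geometry plumbing on an abstract projected
  plane (metres): clipping activity cells to property polygons, union
  areas, trail intersection with optional buffers, GeoJSON/WKT-CSV I/O.
- **`parkactivity.metrics`** — per-property metrics: the overnight
  exclusion filter (cells with any activity in the 00:00–06:00 windows
  are dropped everywhere, as a road-contamination proxy), activity
  density (area-weighted sum of indices over retained clipped cells ÷
  property area), activity coverage (% of property area with any
  activity), trail density (km/km²), on-trail activity percentage, and
  land-cover usage fractions.
- **`parkactivity.stats`** — interaction OLS with sequential (type-I)
  ANOVA, and a from-scratch (partial) constrained correspondence
  analysis with a permutation test of the pseudo-F (verified against
  R's vegan during development).
- **`parkactivity.pipeline` / CLI** — a reproducible
  generate → clip → filter → metrics → stats pipeline with YAML config,
  per-stage record counts and a run manifest.

## CLI

All subcommands take a YAML config (the seed is mandatory):

```yaml
# config.yaml
seed: 7
output_dir: out
landscape:
  n_properties: 6
  trails_per_property: [0, 3]
visitation:
  trail_multiplier: 3.0
  weekend_multiplier: 2.0
  road_night_intensity: 0.6
  daily_visitor_rate: 0.002
anonymization:
  threshold: 0.3
  noise_sd: 0.05
tree_surveys:
  loadings: {birch: 0.8, elm: -0.8, hemlock: 0.3}
n_perm: 999
```

```bash
parkactivity all --config config.yaml          # full pipeline + manifest
parkactivity generate --config config.yaml     # landscape, tiles, tables
parkactivity metrics --config config.yaml      # activity_summary.csv
parkactivity landcover --config config.yaml    # land_cover_usage.csv
parkactivity stats --config config.yaml        # lm + pCCA outputs
```

Outputs are plain text: GeoJSON layers, a WKT-geometry tile CSV,
summary CSVs, and a JSON ordination summary. Rerunning with the same
config is byte-identical. Exit codes: 0 ok, 1 user error, 2 internal.

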
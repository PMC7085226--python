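"""Run the complete pipeline on a small synthetic cohort.

Both branches (nuclear morphometry from TPAF, collagen content from SHG)
run on every sample, per-sample metrics are tabulated, and the two groups
are compared; all outputs land under outputs/<run-id>/ and a re-run with
the same config and seed is byte-identical.
"""

from pathlib import Path

from mpmquant import run_pipeline, validate_config

config = validate_config(
    """
mode: synthetic
seed: 11
output_dir: outputs
cohort:
  image_shape: [160, 160]
  n_nuclei: 5
  pre:  {n_samples: 6, nuclear_area_mean: 596.56, nuclear_area_sd: 208.69,
         collagen_mean_pct: 22.81, collagen_sd_pct: 10.23}
  post: {n_samples: 6, nuclear_area_mean: 856.22, nuclear_area_sd: 255.74,
         collagen_mean_pct: 36.10, collagen_sd_pct: 12.42}
sws: {seed_spacing_px: 10}
"""
)
report = run_pipeline(config)
print(f"run {report['run_id']}: {report['n_ok']} samples ok, "
      f"{report['n_failed']} failed -> {report['output_dir']}")
for row in report["comparison"]:
    print(f"  {row['metric']}: pre {row['mean_pre']:.2f} +/- {row['sd_pre']:.2f} "
          f"vs post {row['mean_post']:.2f} +/- {row['sd_post']:.2f}, "
          f"t = {row['t_statistic']:.3f}, p {row['p_bin']}")
print("tables:", sorted(p.name for p in (Path(report["output_dir"]) / "tables").iterdir()))
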
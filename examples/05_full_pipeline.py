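"""Run the whole pipeline from a config, as the CLI would.

Writes a YAML config describing a 2-day synthetic study (2 images per
day), validates it, executes synthetic generation -> segmentation ->
morphometry -> mixture fits -> spatial statistics -> expansion metrics,
and lists the results tree.
"""

import json
import tempfile
from pathlib import Path

import yaml

from fibrilmorph import pipeline

workdir = Path(tempfile.mkdtemp(prefix="fibrilmorph_demo_"))
config_path = workdir / "config.yaml"
config_path.write_text(yaml.safe_dump({
    "output_dir": str(workdir / "results"),
    "seed": 11,
    "synthetic": {
        "days": [4, 16],
        "images_per_day": 2,
        "image": {"width_px": 512, "height_px": 512, "nm_per_px": 4.0,
                  "target_count": 100, "min_gap_nm": 30.0, "noise_sd": 4.0},
    },
}))

config = pipeline.load_config(config_path)
assert pipeline.validate_config(config) == []
outdir = pipeline.run(config)

print("results tree:")
for path in sorted(outdir.rglob("*")):
    if path.is_file():
        print(" ", path.relative_to(outdir))

log = json.loads((outdir / "run_log.json").read_text())
print("\nrun log:", json.dumps(log, indent=1)[:400], "...")
# The same run is available from a shell as
#   fibrilmorph run-all --config config.yaml
# and reruns with the same config and seed are numerically identical.
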
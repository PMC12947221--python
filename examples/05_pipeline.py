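"""One-config end-to-end run: simulate fixtures, analyze, verify digests.

Writes a YAML config describing two synthetic conditions with three
replicates each, runs every stage, and shows the manifest: every output
file with its content digest, so an identical config reproduces
identical bytes.
"""

import json
import tempfile
from pathlib import Path

import yaml

from mdinfonet.pipeline import PipelineConfig, run

workdir = Path(tempfile.mkdtemp(prefix="mdinfonet_demo_"))
config = {
    "output_dir": str(workdir / "out"),
    "seed": 1,
    "stages": ["simulate", "fluct", "pca", "hbonds", "contacts",
               "mi-calpha", "network"],
    "simulate": {
        "n_res": 16, "n_frames": 150, "n_replicates": 3,
        "conditions": {
            "control": {"blocks": []},
            "ph65": {"blocks": [{"residues": [3, 4, 5], "rho": 0.85}]},
        },
    },
    "regions": {"loop": [6, 10]},
}
cfg_path = workdir / "config.yaml"
cfg_path.write_text(yaml.safe_dump(config))

manifest = run(PipelineConfig.from_yaml(cfg_path))
print(f"\ncompleted stages: {manifest['completed']}")
print(f"outputs written to {config['output_dir']}:")
for name in sorted(manifest["outputs"]):
    print(f"  {name}  sha256:{manifest['outputs'][name][:12]}...")
print("\nre-running the same config reproduces these digests exactly "
      "(deterministic stages, seeded generators).")
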
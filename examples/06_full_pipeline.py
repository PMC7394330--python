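"""The end-to-end pipeline with a reproducible run manifest.

Runs network build -> module detection -> enrichment -> specificity ->
pathway validation from one declarative config, writing every intermediate
table plus a manifest. Reruns with the same config and seed are
byte-identical.
"""

import json
import tempfile
from pathlib import Path

from funcspec import run_pipeline

config = {
    "synthetic": {"n_blocks": 6, "block_sizes": [40] * 6, "aspects": ["MF"], "seed": 3},
    "aspects": ["MF"],
    "seed": 3,
}

out = run_pipeline(config, Path(tempfile.mkdtemp()) / "run")
print("outputs:")
for p in sorted(out.iterdir()):
    print("  ", p.name)

counts = json.loads((out / "manifest.json").read_text())["counts"]
print("\nmanifest counts:", json.dumps(counts, indent=2))
print("\nEvery stage's table is on disk with headers; the manifest records the")
print("parameters, input digests and headline counts, so any stage can be")
print("re-run or audited independently.")
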
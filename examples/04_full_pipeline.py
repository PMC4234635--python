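"""Run the whole simulate -> test -> enrich pipeline from one config file.

Writes a key = value config, executes the pipeline, and prints the run
manifest: every threshold used plus the DEG partition and the enrichment
universes, all recomputable from the tables written next to it.
"""

import tempfile
from pathlib import Path

from tagdge import run_all

CONFIG = """\
n_genes = 3000
total_a = 1000000
total_b = 1000000
de_fraction = 0.05
log2_fc_magnitude = 2.0
n_terms = 30
planted_terms = 2
seed = 11
fdr_max = 0.001
min_abs_log2 = 1.0
"""

workdir = Path(tempfile.mkdtemp())
(workdir / "run.cfg").write_text(CONFIG)
manifest = run_all(workdir / "run.cfg")

print(manifest.to_json())
print(f"\noutputs in {workdir}: deg.tsv, enrichment.tsv, sim.*.tsv, manifest.json")
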
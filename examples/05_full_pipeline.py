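"""End-to-end run on the default synthetic study.

Generates every input (network landscape, cohort genotypes, openness
model, coding scores, gene sets), runs the noncoding and coding arms,
combines them at the pathway level, writes the RE/gene/term tables and
compares the results with the planted ground truth.
"""
import json
from pathlib import Path

from retgnet.pipeline import run_all
from retgnet.simulate import SimConfig

outdir = Path("pipeline_out")
result = run_all(SimConfig(seed=1), outdir=outdir)

print("tables written to", outdir)
print(json.dumps(result.report, indent=1))
print(
    "\nrecovery = fraction of planted target genes reaching q<0.01;\n"
    "burden top decile = fraction of planted burden genes in the smallest\n"
    "10% of coding p-values; term rank 1 means the planted GO term tops\n"
    "the combined coding+noncoding ranking."
)
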
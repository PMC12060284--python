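"""One-call pipeline run with provenance.

Drives environment synthesis, the bubble stage, transport and the
ventilation diagnostic from a single validated configuration, writing
every stage product plus a provenance record to the output directory.
"""

from seepfate import validate_config
from seepfate.pipeline import run_pipeline

config = validate_config({
    "station_depth": 65.0,
    "halflife_days": 16.0,
    "seed": 1,
    "outdir": "scratch/pipeline_demo",
})
report = run_pipeline(config)

print(f"outputs in {report.outdir} (config hash {config.config_hash()})")
for key, value in report.fate_components.items():
    print(f"  {key:12s} {100 * value:8.3f}%")
print("The four components sum to 100% to numerical precision: every part")
print("of the released methane is accounted for as direct bubble transport,")
print("ventilation through the sea surface, biodegradation, or the")
print("sub-criterion residue still dissolved when the run stopped.")
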
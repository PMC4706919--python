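"""Run the whole study replica with one config and read the report.

simulate -> connectome -> edge statistics -> NBS (interaction first,
then group and time if the interaction is null) -> functional-domain
annotation -> multiview clustering -> report.  Identical config + seed
reproduce every artifact byte for byte.
"""

import tempfile
from pathlib import Path

from longconn import PipelineConfig, run_pipeline

out = Path(tempfile.mkdtemp()) / "run"
config = PipelineConfig(
    out_dir=str(out),
    seed=11,
    simulation=dict(
        n_nodes=100, n_controls=24, n_patients=16, n_blocks=8,
        effect_type="group", effect_edges=20, effect_delta_z=0.2,
    ),
    nbs=dict(threshold=5.0, n_permutations=500),
    clustering=dict(k=8),
)
report = run_pipeline(config)
print(report.human_readable())
print("artifacts under:", out)
for p in sorted(out.glob("*")):
    n = len(list(p.rglob("*"))) if p.is_dir() else ""
    print(f"   {p.name}{'/' if p.is_dir() else ''} {n and f'({n} files)' or ''}")
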
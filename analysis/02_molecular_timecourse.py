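"""Molecular SIN/Byr4 model: wild-type asymmetry establishment time course.

SIN ends on the new SPB with phosphorylated Cdc11; Byr4 ends on the old SPB
with dephosphorylated Cdc11.
"""
from pathlib import Path

from sin_asym.experiments import run_experiment

res = run_experiment("fig2A", Path("results"))
s = res.summary
print(f"[fig2A] {s['phenotype']}, asymmetry at t={s['asymmetry_time']:.1f}; "
      f"terminal SIN_new={s['sin_new']:.2f}, Byr4_old={s['byr4_old']:.2f}")
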
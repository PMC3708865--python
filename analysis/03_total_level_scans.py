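"""Total-level sensitivity: narrow SIN window, Byr4 cannot be increased.

Molecular-model scans of each protein total (log2 grid) with terminal
phenotype calls, plus the extended-model level scans and the Byr4:SIN
crossover of the early-mitotic state.
"""
from pathlib import Path

from sin_asym.experiments import run_experiment

res = run_experiment("fig2BE", Path("results"))
print(f"[fig2BE] SINx2 -> {res.summary['sin_x2']}, "
      f"SINx0.5 -> {res.summary['sin_x05']}, Byr4x2 -> {res.summary['byr4_x2']}")

res = run_experiment("figS1", Path("results"))
print(f"[figS1] extended model: initial SPB-bound Byr4 exceeds bound SIN "
      f"above a Byr4 multiplier of {res.summary['byr4_crossover_multiplier']:.2f}")
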
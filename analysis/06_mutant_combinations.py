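"""Double and triple mutants: the model's predictions as published.

cdc16-116@36 delays asymmetry strongly; the model predicts efficient
compensation by cdc11-S5A and mild compensation by cdc11-S8A (the S5A
prediction was falsified experimentally, which the model cannot know).
SIP loss (csc1D) and mild cdc16-ts are additive.
"""
from pathlib import Path

from sin_asym.experiments import run_experiment

res = run_experiment("fig5A", Path("results"))
for k, v in res.summary.items():
    print(f"[fig5A] {k}: asymmetry at t={v:.1f}")
res = run_experiment("fig5C", Path("results"))
for k, v in res.summary.items():
    print(f"[fig5C] {k}: asymmetry at t={v:.1f}")
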
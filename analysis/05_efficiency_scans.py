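"""Kinase/phosphatase efficiency scans on asymmetry timing (Byr4_old curve).

Halved SIN efficiency (the cdc11-S5A proxy) advances the transition; Cdk
efficiency between 0.25x and 1x barely moves it; ppC increases change no
phenotype.
"""
from pathlib import Path

from sin_asym.experiments import run_experiment

res = run_experiment("fig4AB", Path("results"))
s = res.summary
print(f"[fig4AB] wild-type timing t={s['wt_time']:.1f}; "
      f"e_SIN x0.5 t={s['s5a_time']:.1f} (advance); "
      f"Cdk 0.25-1x within 5%: {s['cdk_insensitive']}; "
      f"ppC x1-4 no phenotype change: {s['ppc_no_phenotype']}")
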
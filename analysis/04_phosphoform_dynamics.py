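"""Four-form Cdc11 model: terminal phosphoform composition at the two SPBs.

About three quarters of old-SPB Cdc11 ends fully dephosphorylated with the
rest Cdk-phosphorylated; new-SPB Cdc11 is mostly on SIN-phosphorylated forms.
"""
from pathlib import Path

from sin_asym.experiments import run_experiment

res = run_experiment("fig3BC", Path("results"))
s = res.summary
print(f"[fig3BC] old SPB: U={100*s['u_old_frac']:.1f}% "
      f"CP={100*s['cp_old_frac']:.1f}%; "
      f"new SPB SIN-phosphorylated forms={100*s['sin_phos_new_frac']:.1f}%; "
      f"asymmetry at t={s['asymmetry_time']:.1f}")
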
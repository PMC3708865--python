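"""Symmetric steady states of the minimal model: a pitchfork bifurcation.

With zero bias the system has, in the bistable regime, one unstable
symmetric state and a stable mirror pair of asymmetric states; the
symmetric branch regains stability at higher X totals.
"""
from pathlib import Path

from sin_asym.experiments import run_experiment

res = run_experiment("figS2", Path("results"))
s = res.summary
print(f"[figS2] steady states at wild type: {s['n_steady_states_wt']} "
      f"(1 unstable symmetric + stable mirror pair); "
      f"symmetric branch changes stability between X-total multipliers "
      f"{s['pitchfork_bracket'][1]} and {s['pitchfork_bracket'][0]}")
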
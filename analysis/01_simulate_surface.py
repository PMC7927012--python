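"""Generate the synthetic mortality surface used throughout the analysis.

Draws the default scenario — ages 0-99, 20 calendar years (1993-2012),
100 000 exposure per cell, binomial deaths around an LC1 (bilinear logit)
truth with drifting period index — and writes the exposure and death-count
matrices plus the ground-truth parameters under results/.
"""

from pathlib import Path

import numpy as np

import mortcomp as mc

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

spec = mc.ScenarioSpec(seed=20260926)
surface, truth = mc.make_scenario_surface(spec)
mc.write_surface(surface, OUT / "surface_E.csv", OUT / "surface_d.csv")
truth.to_json(OUT / "true_params.json")

q = surface.q
print(f"simulated {spec.family} surface: ages {surface.ages[0]}-{surface.ages[-1]}, "
      f"years {surface.years[0]}-{surface.years[-1]}, E={spec.exposure:g}/cell")
print(f"crude q range: {q.min():.2e} .. {q.max():.3f}")
print(f"total deaths {surface.d.sum():.0f}; "
      f"first-year e0 = {mc.life_expectancy(mc.build_period_table(q[:, 0])):.2f} y, "
      f"last-year e0 = {mc.life_expectancy(mc.build_period_table(q[:, -1])):.2f} y")
print(f"wrote {OUT / 'surface_E.csv'}, {OUT / 'surface_d.csv'}, "
      f"{OUT / 'true_params.json'}")
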
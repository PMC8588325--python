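"""Sweep bone volume fraction and reproduce the detectability trend.

Reconstructs the thin-fat model at three BVF levels and shows the
extracted tibia permittivity rising as bone mass falls. A full
nine-scenario sweep (as in scripts/acceptance.py) takes ~3 min; this
reduced version takes ~1 min.
"""

from legtomo import bvf_to_permittivity
from legtomo.pipeline import ExperimentConfig, run_bvf_sweep

config = ExperimentConfig(scenario="thin_fat", bvf_list=(0.50, 0.30, 0.10))
report = run_bvf_sweep(config)

print(f"{'BVF':>5} {'actual eps':>11} {'tibia extract':>14} {'fibula':>8}")
for rec in report.records:
    bvf = rec["bvf"]
    tib = rec["estimates"]["tibia"]
    fib = rec["estimates"]["fibula"]
    tib_s = f"{tib.mean_real_permittivity:.2f}" if tib.detected else "(x)"
    fib_s = "(o)" if fib.detected else "(x)"
    print(f"{bvf:5.2f} {bvf_to_permittivity(bvf).real:11.1f} "
          f"{tib_s:>14} {fib_s:>8}")

rmse = report.rmse["tibia"]
print(f"\ntibia RMSE over {rmse.n_detected} detected scenarios: {rmse.rmse:.2f}")
print("Lower BVF -> higher extracted permittivity: bone-density loss is "
      "visible as a dielectric change in the reconstructions. '(x)' marks "
      "a bone the automated detectability rule rejects.")
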
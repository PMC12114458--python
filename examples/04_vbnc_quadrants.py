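"""Dual-stain (SYTO9/PI) quadrant analysis with spillover compensation.

Simulates a sample with known live/dead/membrane-compromised/debris
fractions plus unstained and single-stain controls, estimates the green-red
spillover from the single stains, compensates, and recovers the quadrant
fractions.  The double-positive (SYTO9+/PI+) quadrant is the
membrane-compromised / VBNC-candidate population.
"""

from cytocide import (StainControls, SyntheticConfig, estimate_spillover,
                      quadrant_fractions, simulate_sample,
                      simulate_stained_sample)

cfg = SyntheticConfig(seed=5, spillover=((1.0, 0.05), (0.10, 1.0)))
truth = {"live": 0.50, "dead": 0.30, "double_positive": 0.15,
         "unstained": 0.05}

sample = simulate_stained_sample(cfg, tuple(truth.values()), n_events=5000)
controls = StainControls(
    unstained=simulate_sample(cfg, role="unstained"),
    single_stain_fl1=simulate_stained_sample(cfg, (1, 0, 0, 0), 3000),
    single_stain_fl3=simulate_stained_sample(cfg, (0, 1, 0, 0), 3000),
)

spill = estimate_spillover(controls.single_stain_fl1,
                           controls.single_stain_fl3, controls.unstained)
print("estimated spillover matrix (true off-diagonals 0.05 / 0.10):")
print(f"  [[1, {spill[0, 1]:.3f}], [{spill[1, 0]:.3f}, 1]]")

result = quadrant_fractions(sample, controls)
print(f"\nquadrants over {result.n_analyzed} events "
      f"(cuts log10 FL1/FL3 = {result.cuts[0]:.2f}/{result.cuts[1]:.2f}, "
      f"compensated: {result.compensation_applied}):")
for key, value in result.fractions.items():
    print(f"  {key:>16}: {value:.3f}  (truth {truth[key]:.2f})")
print("-> the SYTO9+/PI+ double-positive quadrant flags membrane-"
      "compromised, VBNC-candidate cells after sub-MBC exposure.")
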
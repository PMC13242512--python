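"""Per-droplet freeze-thaw statistics and the memory effect.

Simulates two consecutive freeze-thaw cycles of a solubility-critical
solution in which warm-active nucleation sites lose efficiency while
cold-active sites gain (the crystal-reorganization memory effect), and
quantifies it with paired per-droplet statistics.
"""

from icespec import SimulationConfig, compare_cycles, simulate_assay
from icespec.simulate import FreezeThawTransform, fresh_population

population = fresh_population(modes=(-7.0, -13.0), spreads=(0.8, 0.8), n_tot=2.0 / 0.03)
config = SimulationConfig(
    seed=11,
    population=population,
    n_cycles=2,
    transform=FreezeThawTransform(warm_loss_fraction=0.6, cold_boost_fraction=1.0),
    memory=True,  # droplets keep their site sets between cycles
)
assay = simulate_assay(config)
cmp = compare_cycles(assay, cycle_a=1, cycle_b=2)

print(f"paired droplets:        {len(cmp.pairs)}")
print(f"mean shift:             {cmp.mean_shift:+.2f} degC (cycle 2 - cycle 1)")
print(f"rank correlation:       {cmp.rank_correlation:.2f} (persistent site sets)")
print(f"warm-quartile shift:    {cmp.warm_tail_shift:+.2f} degC")
print(f"cold-quartile shift:    {cmp.cold_tail_shift:+.2f} degC")
print(
    "-> droplets that froze warmest now freeze colder (efficient sites "
    "lost) while the coldest quartile freezes warmer (cold sites "
    "boosted): the freeze-thaw memory signature"
)
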
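"""Isotope arithmetic: from bulk delta13C to the labeled-carbon fraction.

Converts measured delta values to atom fractions, then inverts the two-pool
mixing model to estimate what share of DNA carbon came from the labeled
substrate — first on printed-scale numbers, then round-trip through the
simulator's IRMS model with measurement noise.
"""

from pyrosip import isotope as iso
from pyrosip.scenarios import demo_community
from pyrosip.sipsim import LabelingScenario, NATURAL_DELTA_C13, apply_labeling, simulate_irms

# a 48 h-scale enrichment reading against the natural-abundance control
delta_bulk, delta_control = 141.2, -30.7
excess = iso.excess_atom_fraction(delta_bulk, delta_control)
print(f"delta13C {delta_bulk:+.1f} vs {delta_control:+.1f} permil "
      f"=> excess atom fraction {excess:.3e}")

est = iso.mixing_fraction(delta_bulk, delta_control, af_label_pool=0.99)
print(f"two-pool mixing: {100 * est.fraction:.3f}% of DNA carbon from the "
      f"0.99-atom-fraction pool")
print()

# simulator round trip with realistic IRMS noise (control sd 1.3 permil)
community = demo_community()
scenario = LabelingScenario(
    substrate_af=0.99,
    turnover={t: 0.004 for t in ("consumer_a", "consumer_b", "consumer_c")},
)
lab = apply_labeling(community, scenario)
f_true = sum(p.mass for ps in lab.pools.values() for p in ps
             if p.af > lab.natural_af) / lab.total_mass()
bulk = simulate_irms(lab, noise_sd=1.3, seed=3)
est = iso.mixing_fraction(bulk.delta, NATURAL_DELTA_C13,
                          af_label_pool=lab.natural_af + (0.99 - lab.natural_af))
print(f"simulated bulk delta13C: {bulk.delta:+.1f} permil (noise sd 1.3)")
print(f"true labeled fraction {f_true:.5f}, recovered {est.fraction:.5f}")
print()
print(
    "Mixing is computed in atom-fraction space: delta mixing is only\n"
    "approximately linear, and the labeled pool is very far from natural\n"
    "abundance. Per-mil-scale noise maps to ~1e-5 atom fraction, so even a\n"
    "0.2% labeled-carbon fraction is recovered to better than a percent."
)
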
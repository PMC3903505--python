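"""Simulate a full SIP experiment: community -> labeling -> gradient -> reads.

Builds the five-taxon demonstration community (three glucose consumers, two
bystanders, insect host DNA at 30%), runs a 48 h labeling window and an
unlabeled control through the CsCl gradient, and prints where the DNA went.
"""

from pyrosip.scenarios import demo_community, demo_scenario
from pyrosip.sipsim import simulate_experiment

community = demo_community()
scenario = demo_scenario("48h")
exp = simulate_experiment(community, scenario, depth=5000, n_replicates=3, seed=1)

print("fraction  BD (g/ml)  control DNA (ng)  labeled DNA (ng)")
for ctl, lab in zip(exp.control_fractions.fractions, exp.labeled_fractions.fractions):
    print(f"{ctl.index:>8d}  {ctl.density:9.4f}  {ctl.dna_ng:16.1f}  {lab.dna_ng:16.1f}")

print()
print(f"bulk delta13C, control: {exp.bulk_delta_control:9.1f} permil")
print(f"bulk delta13C, labeled: {exp.bulk_delta_labeled:9.1f} permil")
print()
print(
    "The control DNA piles up in the light fractions (low BD, high index);\n"
    "in the labeled sample a large share of consumer DNA has moved into the\n"
    "dense fractions near the bottom - that mass displacement is what the\n"
    "activity analysis quantifies taxon by taxon."
)
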
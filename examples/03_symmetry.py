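"""Bilateral symmetry of cluster-level synaptic budgets.

Splits each cluster's incoming and outgoing synapse pairs by origin x target
hemisphere (LL, RR, LR, RL), computes ipsi- and contralateral asymmetry
indices AI = (LL-RR)/(LL+RR) x 100% (resp. LR vs RL), and rank-correlates
ipsi vs contra budgets across clusters.
"""

from vagusconn import circuit
from vagusconn.symmetry import symmetry_report
from vagusconn.synthgen import default_demo_config, generate_circuit

config = default_demo_config(seed=1)
config.asymmetry_eps = 0.2  # plant a 20% left bias -> expected AI ~ +20
sim = generate_circuit(config)

budgets = []
paired = sim.annotations.query("hemisphere in ('L', 'R')")["cluster"].unique()
for cl in sorted(paired):
    for direction in ("in", "out"):
        b = circuit.hemisphere_budgets(sim.connectors, sim.annotations,
                                       cl, direction)
        if b.total > 0:
            budgets.append(b)

table, summary = symmetry_report(budgets)
cols = ["cluster", "direction", "LL", "RR", "LR", "RL", "AI_ipsi", "AI_contra"]
print(table[cols].round(1).to_string(index=False))
print("\nPositive AI = left-dominant. The generator planted a 20% excess of "
      "left-origin\nconnections, so AI_ipsi should scatter around +20.")
for direction, entry in summary["directions"].items():
    if entry.get("rho") is not None:
        print(f"ipsi-vs-contra Spearman ({direction}): "
              f"rho={entry['rho']:.2f}, p={entry['p']:.3f}")
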
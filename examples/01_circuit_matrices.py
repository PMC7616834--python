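"""Build count and input-fraction matrices from a synthetic connectome.

Generates a small bilateral circuit, tallies monosynaptic (pre, post)
synapse pairs — a polyadic connector with k partners contributes k pairs —
and normalizes each column by the target's total input count.
"""

from vagusconn import circuit
from vagusconn.synthgen import default_demo_config, generate_circuit

sim = generate_circuit(default_demo_config(seed=1))
counts = circuit.build_counts(sim.connectors, sim.annotations)
fractions = circuit.input_fractions(counts)

print(f"neurons: {len(sim.annotations)}, synaptic pairs: "
      f"{int(counts.to_numpy().sum())}")

cluster_pct = circuit.aggregate_by_cluster(counts, sim.annotations,
                                           percent_of_out=True)
print("\nEG_post outgoing budget (% of its total output, by target cluster):")
row = cluster_pct.loc["EG_post"].dropna()
for target, pct in row[row > 0].round(1).items():
    print(f"  -> {target}: {pct}%")

# a modulatory neuron's largest presynaptic partners
target = sim.annotations.query("cell_class == 'modulatory'")["neuron_id"].iloc[0]
col = fractions[target].dropna().sort_values(ascending=False)
print(f"\ntop inputs onto {target} (fraction of its total inputs):")
print(col.head(5).round(3).to_string())
print("\nEach fraction is that partner's share of the target's input budget;"
      "\nthe full column sums to 1 when every partner is in the table.")
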
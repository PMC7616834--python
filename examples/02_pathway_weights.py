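"""Direct and indirect sensory pathway weights onto modulatory neurons.

A pathway score is the product of synaptic input fractions along a layered
path (sensory -> interneuron(s) -> target); the pathway weight of a sensory
modality sums all direct and indirect scores of its neurons.
"""

import pandas as pd

from vagusconn import circuit, pathways
from vagusconn.synthgen import default_demo_config, generate_circuit

sim = generate_circuit(default_demo_config(seed=1))
fractions = circuit.input_fractions(
    circuit.build_counts(sim.connectors, sim.annotations))

cls = sim.annotations.set_index("neuron_id")["cell_class"]
sensory = list(cls.index[cls == "sensory"])
inter = list(cls.index[cls == "interneuron"])
targets = list(cls.index[cls == "modulatory"])

direct = pathways.direct_scores(fractions, sensory, targets)
indirect = pathways.indirect_scores(fractions, sensory, inter, targets,
                                    max_layers=2)
print(f"direct pathways: {len(direct)}, indirect (1-2 interneuron layers): "
      f"{len(indirect)}")

scores = pd.concat([direct, indirect], ignore_index=True)
modality = sim.annotations.set_index("neuron_id")["modality"].dropna().to_dict()

# roll every target up into a single cluster-level pathway-weight table
roll = pathways.modality_rollup(
    scores, modality, target_group={t: "Se0_ens" for t in targets})
print("\nmodality pathway weights onto Se0_ens (summed over members):")
print(roll.round(3).to_string(index=False))
print(f"\ndominant modality: {pathways.dominant_modality(roll, 'Se0_ens')}")
print("normalized_percent is each modality's share of the total sensory "
      "influence\n(direct + indirect) on the target; it sums to 100.")
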
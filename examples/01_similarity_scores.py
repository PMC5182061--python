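"""Worked examples of the two similarity scores on tiny hand inputs.

The connectivity score compares two neurons' synaptic-partner count
vectors; the synapse score compares where two neurons place their synapses
in space.
"""

from connclust import ConnSimParams, SynapseRecord, conn_sim, conn_sim_term, syn_sim

# --- connectivity similarity ----------------------------------------------
# Per-partner term f(a, b) = min - C1 * max * exp(-C2 * min), C1=0.5, C2=1:
# a partner contacted by both neurons scores ~min(a, b); a partner private
# to one of them is punished by -C1 * max.
print("f(5, 5) =", conn_sim_term(5, 5))   # ~4.983: strong shared partner
print("f(0, 4) =", conn_sim_term(0, 4))   # -2.0: partner private to one neuron

# Two neurons over three partners: both make 5 synapses onto partner 1,
# neither contacts partner 2, and only the first contacts partner 3.
# The summed score is normalized to its attainable extremes, giving [0, 1].
score = conn_sim((5, 0, 3), (5, 0, 0), ConnSimParams())
print(f"conn_sim((5,0,3), (5,0,0)) = {score:.6f}")
# 0.623596: high overlap on partner 1, dragged down by the private partner 3.

# --- synapse similarity ----------------------------------------------------
# Neuron i has presynaptic sites at x = 0 and 10,000 nm; neuron j at
# x = 2,000 and 10,000 nm. Each site of i is matched to the nearest
# same-sign site of j through a Gaussian distance kernel (sigma = 2000 nm)
# times a local-density-mismatch penalty (radius omega = 2000 nm).
i = [SynapseRecord(1, k, "pre", (x, 0.0, 0.0)) for k, x in enumerate((0.0, 10000.0))]
j = [SynapseRecord(2, k, "pre", (x, 0.0, 0.0)) for k, x in enumerate((2000.0, 10000.0))]
print(f"syn_sim directional = {syn_sim(i, j, symmetrize=False):.6f}")
# 0.803265 = mean of exp(-0.5) (sites one sigma apart) and 1.0 (coincident).
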
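"""Partner filtering, coverage, bilateral consistency and DCV proximity.

Circuit statistics on the reference synthetic connectome: which synaptic
partners pass the reconstruction-inclusion rule (bilateral homolog plus a
3-synapse threshold, sensory neurons exempt), what fraction of the focal
neurons' synapses those partners cover, whether connections are mirrored
across hemispheres, and how often presynaptic sites have a dense-core
vesicle nearby.
"""

import numpy as np

from connclust import (
    class_connectivity,
    connection_fraction,
    dcv_proximity,
    default_fixture,
    filter_partners,
    region_fraction,
)

connectome, truth = default_fixture()
focal = connectome.ids_by_class(["hugin"])
print(f"focal set: {len(focal)} hugin-like neurons")

result = filter_partners(connectome, focal, min_syn=3)
print(f"included partners: {len(result.included)}, excluded: {len(result.excluded)}")
print(f"coverage of focal pre-/postsynaptic links: "
      f"{result.coverage_pre:.1f}% / {result.coverage_post:.1f}%")

neuron = focal[0]
sensory = connectome.ids_by_class(["sensory"])
print(f"neuron {neuron}: {connection_fraction(connectome, neuron, sensory, 'incoming'):.1f}%"
      " of inputs from sensory afferents")
print(f"neuron {neuron}: {region_fraction(connectome, neuron, 'SEZ', 'incoming'):.1f}%"
      " of inputs inside the SEZ region box")

sided = [i for i, s in connectome.skeletons.items() if s.side != "medial"]
summary = class_connectivity(connectome, sided)
frac = np.mean(list(summary.bilateral_ok.values()))
print(f"bilaterally recapitulated connections among sided neurons: {100 * frac:.1f}%")

dcv = [dcv_proximity(connectome, s, radius=450.0) for s in focal]
print(f"mean DCV proximity over focal neurons: {np.nanmean(dcv):.1f}% "
      f"(generator places DCVs at {100 * truth.config.dcv_prob:.0f}% of presites)")
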
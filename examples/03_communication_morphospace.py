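"""Communication models and the routing/diffusion morphospace.

Computes shortest-path efficiency (routing), negative search information
(accessibility of shortest routes to a random walker), and communicability
(diffusive broadcasting) for one network, then standardizes the network's
mean routing and diffusion efficiency against matched ring-lattice and
random-graph ensembles.
"""

import numpy as np

from connscale import (
    CohortSpec,
    communication_set,
    generate_connectome,
    pairwise_coupling,
    scaled_morphospace,
)

bundle = generate_connectome(volume=50.0, spec=CohortSpec(n_nodes=100), seed=3)
ed = bundle.euclidean_distances()

comm = communication_set(bundle.weights)
print(f"valid node pairs: {int(comm.valid.sum() / 2)} of {100 * 99 // 2}")
print(f"rho(ED, SPE) = {pairwise_coupling(ed, comm.spe, comm.valid):+.3f}")
print(f"rho(ED, NSI) = {pairwise_coupling(ed, comm.nsi, comm.valid):+.3f}")
print(f"rho(ED, CMY) = {pairwise_coupling(ed, comm.cmy, comm.valid):+.3f}")
print("(negative: communication is more efficient between nearby regions)")

point = scaled_morphospace(bundle.weights, n_realizations=10, seed=0)
print(f"\nmorphospace: SPE_scaled = {point.spe_scaled:.3f}, CMY_scaled = {point.cmy_scaled:.3f}")
print(
    "0 means lattice-like, 1 means random-like; brain-like networks sit "
    "between the two, trading routing efficiency against diffusion."
)
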
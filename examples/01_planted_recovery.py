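"""Recover planted subgraphs from synthetic FC matrices.

Generates three seizures worth of edge-by-window connectivity built from
four shared sparse subgraphs with boxcar activations, fits the joint
factorization, and scores the recovered factors against the ground truth.
"""

import numpy as np

from btnd import (
    BTNDConfig,
    FusedLassoParams,
    fit,
    generate_planted_dataset,
    recovery_report,
)

# 20 contacts -> 190 edges; seizures of 60/80/100 windows; PLV-scale noise
X, truth = generate_planted_dataset(
    n_nodes=20, K=4, durations=[60, 80, 100],
    edge_sparsity=0.1, noise_sigma=0.05, seed=1,
)
print(f"dataset: S={X.S} seizures, L={X.L} edges, T={X.durations}")

config = BTNDConfig(
    K=4, lam=0.001,
    base_fused=FusedLassoParams(gamma=0.001, eta=0.2),
    n_restarts=20, seed=0,
)
dec = fit(X, config)
print(f"fit: final objective {dec.final_objective:.4f} "
      f"(best of {config.n_restarts} restarts, "
      f"{len(dec.objective_trace) - 1} iterations)")

rep = recovery_report(dec, truth)
print(f"matched subgraph cosine:   {rep.mean_subgraph_cosine:.3f}")
print(f"matched activation cosine: {rep.mean_activation_cosine:.3f}")
print(f"support Jaccard:           {rep.mean_support_jaccard:.3f}")
print("Cosines near 1 mean each planted subgraph and its activation time")
print("course were found up to the method's inherent scale/permutation")
print("ambiguity; Jaccard near 1 means on/off periods align window-wise.")
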
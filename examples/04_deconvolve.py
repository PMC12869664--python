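"""Merge clusters into a signature matrix and deconvolve bulk mixtures.

Cluster centroids correlating at r > 0.986 merge (after dropping clusters
under 50 cells); bulk profiles are then expressed as non-negative,
sum-to-one mixtures of the signature columns by exact simplex-constrained
least squares.
"""

import numpy as np

from clonerisk import SimConfig, make_programs, simulate_bulk_cohort
from clonerisk.benchmarks import _signature_from_profiles
from clonerisk.deconvolve import deconvolve_bulk

rng = np.random.default_rng(0)
cfg = SimConfig(n_genes=2000, n_subclones=8, n_markers_per_subclone=50, seed=0)
programs = make_programs(cfg, rng=rng)
signature = _signature_from_profiles(programs.mean_profiles())
print(f"signature: {signature.matrix.shape[0]} genes x "
      f"{signature.matrix.shape[1]} subclones")

truth = rng.dirichlet(np.ones(8), 5)
for mode, kwargs in [("exact", {}),
                     ("cell_resample", {"config": cfg, "rng": rng,
                                        "n_cells_per_sample": 500})]:
    bulk, _ = simulate_bulk_cohort(programs, truth, mode, **kwargs)
    errs = [np.abs(deconvolve_bulk(bulk[s], signature).proportions.to_numpy()
                   - truth[i]).max()
            for i, s in enumerate(bulk.columns)]
    print(f"{mode:>13}: max abundance error per sample = "
          f"{np.round(errs, 4)}")
# Noiseless mixtures are recovered to machine precision; pseudobulks built
# from 500 resampled cells stay within a few points of the true proportions.
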
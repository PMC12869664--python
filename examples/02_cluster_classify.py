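"""Cluster one patient's paired cells and classify subclone dynamics.

QC -> library-size log-normalization -> PCA/kNN/Louvain -> per-cluster
diagnosis/relapse composition -> expanded/stable/diminished/relapsed/other
labels at the 10% threshold, plus the transforming flag from residual
centroid correlation.
"""

from clonerisk import SimConfig, StudyConfig, simulate_study
from clonerisk.pipeline import PipelineConfig, analyze_patient

study = simulate_study(StudyConfig(
    n_patients=1, sim=SimConfig(n_genes=800, seed=0),
    n_cells_dx=500, n_cells_rel=500, n_cells_normal=150,
    n_resistance_genes=60, n_bulk_samples=10, seed=0))

result = analyze_patient("P00", study.cohorts["P00"],
                         PipelineConfig(seed=0, resolution=2.5))

cols = ["n_dx", "n_rel", "f_dx", "f_rel", "frac_normal", "label",
        "transforming"]
print(result.class_table[cols].round(3).to_string())
print(f"\npatient group: {result.group} "
      "(A = at least one expanded subclone present)")
# f_dx / f_rel are the cluster's share of each timepoint's QC-passing tumor
# cells; a cluster is 'expanded' when it holds >10% of relapse cells but
# <=10% of diagnosis cells while being present at diagnosis.  The
# transforming flag marks diminished clusters whose expression program
# tracks a relapse-emergent cluster.
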
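"""On-disk study layout and format helpers.

A written study directory looks like::

    study/
      manifest.json                 # config + seed, for exact reproduction
      cells/<sample_id>/matrix.mtx  # genes x cells, 1-based Matrix Market
      cells/<sample_id>/features.tsv
      cells/<sample_id>/barcodes.tsv
      cell_meta.csv                 # barcode, patient, sample_id, timepoint
      bulk.csv                      # genes x bulk samples
      clinical.csv                  # survival + MRD + cytogenetics + FLT3-ITD

Counts are written per sample (10x-style triplet); ``load_study`` restores
the per-patient cohorts exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CellCohort, concat_cohorts

CLINICAL_COLUMNS = [
    "patient_id", "os_time", "os_event", "efs_time", "efs_event",
    "mrd", "cyto_risk", "flt3_itd",
]


def write_counts(path, counts: sp.spmatrix, gene_ids, cell_ids) -> None:
    """Write a genes x cells triplet: matrix.mtx + features.tsv + barcodes.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "matrix.mtx", sp.coo_matrix(counts), field="integer")
    pd.Series(list(gene_ids)).to_csv(path / "features.tsv", sep="\t",
                                     index=False, header=False)
    pd.Series(list(cell_ids)).to_csv(path / "barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_counts(path):
    """Read a matrix.mtx triplet; returns (csr counts, gene_ids, cell_ids)."""
    path = Path(path)
    counts = sp.csr_matrix(mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].to_numpy(object)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(object)
    return counts, genes, cells


def write_study(study, out_dir) -> None:
    """Write a StudyData to disk (see module docstring for the layout)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create study directory {out}: {e}") from e
    metas = []
    for pid, cohort in study.cohorts.items():
        for sid in cohort.cell_meta["sample_id"].unique():
            mask = (cohort.cell_meta["sample_id"] == sid).to_numpy()
            write_counts(out / "cells" / sid, cohort.counts[:, mask],
                         cohort.gene_ids, cohort.cell_ids[mask])
        metas.append(cohort.cell_meta.rename_axis("barcode").reset_index())
    pd.concat(metas).to_csv(out / "cell_meta.csv", index=False)
    study.bulk.rename_axis("gene").to_csv(out / "bulk.csv")
    study.clinical.to_csv(out / "clinical.csv", index=False)
    study.subclone_table.to_csv(out / "subclone_truth.csv", index=False)
    study.bulk_truth.rename_axis("sample").to_csv(out / "bulk_truth.csv")
    manifest = {
        "config": _config_dict(study.config),
        "seed": study.config.seed,
        "samples": sorted(
            sid for c in study.cohorts.values()
            for sid in c.cell_meta["sample_id"].unique()
        ),
        "resistance_genes": list(study.resistance_genes),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _config_dict(cfg):
    d = dataclasses.asdict(cfg)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return clean(d)


def study_config_from_manifest(path):
    """Rebuild a StudyConfig from a manifest.json (exact reproduction)."""
    from .simulate import SimConfig, StudyConfig, SurvivalSimConfig

    d = json.loads(Path(path).read_text())["config"]
    d["sim"] = SimConfig(**{**d["sim"],
                            "logfc_range": tuple(d["sim"]["logfc_range"])})
    d["survival"] = SurvivalSimConfig(**d["survival"])
    d["roles"] = tuple(tuple(r) for r in d["roles"])
    d["resistance_logfc_range"] = tuple(d["resistance_logfc_range"])
    return StudyConfig(**d)


def load_study_cells(study_dir) -> dict:
    """Read per-patient cohorts back from a study directory."""
    study_dir = Path(study_dir)
    meta = pd.read_csv(study_dir / "cell_meta.csv").set_index("barcode")
    cohorts = {}
    for pid, pmeta in meta.groupby("patient", sort=True):
        parts = []
        for sid in pmeta["sample_id"].unique():
            counts, genes, cells = read_counts(study_dir / "cells" / sid)
            parts.append(CellCohort(
                counts=counts, gene_ids=genes, cell_ids=cells,
                cell_meta=meta.loc[cells],
            ))
        cohorts[pid] = concat_cohorts(parts)
    return cohorts


def load_bulk(study_dir) -> pd.DataFrame:
    return pd.read_csv(Path(study_dir) / "bulk.csv", index_col="gene")


def load_clinical(study_dir) -> pd.DataFrame:
    return pd.read_csv(Path(study_dir) / "clinical.csv")


def read_gmt(path) -> dict:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        sets[fields[0]] = list(dict.fromkeys(fields[2:]))
    return sets


def write_gmt(gene_sets: dict, path, description: str = "clonerisk") -> None:
    lines = [
        "\t".join([name, description, *map(str, genes)])
        for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
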
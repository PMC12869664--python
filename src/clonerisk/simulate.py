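"""Synthetic paired-cohort generator.

Emulates the data structure of a paired diagnosis-relapse pediatric AML
study: per-patient single-cell samples containing subclones with planted
expansion / diminution / transformation dynamics, bulk mixtures of known
subclone composition, and survival outcomes whose hazard depends on planted
risk-subclone abundance.

Count model: per-cell library sizes are log-normal; given a cell's subclone
k, gene g counts are negative binomial with mean
``libsize_c * baseline_g * 2**logfc_{k,g} / Z_k`` and inverse-dispersion
theta (gamma-Poisson mixture), the standard scRNA-seq count assumption.
Subclone identity is encoded as log2 fold-changes on disjoint marker-gene
sets so planted signals are identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellCohort, concat_cohorts

_SIMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the single-cell count model."""

    n_genes: int = 3000
    n_subclones: int = 6
    n_markers_per_subclone: int = 60
    dispersion: float = 2.0  # NB inverse-dispersion theta
    libsize_meanlog: float = math.log(2500.0)
    libsize_sdlog: float = 0.35
    logfc_range: tuple = (1.0, 3.0)  # log2 fold-change of marker genes
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_subclones < 1 or self.n_markers_per_subclone < 1:
            raise ValueError("counts must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion theta must be > 0")
        lo, hi = self.logfc_range
        if not (0 < lo <= hi):
            raise ValueError("logfc_range must satisfy 0 < low <= high")


@dataclass
class ExpressionPrograms:
    """Per-subclone expression programs over a shared gene universe."""

    gene_ids: np.ndarray
    baseline_mean: np.ndarray  # positive expected counts, length n_genes
    program_logfc: np.ndarray  # n_subclones x n_genes log2 fold-changes
    marker_sets: dict  # subclone index -> array of marker gene ids

    def __post_init__(self):
        if (self.baseline_mean <= 0).any():
            raise ValueError("baseline_mean must be positive")
        if self.program_logfc.shape[1] != len(self.gene_ids):
            raise ValueError("program_logfc gene dimension mismatch")
        for k, m in self.marker_sets.items():
            if len(m) == 0:
                raise ValueError(f"subclone {k} has no markers")

    @property
    def n_subclones(self) -> int:
        return self.program_logfc.shape[0]

    def mean_profiles(self) -> np.ndarray:
        """Relative expression per subclone (genes x subclones, columns sum 1)."""
        m = self.baseline_mean[:, None] * 2.0 ** self.program_logfc.T
        return m / m.sum(axis=0, keepdims=True)


def make_programs(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    allow_overlap: bool = False,
) -> ExpressionPrograms:
    """Draw baseline expression and disjoint marker programs.

    Baselines are log-normal; each subclone gets ``n_markers_per_subclone``
    markers with log2 fold-changes uniform in ``logfc_range``.  Marker sets
    are disjoint unless ``allow_overlap`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G, K, M = config.n_genes, config.n_subclones, config.n_markers_per_subclone
    if not allow_overlap and K * M > G:
        raise ValueError(
            f"cannot place {K} x {M} disjoint markers in {G} genes"
        )
    gene_ids = np.array([f"G{i:05d}" for i in range(G)], dtype=object)
    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, G)
    logfc = np.zeros((K, G))
    marker_sets = {}
    if allow_overlap:
        marker_idx = [rng.choice(G, M, replace=False) for _ in range(K)]
    else:
        perm = rng.permutation(G)
        marker_idx = [perm[k * M : (k + 1) * M] for k in range(K)]
    lo, hi = config.logfc_range
    for k in range(K):
        logfc[k, marker_idx[k]] = rng.uniform(lo, hi, M)
        marker_sets[k] = gene_ids[np.sort(marker_idx[k])]
    return ExpressionPrograms(gene_ids, baseline, logfc, marker_sets)


def _check_simplex(f, name):
    f = np.asarray(f, dtype=float)
    if (f < -_SIMPLEX_TOL).any() or abs(f.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return np.clip(f, 0.0, None) / np.clip(f, 0.0, None).sum()


def _nb_counts(rng, mean, theta):
    """Gamma-Poisson draw with mean ``mean`` and variance mean + mean^2/theta."""
    lam = rng.gamma(theta, mean / theta)
    return rng.poisson(lam)


def simulate_sample(
    programs: ExpressionPrograms,
    fractions,
    n_cells: int,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    patient_id: str = "P0",
    sample_id: str = "S0",
    timepoint: str = "diagnosis",
    low_depth_frac: float = 0.0,
    low_depth_scale: float = 0.05,
) -> CellCohort:
    """Draw one single-cell sample with subclone composition ``fractions``."""
    fractions = _check_simplex(fractions, "fractions")
    if len(fractions) != programs.n_subclones:
        raise ValueError("fractions length must match number of subclones")
    subclone = rng.choice(programs.n_subclones, size=n_cells, p=fractions)
    libsize = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, n_cells)
    low = np.zeros(n_cells, dtype=bool)
    if low_depth_frac > 0:
        low = rng.random(n_cells) < low_depth_frac
        libsize = np.where(low, libsize * low_depth_scale, libsize)
    profiles = programs.mean_profiles()  # genes x subclones, cols sum 1
    mean = profiles[:, subclone] * libsize[None, :]
    counts = _nb_counts(rng, mean, config.dispersion)
    barcodes = np.array(
        [f"{sample_id}:c{i:05d}" for i in range(n_cells)], dtype=object
    )
    meta = pd.DataFrame(
        {"patient": patient_id, "sample_id": sample_id, "timepoint": timepoint},
        index=barcodes,
    )
    truth = pd.DataFrame({"subclone": subclone, "low_depth": low}, index=barcodes)
    return CellCohort(
        counts=sp.csr_matrix(counts),
        gene_ids=programs.gene_ids,
        cell_ids=barcodes,
        cell_meta=meta,
        truth=truth,
    )


def simulate_paired_cells(
    programs: ExpressionPrograms,
    fractions_dx,
    fractions_rel,
    n_cells_dx: int,
    n_cells_rel: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    *,
    patient_id: str = "P0",
    **sample_kwargs,
) -> CellCohort:
    """Paired diagnosis + relapse sample for one patient.

    A zero entry in either fraction vector means the subclone is absent at
    that timepoint; true per-cell subclone labels are stored in
    ``cohort.truth``, separate from the observable metadata.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dx = simulate_sample(
        programs, fractions_dx, n_cells_dx, config, rng,
        patient_id=patient_id, sample_id=f"{patient_id}.dx",
        timepoint="diagnosis", **sample_kwargs,
    )
    rel = simulate_sample(
        programs, fractions_rel, n_cells_rel, config, rng,
        patient_id=patient_id, sample_id=f"{patient_id}.rel",
        timepoint="relapse", **sample_kwargs,
    )
    return concat_cohorts([dx, rel])


def simulate_bulk_from_profiles(
    profiles: np.ndarray,
    proportions: np.ndarray,
    noise_mode: str = "exact",
    *,
    rng: np.random.Generator | None = None,
    config: SimConfig | None = None,
    n_cells_per_sample: int = 500,
    lognormal_sigma: float = 0.25,
    scale: float = 1e4,
) -> np.ndarray:
    """Mix subclone mean profiles into bulk samples (genes x samples).

    ``profiles`` are relative expression columns (summing to 1); output is
    on a counts-per-``scale`` scale.  ``exact`` returns the noiseless linear
    mixture; ``cell_resample`` aggregates NB-sampled cells; ``lognormal``
    multiplies the exact mixture by per-gene log-normal noise.
    """
    proportions = np.atleast_2d(np.asarray(proportions, dtype=float))
    for i, row in enumerate(proportions):
        _check_simplex(row, f"proportions row {i}")
    if profiles.shape[1] != proportions.shape[1]:
        raise ValueError("profile / proportion subclone dimensions differ")
    exact = scale * (profiles @ proportions.T)
    if noise_mode == "exact":
        return exact
    if rng is None:
        rng = np.random.default_rng(0)
    if noise_mode == "lognormal":
        noise = rng.lognormal(0.0, lognormal_sigma, exact.shape)
        return exact * noise
    if noise_mode == "cell_resample":
        if config is None:
            raise ValueError("cell_resample mode requires a SimConfig")
        out = np.empty_like(exact)
        for s, p in enumerate(proportions):
            sub = rng.choice(len(p), size=n_cells_per_sample, p=p)
            lib = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog,
                                n_cells_per_sample)
            mean = profiles[:, sub] * lib[None, :]
            counts = _nb_counts(rng, mean, config.dispersion)
            tot = counts.sum(axis=1).astype(float)
            out[:, s] = tot / tot.sum() * scale
        return out
    raise ValueError(f"unknown noise_mode {noise_mode!r}")


def simulate_bulk_cohort(
    programs: ExpressionPrograms,
    proportions: np.ndarray,
    noise_mode: str = "exact",
    *,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    **kwargs,
):
    """Bulk mixtures of one program set's subclones; returns (bulk df, truth df)."""
    proportions = np.atleast_2d(np.asarray(proportions, dtype=float))
    bulk = simulate_bulk_from_profiles(
        programs.mean_profiles(), proportions, noise_mode,
        rng=rng, config=config or SimConfig(), **kwargs,
    )
    samples = [f"B{i:04d}" for i in range(proportions.shape[0])]
    bulk_df = pd.DataFrame(bulk, index=programs.gene_ids, columns=samples)
    truth = pd.DataFrame(
        proportions, index=samples,
        columns=[f"S{k}" for k in range(proportions.shape[1])],
    )
    return bulk_df, truth


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Exponential proportional-hazards outcome model.

    Event times for OS and EFS are drawn independently from
    ``Exponential(baseline_hazard * exp(beta_T*T + beta_mrd*mrd + beta_cyto*cyto))``
    and censored administratively at a uniform follow-up horizon.
    """

    baseline_hazard: float = 0.09
    beta_T: float = math.log(1.5)  # log-hazard per unit of the supplied T scale
    beta_mrd: float = math.log(2.0)
    beta_cyto: float = math.log(2.5)
    censor_horizon: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")


def simulate_survival(
    T_values,
    mrd,
    cyto,
    config: SurvivalSimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw OS and EFS outcomes under the proportional-hazards model.

    OS and EFS share the same linear predictor with independent exponential
    noise; one uniform follow-up (censoring) time applies to both.
    """
    T_values = np.asarray(T_values, dtype=float)
    mrd = np.asarray(mrd, dtype=float)
    cyto = np.asarray(cyto, dtype=float)
    if not (len(T_values) == len(mrd) == len(cyto)):
        raise ValueError("T_values, mrd and cyto must have equal length")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(T_values)
    lp = (config.beta_T * T_values
          + config.beta_mrd * np.nan_to_num(mrd)
          + config.beta_cyto * cyto)
    rate = config.baseline_hazard * np.exp(lp)
    censor = rng.uniform(0.0, config.censor_horizon, n)
    out = {}
    for ep in ("os", "efs"):
        raw = rng.exponential(1.0 / rate)
        out[f"{ep}_time"] = np.maximum(np.minimum(raw, censor), 1e-9)
        out[f"{ep}_event"] = (raw <= censor).astype(int)
    df = pd.DataFrame(out)
    df.insert(0, "patient_id", [f"B{i:04d}" for i in range(n)])
    df["mrd"] = mrd
    df["cyto_risk"] = cyto.astype(int)
    return df


# ---------------------------------------------------------------------------
# full-study assembly

#: default per-patient subclone dynamics: (role, f_diagnosis, f_relapse).
#: Fractions sit >= 0.03 away from the 10% classification threshold.
DEFAULT_ROLES = (
    ("expanded", 0.06, 0.34),
    ("stable", 0.24, 0.27),
    ("diminished", 0.36, 0.02),
    ("transforming", 0.27, 0.03),
    ("relapsed", 0.00, 0.29),
    ("other", 0.07, 0.05),
)

#: relative Dirichlet weight of each role in diagnostic bulk mixtures
BULK_ALPHA = {
    "expanded": 0.5, "stable": 0.4, "diminished": 0.4,
    "transforming": 0.5, "relapsed": 0.05, "other": 0.3, "normal": 0.6,
}

RISK_ROLES = ("expanded", "transforming")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the full synthetic study (cells + bulk + clinical)."""

    n_patients: int = 8
    sim: SimConfig = field(default_factory=SimConfig)
    roles: tuple = DEFAULT_ROLES
    n_cells_dx: int = 700
    n_cells_rel: int = 700
    n_cells_normal: int = 300
    n_normal_types: int = 2
    n_resistance_genes: int = 150
    resistance_logfc_range: tuple = (1.0, 2.0)
    transform_r: float = 0.8  # designed program correlation transforming/relapsed
    n_bulk_samples: int = 800
    bulk_noise: str = "lognormal"
    bulk_concentration: float = 1.0  # scales BULK_ALPHA jointly
    mrd_rate: float = 0.35
    mrd_missing_rate: float = 0.03
    cyto_rate: float = 0.30
    flt3_rate: float = 0.05
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    seed: int = 0


@dataclass
class StudyData:
    """In-memory synthetic study: inputs plus hidden truth for assertions."""

    config: StudyConfig
    cohorts: dict  # patient -> CellCohort (dx + rel + normal cells)
    subclone_table: pd.DataFrame  # (patient, subclone, role, f_dx, f_rel)
    resistance_genes: np.ndarray
    bulk: pd.DataFrame  # genes x bulk samples
    bulk_truth: pd.DataFrame  # bulk samples x (patient.subclone) true proportions
    clinical: pd.DataFrame
    true_T: pd.Series  # per bulk sample, total risk-subclone proportion
    programs: dict  # patient -> ExpressionPrograms (tumor + normal programs)


def _patient_programs(cfg: StudyConfig, rng, resistance_idx):
    """Programs for one patient: tumor subclones + shared normal cell types.

    The relapse-emergent ("relapsed") subclone's program is built from the
    transforming subclone's marker program so their marker-space correlation
    is ``transform_r``; expanded subclones additionally carry the study-wide
    resistance program on ``resistance_idx`` genes.
    """
    roles = [r[0] for r in cfg.roles]
    K = len(roles) + cfg.n_normal_types
    sim = replace(cfg.sim, n_subclones=K)
    G, M = sim.n_genes, sim.n_markers_per_subclone
    if K * M + cfg.n_resistance_genes > G:
        raise ValueError("gene universe too small for markers + resistance program")
    gene_ids = np.array([f"G{i:05d}" for i in range(G)], dtype=object)
    baseline = rng.lognormal(sim.baseline_meanlog, sim.baseline_sdlog, G)
    # resistance genes get mid/high baseline so the 25%-expressed filter keeps them
    baseline[resistance_idx] = rng.lognormal(0.5, 0.5, len(resistance_idx))
    free = np.setdiff1d(np.arange(G), resistance_idx)
    perm = rng.permutation(free)
    logfc = np.zeros((K, G))
    marker_sets = {}
    lo, hi = sim.logfc_range
    for k in range(K):
        idx = perm[k * M : (k + 1) * M]
        logfc[k, idx] = rng.uniform(lo, hi, M)
        marker_sets[k] = gene_ids[np.sort(idx)]
    # transforming subclone shares the relapsed program at designed correlation:
    # relapsed logfc = r * transforming-marker program + sqrt(1-r^2)-weighted own part
    r = cfg.transform_r
    i_tr, i_rel = roles.index("transforming"), roles.index("relapsed")
    own = logfc[i_rel].copy()
    shared = logfc[i_tr].copy()
    nrm_o, nrm_s = np.linalg.norm(own), np.linalg.norm(shared)
    logfc[i_rel] = r * shared + math.sqrt(1 - r * r) * own * (nrm_s / nrm_o)
    marker_sets[i_rel] = gene_ids[np.sort(np.where(logfc[i_rel] != 0)[0])]
    # study-wide resistance program carried by the expanded subclone
    rlo, rhi = cfg.resistance_logfc_range
    res_fc = rng.uniform(rlo, rhi, len(resistance_idx))
    logfc[roles.index("expanded"), resistance_idx] += res_fc
    return ExpressionPrograms(gene_ids, baseline, logfc, marker_sets), sim


def simulate_study(config: StudyConfig | None = None) -> StudyData:
    """Generate the full synthetic study in memory (deterministic in seed)."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    roles = [r[0] for r in cfg.roles]
    f_dx = np.array([r[1] for r in cfg.roles])
    f_rel = np.array([r[2] for r in cfg.roles])
    _check_simplex(f_dx, "diagnosis fractions")
    _check_simplex(f_rel, "relapse fractions")
    G = cfg.sim.n_genes
    resistance_idx = rng.choice(G, cfg.n_resistance_genes, replace=False)
    resistance_idx.sort()

    cohorts, programs, sub_rows = {}, {}, []
    col_ids, col_profiles, col_roles = [], [], []
    for p in range(cfg.n_patients):
        pid = f"P{p:02d}"
        prog, sim = _patient_programs(cfg, rng, resistance_idx)
        programs[pid] = prog
        Kt = len(roles)
        pad = np.zeros(cfg.n_normal_types)
        paired = simulate_paired_cells(
            prog, np.r_[f_dx, pad], np.r_[f_rel, pad],
            cfg.n_cells_dx, cfg.n_cells_rel, sim, rng, patient_id=pid,
        )
        normal_fracs = np.r_[np.zeros(Kt), np.full(cfg.n_normal_types,
                                                   1.0 / cfg.n_normal_types)]
        normal = simulate_sample(
            prog, normal_fracs, cfg.n_cells_normal, sim, rng,
            patient_id=pid, sample_id=f"{pid}.norm", timepoint="normal",
        )
        cohorts[pid] = concat_cohorts([paired, normal])
        prof = prog.mean_profiles()
        for k, role in enumerate(roles):
            sub_rows.append((pid, k, role, f_dx[k], f_rel[k]))
            col_ids.append(f"{pid}.S{k}")
            col_profiles.append(prof[:, k])
            col_roles.append(role)
        for j in range(cfg.n_normal_types):
            col_ids.append(f"{pid}.N{j}")
            col_profiles.append(prof[:, Kt + j])
            col_roles.append("normal")

    subclone_table = pd.DataFrame(
        sub_rows, columns=["patient", "subclone", "role", "f_dx", "f_rel"]
    )
    profiles = np.column_stack(col_profiles)
    alpha = cfg.bulk_concentration * np.array([BULK_ALPHA[r] for r in col_roles])
    proportions = rng.dirichlet(alpha, size=cfg.n_bulk_samples)
    gene_ids = programs[f"P{0:02d}"].gene_ids
    bulk_vals = simulate_bulk_from_profiles(
        profiles, proportions, cfg.bulk_noise, rng=rng, config=cfg.sim,
    )
    samples = [f"B{i:04d}" for i in range(cfg.n_bulk_samples)]
    bulk = pd.DataFrame(bulk_vals, index=pd.Index(gene_ids, name="gene"),
                        columns=samples)
    bulk_truth = pd.DataFrame(proportions, index=samples, columns=col_ids)

    risk_cols = [c for c, r in zip(col_ids, col_roles) if r in RISK_ROLES]
    true_T = bulk_truth[risk_cols].sum(axis=1).rename("T_true")
    # hazard is log-linear in each risk subclone's standardized abundance,
    # so every planted risk subclone carries HR exp(beta_T) per SD
    z_risk = (bulk_truth[risk_cols] - bulk_truth[risk_cols].mean()) / \
        bulk_truth[risk_cols].std(ddof=0)
    risk_score = z_risk.sum(axis=1).to_numpy()
    mrd = (rng.random(cfg.n_bulk_samples) < cfg.mrd_rate).astype(float)
    mrd[rng.random(cfg.n_bulk_samples) < cfg.mrd_missing_rate] = np.nan
    cyto = (rng.random(cfg.n_bulk_samples) < cfg.cyto_rate).astype(int)
    clinical = simulate_survival(risk_score, mrd, cyto, cfg.survival, rng)
    clinical["flt3_itd"] = (rng.random(cfg.n_bulk_samples) < cfg.flt3_rate).astype(int)

    return StudyData(
        config=cfg, cohorts=cohorts, subclone_table=subclone_table,
        resistance_genes=gene_ids[resistance_idx], bulk=bulk,
        bulk_truth=bulk_truth, clinical=clinical, true_T=true_T,
        programs=programs,
    )


def simulate_full_study(config: StudyConfig | None, out_dir) -> "StudyData":
    """Generate the study and write it to ``out_dir`` (see clonerisk.io)."""
    from . import io as crio

    study = simulate_study(config)
    crio.write_study(study, out_dir)
    return study
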
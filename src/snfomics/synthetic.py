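"""Synthetic multi-omic cohort generator with planted ground truth.

The generator emulates the statistical structure of a two-group pediatric
low-grade glioma discovery cohort: a small number of samples (default 28,
split ~14+14), planted differential features in the transcript and protein
layers, weak global transcript-protein coupling (default median pairwise
Pearson r = 0.168), an opposite group-wise protein/mRNA ratio shift, a
group-uninformative methylation layer, cell-type mixing with a T-cell
enrichment in group 1, and clinical covariates (ages ~7 vs ~12 years,
group-dependent tumor location and progression hazard).

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence` child streams, so a given
``(config, seed)`` reproduces the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClinicalTable, OmicMatrix, SignatureMatrix

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "calibrate_coupling",
    "residual_coupling",
    "simulate_survival",
    "simulate_cohort",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_CELL_TYPES = ("tumor", "t_cell", "microglia", "macrophage")

#: per-group mean mixing fractions over DEFAULT_CELL_TYPES
_DEFAULT_FRACTIONS = {
    "group1": (0.60, 0.15, 0.15, 0.10),
    "group2": (0.70, 0.05, 0.15, 0.10),
}

#: per-group probability of a supratentorial location
_DEFAULT_LOCATION_P_SUPRA = (0.80, 0.25)


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the emulated study conditions.

    ``effect_size`` is the planted |log2 fold change| of differential
    features; ``coupling_rho`` the target pooled-sample Pearson correlation
    of a background matched pair; ``ratio_shift_delta`` the additive shift
    applied to group-1 log mRNA and group-2 log protein, which creates the
    opposite protein/mRNA dominance of the two groups. ``noise_sd`` is the
    within-group residual standard deviation on the log2 scale (default
    0.8, a realistic biological+technical spread for bulk profiling of a
    single tumor entity).
    """

    n_samples: int = 28
    group_proportions: tuple[float, float] = (0.5, 0.5)
    n_genes: int = 2000
    n_matched_pairs: int = 2000
    frac_de: float = 0.1
    effect_size: float = 1.5
    coupling_rho: float = 0.168
    ratio_shift_delta: float = 0.5
    noise_sd: float = 0.8
    methylation_informative: bool = False
    n_methylation: int = 500
    celltype_fractions: dict = field(default_factory=lambda: {k: dict(zip(DEFAULT_CELL_TYPES, v)) for k, v in _DEFAULT_FRACTIONS.items()})
    n_markers_per_type: int = 10
    mixing_concentration: float = 100.0
    mixture_noise_sd: float = 0.05
    age_means: tuple[float, float] = (7.0, 12.0)
    age_sd: float = 3.0
    location_p_supra: tuple[float, float] = _DEFAULT_LOCATION_P_SUPRA
    pfs_hazards: tuple[float, float] = (0.04, 0.012)
    censor_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        p1, p2 = self.group_proportions
        if not math.isclose(p1 + p2, 1.0, abs_tol=1e-9) or min(p1, p2) < 0:
            raise ValueError("group_proportions must be non-negative and sum to 1")
        if abs(self.coupling_rho) > 1:
            raise ValueError("|coupling_rho| must be <= 1")
        if self.n_matched_pairs > self.n_genes:
            raise ValueError("n_matched_pairs cannot exceed n_genes")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for group, fracs in self.celltype_fractions.items():
            vals = np.array(list(fracs.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any() or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"cell-type fractions for {group} must lie in [0,1] and sum to 1")
        if min(self.pfs_hazards) <= 0:
            raise ValueError("pfs_hazards must be positive")

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A fully group-uninformative configuration.

        All group-level contrasts are switched off: no planted differential
        features, no transcript-protein coupling, no ratio shift, identical
        cell-type mixing, ages, locations and hazards in both groups.
        """
        equal = {k: dict(zip(DEFAULT_CELL_TYPES, (0.65, 0.10, 0.15, 0.10))) for k in ("group1", "group2")}
        base = dict(
            frac_de=0.0,
            coupling_rho=0.0,
            ratio_shift_delta=0.0,
            celltype_fractions=equal,
            age_means=(9.0, 9.0),
            location_p_supra=(0.5, 0.5),
            pfs_hazards=(0.02, 0.02),
        )
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "CohortConfig":
        return replace(self, **overrides)


@dataclass
class SyntheticCohort:
    """Bundle of generated layers, clinical table and ground truth."""

    mrna: OmicMatrix
    protein: OmicMatrix
    methylation: OmicMatrix
    clinical: ClinicalTable
    signature: SignatureMatrix
    true_labels: pd.Series
    true_de_features: dict[str, list[str]]
    true_fractions: pd.DataFrame
    config: CohortConfig

    @property
    def layers(self) -> dict[str, OmicMatrix]:
        return {"mrna": self.mrna, "protein": self.protein, "methylation": self.methylation}


def calibrate_coupling(target_r: float) -> float:
    """Coupling parameter for ``protein = rho*z + sqrt(1-rho^2)*e``.

    With ``z`` the standardized transcript signal and ``e`` independent
    standard noise, the population Pearson correlation of the constructed
    pair is exactly ``rho``; the calibration is therefore the identity.
    """
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    return float(target_r)


def residual_coupling(target_r: float, delta: float, sigma: float) -> float:
    """Residual-noise coupling that yields a pooled-sample correlation of
    ``target_r`` for a background matched pair under the group ratio shift.

    The shift puts a group-mean component of +delta on mRNA (group 1) and
    +delta on protein (group 2); across two equal groups this contributes
    covariance ``-delta^2/4`` and variance ``delta^2/4`` per layer, so the
    residual coupling must be inflated to
    ``(target_r*(sigma^2 + delta^2/4) + delta^2/4) / sigma^2``.
    """
    rho = (target_r * (sigma**2 + delta**2 / 4) + delta**2 / 4) / sigma**2
    if abs(rho) > 1:
        raise ValueError(
            f"target correlation {target_r} is unreachable with delta={delta}, sigma={sigma} (needs rho={rho:.3f})"
        )
    return float(rho)


def simulate_survival(labels, hazards, censor_rate: float, seed) -> pd.DataFrame:
    """Exponential event times per group with independent exponential censoring.

    Parameters
    ----------
    labels:
        Group label per sample (any two values; hazard looked up by sorted
        unique order).
    hazards:
        Per-group event rate (events per month), one per group, > 0.
    censor_rate:
        Censoring rate; 0 means no censoring, large values censor everything
        near time 0.
    seed:
        Integer seed or :class:`numpy.random.Generator`.
    """
    hazards = np.asarray(hazards, dtype=float)
    if (hazards <= 0).any():
        raise ValueError("hazards must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) != len(hazards):
        raise ValueError("one hazard per group required")
    rate = labels.map(dict(zip(groups, hazards))).to_numpy(dtype=float)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=len(labels))
    else:
        censor_time = np.full(len(labels), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"pfs_time": time, "pfs_event": event}, index=labels.index)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort with the structure described in the module docstring.

    Deterministic given ``(config, seed)``; ``seed=None`` uses
    ``config.seed``. Ground truth (labels, planted feature sets, mixing
    fractions) is returned alongside the data.
    """
    cfg = config
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    (s_labels, s_de, s_expr, s_meth, s_mix, s_clin, s_surv) = [np.random.default_rng(c) for c in ss.spawn(7)]

    n = cfg.n_samples
    n1 = int(round(n * cfg.group_proportions[0]))
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    labels = np.array(["group1"] * n1 + ["group2"] * (n - n1))
    s_labels.shuffle(labels)
    labels = pd.Series(labels, index=sample_ids, name="group")
    g1 = (labels == "group1").to_numpy()
    # centered group contrast: +1/2 for group1, -1/2 for group2
    contrast = np.where(g1, 0.5, -0.5)

    genes = _gene_ids(cfg.n_genes)
    # Marker identity is part of the configured disease architecture: the
    # same config plants the same genes regardless of the run seed, so
    # independent cohorts share real cross-cohort markers (the premise of
    # subclass-association validation). Only the per-sample noise and
    # covariates depend on the run seed.
    arch = np.random.default_rng(
        np.random.SeedSequence([0xA5C1, cfg.n_genes, cfg.n_matched_pairs, int(round(cfg.frac_de * 1e6))])
    )
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    de_mrna_idx = np.sort(arch.choice(cfg.n_genes, size=n_de, replace=False))
    de_prot_pool = cfg.n_matched_pairs  # protein layer carries the matched genes
    n_de_prot = int(round(cfg.frac_de * de_prot_pool))
    de_prot_idx = np.sort(arch.choice(de_prot_pool, size=n_de_prot, replace=False))
    sign_mrna = arch.choice([-1.0, 1.0], size=n_de)
    sign_prot = arch.choice([-1.0, 1.0], size=n_de_prot)

    # log2-scale baselines and coupled residual noise
    mu_mrna = s_expr.normal(8.0, 2.0, size=cfg.n_genes)
    mu_prot = s_expr.normal(20.0, 2.0, size=de_prot_pool)
    z = s_expr.standard_normal((cfg.n_genes, n))
    e = s_expr.standard_normal((de_prot_pool, n))
    if cfg.ratio_shift_delta > 0:
        rho = residual_coupling(cfg.coupling_rho, cfg.ratio_shift_delta, cfg.noise_sd)
    else:
        rho = calibrate_coupling(cfg.coupling_rho)
    prot_resid = rho * z[:de_prot_pool] + math.sqrt(max(0.0, 1 - rho**2)) * e

    mrna = mu_mrna[:, None] + cfg.noise_sd * z
    protein = mu_prot[:, None] + cfg.noise_sd * prot_resid
    # planted group effects: full contrast magnitude = effect_size in log2FC
    mrna[de_mrna_idx] += (sign_mrna * cfg.effect_size)[:, None] * contrast[None, :]
    protein[de_prot_idx] += (sign_prot * cfg.effect_size)[:, None] * contrast[None, :]
    # opposite protein/mRNA dominance: group-1 mRNA and group-2 protein up
    mrna[:, g1] += cfg.ratio_shift_delta
    protein[:, ~g1] += cfg.ratio_shift_delta

    # cell-type mixtures appended to the mRNA layer (linear scale, then log2)
    cell_types = list(next(iter(cfg.celltype_fractions.values())).keys())
    n_marker = cfg.n_markers_per_type
    marker_ids = [f"IMM{c}{j:02d}" for c in range(len(cell_types)) for j in range(1, n_marker + 1)]
    profiles = np.full((len(marker_ids), len(cell_types)), 2.0)
    for c in range(len(cell_types)):
        profiles[c * n_marker : (c + 1) * n_marker, c] = 100.0
    signature = SignatureMatrix(pd.DataFrame(profiles, index=marker_ids, columns=cell_types))

    mean_fracs = np.array([[cfg.celltype_fractions["group1" if is1 else "group2"][ct] for ct in cell_types] for is1 in g1])
    alpha = np.clip(mean_fracs * cfg.mixing_concentration, 1e-6, None)
    fractions = np.vstack([s_mix.dirichlet(a) for a in alpha])
    true_fractions = pd.DataFrame(fractions, index=sample_ids, columns=cell_types)
    bulk = fractions @ profiles.T  # samples x markers, linear scale
    if cfg.mixture_noise_sd > 0:
        bulk = bulk * np.exp(s_mix.normal(0.0, cfg.mixture_noise_sd, size=bulk.shape))
    marker_log = np.log2(bulk.T)

    mrna_df = pd.DataFrame(
        np.vstack([mrna, marker_log]), index=genes + marker_ids, columns=sample_ids
    )
    protein_df = pd.DataFrame(protein, index=genes[:de_prot_pool], columns=sample_ids)

    # markers whose mixture construction implies |log2FC| >= 1 are true DE
    f1 = np.array([cfg.celltype_fractions["group1"][ct] for ct in cell_types])
    f2 = np.array([cfg.celltype_fractions["group2"][ct] for ct in cell_types])
    expected_fc = np.abs(np.log2((f1 @ profiles.T + 1e-12) / (f2 @ profiles.T + 1e-12)))
    marker_de = [marker_ids[i] for i in np.flatnonzero(expected_fc >= 1.0)]
    true_de = {
        "mrna": [genes[i] for i in de_mrna_idx] + marker_de,
        "protein": [genes[i] for i in de_prot_idx],
    }

    # methylation: Beta-distributed beta values, group-independent by default
    meth_ids = [f"CPG{i:05d}" for i in range(1, cfg.n_methylation + 1)]
    meth_mean = s_meth.uniform(0.1, 0.9, size=cfg.n_methylation)
    precision = 20.0
    a = meth_mean * precision
    b = (1 - meth_mean) * precision
    if cfg.methylation_informative:
        shift = s_meth.choice([-0.15, 0.15], size=cfg.n_methylation)
        a1 = np.clip((meth_mean + shift), 0.02, 0.98) * precision
        b1 = precision - a1
        beta = np.where(g1[None, :], s_meth.beta(a1[:, None], b1[:, None], size=(cfg.n_methylation, n)), s_meth.beta(a[:, None], b[:, None], size=(cfg.n_methylation, n)))
    else:
        beta = s_meth.beta(a[:, None], b[:, None], size=(cfg.n_methylation, n))
    meth_df = pd.DataFrame(beta, index=meth_ids, columns=sample_ids)

    # clinical covariates
    age_mu = np.where(g1, cfg.age_means[0], cfg.age_means[1])
    age = np.clip(s_clin.normal(age_mu, cfg.age_sd), 0.5, None)
    p_supra = np.where(g1, cfg.location_p_supra[0], cfg.location_p_supra[1])
    location = np.where(s_clin.uniform(size=n) < p_supra, "supratentorial", "infratentorial")
    sex = s_clin.choice(["f", "m"], size=n)
    braf = s_clin.choice(["kiaa1549-braf fusion", "wildtype"], size=n, p=[0.7, 0.3])
    surv = simulate_survival(labels, cfg.pfs_hazards, cfg.censor_rate, s_surv)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age": np.round(age, 2),
                "sex": sex,
                "location": location,
                "braf_status": braf,
                "pfs_time": np.round(surv["pfs_time"].to_numpy(), 3),
                "pfs_event": surv["pfs_event"].to_numpy(),
                "group": labels.to_numpy(),
            }
        )
    )

    return SyntheticCohort(
        mrna=OmicMatrix("mrna", mrna_df, is_log=True),
        protein=OmicMatrix("protein", protein_df, is_log=True),
        methylation=OmicMatrix("methylation", meth_df, is_log=False),
        clinical=clinical,
        signature=signature,
        true_labels=labels,
        true_de_features=true_de,
        true_fractions=true_fractions,
        config=cfg,
    )
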
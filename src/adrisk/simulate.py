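"""Case/control genotype cohort simulator.

Controls draw genotypes at Hardy-Weinberg proportions for the configured
population minor-allele frequency.  Cases of a given clinical subtype draw
from the HWE distribution tilted by ``exp(dose * log_or)`` and renormalized,
which is the genotype distribution implied by retrospective (case-control)
sampling under an additive logistic disease model.  Ages are truncated
normal (rounded to years), sex is Bernoulli, and missingness is applied
independently per genotype call.

Default settings reproduce the study conditions this package models: a
75-marker candidate panel, a strong APOE epsilon-4 effect (per-allele OR
4.3) acting in the amnestic subtype, an HFE rs1799945 effect (OR 2.83) in
the atypical subtype, group sizes/ages/sex fractions matching the published
demographics, and 2% missing genotype calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import presets
from .cohort import (
    CohortValidationError,
    GenotypeMatrix,
    SampleRecord,
    VariantRecord,
)

CASE_GROUPS = ("AmnAD", "AtAD")


@dataclass
class SimulationConfig:
    n_per_group: dict  # {"control": int, "AmnAD": int, "AtAD": int}
    marker_ids: list[str]
    mafs: np.ndarray                # control-population MAFs, (0, 0.5]
    log_or_amn: np.ndarray          # per-marker additive log OR, AmnAD vs control
    log_or_aty: np.ndarray          # same, AtAD vs control
    age_mean_sd: dict               # group -> (mean, sd), years
    frac_female: dict               # group -> fraction
    gene_labels: list[str] | None = None
    missing_rate: float = 0.02
    demographic_effects: bool = False  # False: every group draws age/sex from the control distributions
    age_range: tuple = presets.AGE_RANGE
    seed: int = 0

    def __post_init__(self):
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.log_or_amn = np.asarray(self.log_or_amn, dtype=float)
        self.log_or_aty = np.asarray(self.log_or_aty, dtype=float)
        m = len(self.marker_ids)
        for name, arr in (
            ("mafs", self.mafs),
            ("log_or_amn", self.log_or_amn),
            ("log_or_aty", self.log_or_aty),
        ):
            if arr.shape != (m,):
                raise CohortValidationError(
                    f"{name} length {arr.shape} does not match {m} markers"
                )
        if np.any((self.mafs <= 0) | (self.mafs > 0.5)):
            raise CohortValidationError("MAFs must lie in (0, 0.5]")
        if not (0 <= self.missing_rate <= 1):
            raise CohortValidationError("missing_rate must lie in [0, 1]")
        if any(n < 0 for n in self.n_per_group.values()):
            raise CohortValidationError("group sizes must be non-negative")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    samples: list[SampleRecord]
    truth: SimulationConfig


def default_config(seed: int = 0, n_per_group: dict | None = None, **overrides) -> SimulationConfig:
    """Study-calibrated default configuration (global cohort sizes)."""
    panel = presets.panel_marker_table()
    genes = [g for g, _r, _m in panel]
    ids = [r for _g, r, _m in panel]
    mafs = np.array([m for _g, _r, m in panel])
    log_or_amn = np.zeros(len(ids))
    log_or_aty = np.zeros(len(ids))
    log_or_amn[ids.index(presets.APOE_MARKER_ID)] = np.log(presets.APOE_PLANTED_OR)
    log_or_aty[ids.index(presets.HFE_MARKER_ID)] = np.log(presets.HFE_PLANTED_OR)
    demo = presets.DEMOGRAPHICS["global"]
    cfg = SimulationConfig(
        n_per_group=dict(n_per_group or demo["n"]),
        marker_ids=ids,
        gene_labels=genes,
        mafs=mafs,
        log_or_amn=log_or_amn,
        log_or_aty=log_or_aty,
        age_mean_sd=dict(demo["age_mean_sd"]),
        frac_female=dict(demo["frac_female"]),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def amnestic_architecture_config(seed: int = 0, n_case: int = 150, n_control: int = 283) -> SimulationConfig:
    """Amnestic-only cohort: planted APOE effect, no HFE (or other) effect."""
    cfg = default_config(seed, n_per_group={"control": n_control, "AmnAD": n_case, "AtAD": 0})
    return cfg


def atypical_architecture_config(seed: int = 0, n_case: int = 150, n_control: int = 283) -> SimulationConfig:
    """Atypical-only cohort: planted HFE effect, no APOE (or other) effect."""
    cfg = default_config(seed, n_per_group={"control": n_control, "AmnAD": 0, "AtAD": n_case})
    return cfg


def _case_genotype_probs(maf: float, log_or: float) -> np.ndarray:
    q = maf
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    w = hwe * np.exp(np.arange(3) * log_or)
    return w / w.sum()


_PREFIX = {"control": "ctl", "AmnAD": "amn", "AtAD": "aty"}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a reproducible synthetic cohort under the configured architecture."""
    rng = np.random.default_rng(config.seed)
    m = len(config.marker_ids)
    group_log_or = {
        "control": np.zeros(m),
        "AmnAD": config.log_or_amn,
        "AtAD": config.log_or_aty,
    }
    samples: list[SampleRecord] = []
    dose_blocks: list[np.ndarray] = []
    lo, hi = config.age_range
    for group in ("control", "AmnAD", "AtAD"):
        n = int(config.n_per_group.get(group, 0))
        if n == 0:
            continue
        block = np.empty((n, m))
        for j in range(m):
            p = _case_genotype_probs(config.mafs[j], group_log_or[group][j])
            block[:, j] = rng.choice(3, size=n, p=p)
        dose_blocks.append(block)
        demo_group = group if (config.demographic_effects or group == "control") else "control"
        mean, sd = config.age_mean_sd[demo_group]
        ages = rng.normal(mean, sd, size=n)
        ages = np.clip(np.round(ages), lo, hi).astype(int)
        female = rng.random(n) < config.frac_female[demo_group]
        for i in range(n):
            samples.append(
                SampleRecord(
                    f"{_PREFIX[group]}{i + 1:04d}",
                    group,
                    int(ages[i]),
                    "female" if female[i] else "male",
                )
            )
    dose = np.vstack(dose_blocks) if dose_blocks else np.empty((0, m))
    if config.missing_rate > 0 and dose.size:
        mask = rng.random(dose.shape) < config.missing_rate
        dose[mask] = np.nan
    genes = config.gene_labels or [""] * m
    variants = [
        VariantRecord(mid, gene, "a", "b")
        for mid, gene in zip(config.marker_ids, genes)
    ]
    g = GenotypeMatrix([s.sample_id for s in samples], variants, dose)
    return SimulatedCohort(g, samples, config)


def plant_ld_proxy(
    g: GenotypeMatrix,
    parent: str,
    fidelity: float,
    seed: int,
    proxy_id: str | None = None,
) -> GenotypeMatrix:
    """Append a proxy marker in LD with ``parent``.

    Each genotype copies the parent's dose, except with probability
    ``1 - fidelity`` it is redrawn from HWE at the parent's in-sample MAF;
    fidelity 1 yields an exact copy (r^2 = 1), fidelity 0 an independent
    marker.
    """
    if not (0 <= fidelity <= 1):
        raise CohortValidationError("fidelity must lie in [0, 1]")
    j = g.marker_index(parent)  # KeyError for unknown parent
    col = g.dose[:, j].copy()
    rng = np.random.default_rng(seed)
    nonmiss = col[~np.isnan(col)]
    maf = nonmiss.mean() / 2.0 if nonmiss.size else 0.0
    maf = min(max(maf, 1e-6), 0.5)
    p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf * maf])
    redraw = rng.random(col.shape) < (1 - fidelity)
    fresh = rng.choice(3, size=col.shape, p=p).astype(float)
    proxy = np.where(redraw & ~np.isnan(col), fresh, col)
    pid = proxy_id or f"{parent}_proxy"
    parent_var = g.variants[j]
    variants = g.variants + [
        VariantRecord(pid, parent_var.gene_label, parent_var.minor_allele, parent_var.major_allele)
    ]
    dose = np.column_stack([g.dose, proxy])
    return GenotypeMatrix(list(g.sample_ids), variants, dose)


def split_cohort(
    samples: list[SampleRecord], discovery_fraction: float, seed: int
) -> list[SampleRecord]:
    """Assign discovery/validation splits by stratified sampling within group."""
    if not (0 < discovery_fraction < 1):
        raise CohortValidationError("discovery_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for group in _groups_in_order(samples):
        members = [s for s in samples if s.group == group]
        if len(members) < 2:
            warnings.warn(f"group {group!r} has < 2 samples; all sent to discovery")
            for s in members:
                assignment[s.sample_id] = "discovery"
            continue
        n_disc = int(round(discovery_fraction * len(members)))
        n_disc = min(max(n_disc, 1), len(members) - 1)
        order = rng.permutation(len(members))
        for rank, idx in enumerate(order):
            assignment[members[idx].sample_id] = (
                "discovery" if rank < n_disc else "validation"
            )
    return [replace(s, split=assignment[s.sample_id]) for s in samples]


def _groups_in_order(samples: list[SampleRecord]) -> list[str]:
    seen: list[str] = []
    for s in samples:
        if s.group not in seen:
            seen.append(s.group)
    return seen
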
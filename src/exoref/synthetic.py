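"""Seeded generators for count matrices and Ct tables.

These emulate the statistical structure the analysis assumes, so every
pipeline stage is testable without any external download:

* ``simulate_counts`` - plasma-exosome-style small RNA-seq counts:
  negative-binomial reads with log-normal gene abundance, log-normal
  library-size factors, multiplicative batch effects on a fraction of
  genes, and a planted set of high-abundance low-dispersion miRNAs that a
  correct stability ranking should recover.
* ``simulate_ct`` - replicate-level qRT-PCR Ct tables for a healthy-donor
  plus four-disease cohort, with per-sample biological noise, replicate
  noise, planted between-group shifts, censoring of reactions past the
  cycle limit, and a uniform spike-in within its efficiency window.
* ``null_panel`` - ``simulate_ct`` with every group shift forced to zero,
  for type-I-error calibration.

Each generator returns the data, a matching sample sheet, and a truth
table recording all latent parameters, and is bit-reproducible given its
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix, CtTable, SampleSheet, ValidationError

# Cohort of the emulated study design: healthy donors plus four pediatric
# hematological malignancies.
DEFAULT_GROUP_SIZES = {"HD": 13, "ALCL": 14, "BL": 15, "HL": 15, "mALL": 15}

# Candidate-normalizer panel with baselines inside the observed
# average-Ct range of well-expressed plasma-exosome miRNAs (22-25 cycles).
DEFAULT_BASELINES = {
    "miR-486-5p": 22.9,
    "miR-26a-5p": 22.26,
    "miR-423-5p": 24.84,
    "miR-191-5p": 23.6,
}

SPIKEIN_TARGET = "cel-miR-39"


@dataclass
class CountSimConfig:
    """Negative-binomial count simulator settings.

    ``base_mean_logdist`` sets the log-normal distribution of per-gene
    mean reads; with 300 genes and meanlog 8.5 / sdlog 1.5 the library
    depths land around 4-5 million reads, the scale of plasma-exosome
    small RNA-seq.  Planted stable genes draw their mean from the top
    decile of that distribution, take the minimum dispersion, and carry
    no batch effect.
    """

    n_genes: int = 300
    n_samples: int = 69
    n_batches: int = 3
    base_mean_logdist: tuple[float, float] = (8.5, 1.5)  # (meanlog, sdlog)
    dispersion_range: tuple[float, float] = (0.05, 0.6)
    libsize_sdlog: float = 0.25
    batch_effect_sdlog: float = 0.25
    batch_affected_frac: float = 0.5
    n_planted_stable: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_stable > self.n_genes:
            raise ValidationError("n_planted_stable exceeds n_genes")
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise ValidationError("dispersion_range must satisfy 0 < lo <= hi")
        for name in ("libsize_sdlog", "batch_effect_sdlog"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.batch_affected_frac <= 1):
            raise ValidationError("batch_affected_frac must be in [0, 1]")
        if self.n_batches < 1 or self.n_samples < self.n_batches:
            raise ValidationError("need n_samples >= n_batches >= 1")


@dataclass
class CtSimConfig:
    """qRT-PCR Ct simulator settings.

    Replicate Ct = baseline + group shift + per-sample biological effect
    N(0, sample_sd^2) + replicate noise N(0, replicate_sd^2); values past
    ``max_cycles`` are censored to undetermined.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    target_baselines: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    group_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    replicate_sd: float = 0.15
    sample_sd: float = 0.2
    n_replicates: int = 3
    spikein_range: tuple[float, float] = (14.0, 19.0)
    max_cycles: int = 40
    control_group: str = "HD"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValidationError("every group needs >= 2 samples")
        if self.replicate_sd < 0 or self.sample_sd < 0:
            raise ValidationError("noise sds must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for (target, group), shift in self.group_shifts.items():
            if target not in self.target_baselines:
                raise ValidationError(f"shift for unknown target {target!r}")
            if group not in self.group_sizes:
                raise ValidationError(f"shift for unknown group {group!r}")


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def simulate_counts(cfg: CountSimConfig
                    ) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Simulate an over-dispersed count matrix with planted stable miRNAs.

    Counts ~ NB(mean = lambda_g * f_j * b_{g,batch(j)}, dispersion phi_g)
    parameterized so that Var = mu + phi * mu^2.  Returns the matrix, a
    sample sheet (batch labels, group ``HD``) and a truth table with the
    latent per-gene parameters and the planted flags.
    """
    rng = np.random.default_rng(cfg.seed)
    meanlog, sdlog = cfg.base_mean_logdist
    lam = rng.lognormal(meanlog, sdlog, size=cfg.n_genes)
    lo, hi = cfg.dispersion_range
    phi = rng.uniform(lo, hi, size=cfg.n_genes)

    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[: cfg.n_planted_stable] = True
    if cfg.n_planted_stable:
        # planted stable genes take the largest drawn abundances (all in the
        # top decile) and the minimum dispersion: stability with high
        # abundance is the signal the ranking must recover
        order = np.argsort(lam)
        top = order[-cfg.n_planted_stable:]
        rest = order[: cfg.n_genes - cfg.n_planted_stable]
        reassigned = np.empty_like(lam)
        reassigned[planted] = lam[rng.permutation(top)]
        reassigned[~planted] = lam[rng.permutation(rest)]
        lam = reassigned
        phi[planted] = lo

    batch_ids = np.array([f"batch{1 + i % cfg.n_batches}"
                          for i in range(cfg.n_samples)])
    f = rng.lognormal(0.0, cfg.libsize_sdlog, size=cfg.n_samples)

    affected = (~planted) & (rng.random(cfg.n_genes) < cfg.batch_affected_frac)
    batch_levels = sorted(set(batch_ids))
    b = np.ones((cfg.n_genes, len(batch_levels)))
    b[affected] = rng.lognormal(0.0, cfg.batch_effect_sdlog,
                                size=(int(affected.sum()), len(batch_levels)))
    batch_index = np.array([batch_levels.index(x) for x in batch_ids])

    mu = lam[:, None] * f[None, :] * b[:, batch_index]
    # NB with Var = mu + phi mu^2  <=>  gamma-Poisson with shape 1/phi
    shape = 1.0 / phi[:, None]
    lam_gp = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam_gp)

    gene_ids = [f"planted-miR-{i+1}" if planted[i] else f"miR-sim-{i+1}"
                for i in range(cfg.n_genes)]
    sample_ids = [f"S{j+1:03d}" for j in range(cfg.n_samples)]
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame(
        {"batch": batch_ids, "group": "HD", "timepoint": "none"},
        index=pd.Index(sample_ids, name="sample_id")))
    truth = pd.DataFrame({
        "mirna": gene_ids,
        "lambda": lam,
        "dispersion": phi,
        "batch_affected": affected,
        "planted": planted,
    })
    return cm, sheet, truth


# ---------------------------------------------------------------------------
# Ct simulation
# ---------------------------------------------------------------------------

def simulate_ct(cfg: CtSimConfig) -> tuple[CtTable, SampleSheet, pd.DataFrame]:
    """Simulate a replicate-level Ct table for the configured cohort."""
    rng = np.random.default_rng(cfg.seed)
    sample_ids, groups = [], []
    for g, n in cfg.group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i+1:02d}")
            groups.append(g)
    n_samples = len(sample_ids)
    targets = list(cfg.target_baselines)
    truth_rows = []
    rows: dict[str, list] = {"sample_id": [], "target": [],
                             "replicate": [], "ct": []}
    sample_effects = rng.normal(0.0, cfg.sample_sd,
                                size=(n_samples, len(targets)))
    for si, (sid, grp) in enumerate(zip(sample_ids, groups)):
        for ti, target in enumerate(targets):
            base = cfg.target_baselines[target]
            shift = cfg.group_shifts.get((target, grp), 0.0)
            center = base + shift + sample_effects[si, ti]
            reps = center + rng.normal(0.0, cfg.replicate_sd,
                                       size=cfg.n_replicates)
            for r in range(cfg.n_replicates):
                ct = reps[r]
                rows["sample_id"].append(sid)
                rows["target"].append(target)
                rows["replicate"].append(r + 1)
                rows["ct"].append(math.nan if ct > cfg.max_cycles else ct)
            truth_rows.append({"sample_id": sid, "target": target,
                               "group": grp, "true_mean_ct": center,
                               "shift": shift})
        # one per-sample spike value inside the window, shared by replicates,
        # so the QC window check is exercised without censoring artifacts
        spike = rng.uniform(*cfg.spikein_range)
        for r in range(cfg.n_replicates):
            rows["sample_id"].append(sid)
            rows["target"].append(SPIKEIN_TARGET)
            rows["replicate"].append(r + 1)
            rows["ct"].append(spike)
    records = pd.DataFrame(rows)
    ct = CtTable(records, max_cycles=cfg.max_cycles)
    timepoint = ["none" if g == cfg.control_group else "diagnosis"
                 for g in groups]
    sheet = SampleSheet(pd.DataFrame(
        {"batch": "run1", "group": groups, "timepoint": timepoint},
        index=pd.Index(sample_ids, name="sample_id")))
    return ct, sheet, pd.DataFrame(truth_rows)


def null_panel(cfg: CtSimConfig) -> tuple[CtTable, SampleSheet, pd.DataFrame]:
    """``simulate_ct`` with all group shifts forced to zero."""
    from dataclasses import replace
    return simulate_ct(replace(cfg, group_shifts={}))
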
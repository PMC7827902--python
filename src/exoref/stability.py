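"""Sequencing-based stability ranking of candidate reference miRNAs.

Given a raw miRNA count matrix from plasma-exosome small RNA-seq and a
sample sheet with study-of-origin (batch) labels, this module reproduces
the ranking stage of the reference-selection pipeline:

1. drop samples sequenced to fewer than ``min_reads_per_sample`` reads;
2. keep miRNAs with read sum >= ``min_read_sum`` that are detected
   (count > 0) in at least ``min_detect_frac`` of the retained samples;
3. normalize depths with median-of-ratios size factors and move to
   log2(count/size_factor + pseudocount);
4. remove between-study batch effects by per-gene linear modelling on the
   batch factor (per-batch mean centering, grand mean restored);
5. score each miRNA by a modified (median/MAD) Z-score that rewards high
   mean abundance and low coefficient of variation, rank, and pick the
   validation candidates, skipping known oncomiRs.

The score is ``mz(mean) - mz(CV)`` by default, where ``mz`` is the robust
Z-transform 0.6745 * (x - median) / MAD computed across miRNAs; an
``inv_cv`` alternative scores by ``mz(-CV)`` alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    AbundanceMatrix,
    CountMatrix,
    SampleSheet,
    StabilityTable,
    ValidationError,
)

logger = logging.getLogger("exoref.stability")

MODIFIED_Z_CONSTANT = 0.6745  # makes MAD consistent with sigma for normals


@dataclass
class RankingConfig:
    """Thresholds and scoring choices for the ranking stage."""

    min_reads_per_sample: int = 2_000_000
    min_read_sum: int = 10
    min_detect_frac: float = 0.8
    pseudocount: float = 1.0
    top_n: int = 20
    scoring: str = "mz_diff"  # or "inv_cv"
    tie_break: str = "mean_abundance_then_id"

    def __post_init__(self) -> None:
        if self.min_reads_per_sample <= 0 or self.min_read_sum <= 0:
            raise ValidationError("read thresholds must be positive")
        if not (0 < self.min_detect_frac <= 1):
            raise ValidationError("min_detect_frac must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.scoring not in ("mz_diff", "inv_cv"):
            raise ValidationError(f"unknown scoring {self.scoring!r}")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def drop_low_depth_samples(cm: CountMatrix, min_reads: int = 2_000_000) -> CountMatrix:
    """Discard samples with fewer than ``min_reads`` total reads.

    The boundary is inclusive: a sample with exactly ``min_reads`` reads
    is kept (only *fewer* are discarded).
    """
    totals = cm.counts.sum(axis=0)
    keep = totals >= min_reads
    for s in cm.counts.columns[~keep]:
        logger.info("depth filter: dropped sample %s (%d reads < %d)",
                    s, totals[s], min_reads)
    if not keep.any():
        raise ValidationError("no samples pass depth filter")
    return CountMatrix(cm.counts.loc[:, keep])


def filter_consistent_mirnas(cm: CountMatrix, min_sum: int = 10,
                             min_frac: float = 0.8) -> CountMatrix:
    """Keep miRNAs with row sum >= min_sum detected in >= min_frac of samples."""
    if cm.counts.shape[1] < 1:
        raise ValidationError("count matrix has no samples")
    sums = cm.counts.sum(axis=1)
    det_frac = (cm.counts > 0).mean(axis=1)
    keep = (sums >= min_sum) & (det_frac >= min_frac)
    for g in cm.counts.index[~keep]:
        logger.info("consistency filter: dropped %s (sum=%d, detected=%.0f%%)",
                    g, sums[g], 100 * det_frac[g])
    if not keep.any():
        logger.warning("consistency filter removed every miRNA")
    return CountMatrix(cm.counts.loc[keep])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, s_j is the median over genes g (restricted to genes
    with all-positive counts, i.e. a positive geometric mean) of
    c_gj / geomean_g.  Factors are left as raw medians; no rescaling.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no gene with all-positive counts; cannot form the geometric-mean "
            "reference (pseudo-reference fallback is disabled)"
        )
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geomean)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=cm.counts.columns, name="size_factor")


def normalize_log2(cm: CountMatrix, sf: pd.Series,
                   pseudocount: float = 1.0) -> AbundanceMatrix:
    """log2(count / size_factor + pseudocount), per sample."""
    missing = [s for s in cm.sample_ids if s not in sf.index]
    if missing:
        raise ValidationError(f"size factors missing for samples {missing}")
    scaled = cm.counts.to_numpy(dtype=float) / sf.loc[cm.sample_ids].to_numpy()
    values = pd.DataFrame(np.log2(scaled + pseudocount),
                          index=cm.counts.index, columns=cm.counts.columns)
    return AbundanceMatrix(values, pseudocount=pseudocount,
                           normalized=True, batch_corrected=False)


def correct_batch(am: AbundanceMatrix, sheet: SampleSheet) -> AbundanceMatrix:
    """Remove between-batch shifts by per-gene OLS on the batch factor.

    With a batch-only design the least-squares fit is saturated, so the
    correction is per-batch mean centering with the grand fitted mean
    (unweighted mean of batch means) restored.  After correction every
    batch has the same per-gene mean; within-batch deviations are
    untouched.  Single-batch input is returned unchanged.
    """
    if not am.normalized:
        raise ValidationError("batch correction expects normalized abundances")
    batches = sheet.batch_of(am.sample_ids)
    sizes = batches.value_counts()
    singletons = sizes.index[sizes < 2].tolist()
    if singletons:
        raise ValidationError(
            f"batches with a single sample are confounded with it: {singletons}"
        )
    if sizes.size <= 1:
        return AbundanceMatrix(am.values.copy(), pseudocount=am.pseudocount,
                               normalized=True, batch_corrected=True)
    vals = am.values
    batch_means = vals.T.groupby(batches.to_numpy()).mean().T  # genes x batches
    grand = batch_means.mean(axis=1)
    deviations = batch_means.sub(grand, axis=0)  # genes x batches
    correction = deviations.loc[:, batches.to_numpy()]
    correction.columns = vals.columns
    corrected = vals - correction
    return AbundanceMatrix(corrected, pseudocount=am.pseudocount,
                           normalized=True, batch_corrected=True)


# ---------------------------------------------------------------------------
# Stability scoring
# ---------------------------------------------------------------------------

def modified_z(x: np.ndarray) -> np.ndarray:
    """Robust Z-score 0.6745 * (x - median) / MAD across an array."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValidationError("MAD is zero; input is degenerate (constant)")
    return MODIFIED_Z_CONSTANT * (x - med) / mad


def compute_stability(am: AbundanceMatrix, cfg: RankingConfig | None = None) -> StabilityTable:
    """Per-miRNA mean abundance, CV% and modified Z stability score.

    CV is 100 * sd / mean of log2 abundances across samples (sample sd,
    n-1 denominator); genes with nonpositive mean are dropped with a
    logged reason.  The score combines robust Z-transforms of mean and CV
    across the retained genes.
    """
    cfg = cfg or RankingConfig()
    if am.values.shape[1] < 3:
        raise ValidationError("need >= 3 samples to assess stability")
    means = am.values.mean(axis=1)
    sds = am.values.std(axis=1, ddof=1)
    ok = means > 0
    for g in means.index[~ok]:
        logger.info("stability: dropped %s (mean log2 abundance %.3f <= 0)",
                    g, means[g])
    means, sds = means[ok], sds[ok]
    cv = 100.0 * sds / means
    mz_mean = modified_z(means.to_numpy())
    mz_cv = modified_z(cv.to_numpy())
    if cfg.scoring == "mz_diff":
        z = mz_mean - mz_cv
    else:  # inv_cv
        z = modified_z(-cv.to_numpy())
    df = pd.DataFrame({
        "mirna": means.index,
        "mean_abundance": means.to_numpy(),
        "cv_percent": cv.to_numpy(),
        "z_score": z,
    })
    return _rank(df)


def _rank(df: pd.DataFrame) -> StabilityTable:
    # sort by z desc, ties by higher mean abundance then gene id
    df = df.sort_values(
        by=["z_score", "mean_abundance", "mirna"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return StabilityTable(df)


def rank_select(stab: StabilityTable, top_n: int = 20) -> StabilityTable:
    """Re-rank by Z descending and return the top ``top_n`` rows."""
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    if len(stab) == 0:
        raise ValidationError("empty stability table")
    ranked = _rank(stab.table.drop(columns=["rank"]))
    return StabilityTable(ranked.table.head(top_n).reset_index(drop=True))


def select_candidates(ranked: StabilityTable, exclude: list[str] | None = None,
                      add_external: list[str] | None = None,
                      n_candidates: int = 3) -> list[str]:
    """Pick validation candidates from the ranking.

    Walks the table in rank order, skips miRNAs in ``exclude`` (e.g. known
    oncomiRs that would be study targets rather than normalizers), stops
    after ``n_candidates`` picks, then appends ``add_external`` names
    (externally motivated normalizers), deduplicated.
    """
    exclude = list(exclude or [])
    add_external = list(add_external or [])
    ordered = ranked.table.sort_values("rank")
    picks: list[str] = []
    for _, row in ordered.iterrows():
        name = row["mirna"]
        if name in exclude:
            logger.info("candidate selection: skipped %s (rank %d, excluded)",
                        name, row["rank"])
            continue
        picks.append(name)
        if len(picks) >= n_candidates:
            break
    if not picks:
        raise ValidationError("exclusion list removed every ranked miRNA")
    for name in add_external:
        if name not in picks:
            picks.append(name)
            logger.info("candidate selection: added external candidate %s", name)
    return picks


# ---------------------------------------------------------------------------
# End-to-end ranking
# ---------------------------------------------------------------------------

def rank_mirnas(cm: CountMatrix, sheet: SampleSheet,
                cfg: RankingConfig | None = None) -> StabilityTable:
    """Full ranking: depth filter -> gene filter -> normalize -> batch
    correction -> stability score -> top-n table."""
    cfg = cfg or RankingConfig()
    cm = drop_low_depth_samples(cm, cfg.min_reads_per_sample)
    cm = filter_consistent_mirnas(cm, cfg.min_read_sum, cfg.min_detect_frac)
    sf = estimate_size_factors(cm)
    am = normalize_log2(cm, sf, cfg.pseudocount)
    am = correct_batch(am, sheet)
    stab = compute_stability(am, cfg)
    return rank_select(stab, cfg.top_n)


def plot_abundance_vs_cv(stab: StabilityTable, path=None):
    """Scatter of mean abundance vs CV%, annotated with ranks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = stab.table
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["mean_abundance"], df["cv_percent"], c=df["z_score"],
               cmap="viridis", s=40)
    for _, r in df.iterrows():
        ax.annotate(str(int(r["rank"])), (r["mean_abundance"], r["cv_percent"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("mean log2 abundance")
    ax.set_ylabel("CV (%)")
    ax.set_title("Abundance vs variation of ranked miRNAs")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
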
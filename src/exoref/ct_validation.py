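"""qRT-PCR stability assessment of candidate reference miRNAs.

Replicate Ct values are collapsed to per-(sample, target) means, the
exogenous spike-in (cel-miR-39) is checked against its expected
retrotranscription-efficiency window, and each target's Ct distribution
is compared between healthy donors and patients (two-group) and across
disease groups (multi-group).  A Shapiro-Wilk gate decides, per contrast
family, between the parametric branch (pooled-variance unpaired t /
one-way ANOVA + Tukey HSD) and the nonparametric branch (Mann-Whitney /
Kruskal-Wallis + Dunn with Bonferroni adjustment).  A target is declared
*stable* when no contrast - omnibus or adjusted pairwise - is significant
at alpha.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CtTable, SampleSheet, TestReport, ValidationError

logger = logging.getLogger("exoref.ct")

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"

TWO_GROUP_CONTRAST = "HD_vs_patients"
OMNIBUS_CONTRAST = "between_groups"


@dataclass
class ValidationConfig:
    alpha: float = 0.05
    spikein_target: str = "cel-miR-39"
    spikein_window: tuple[float, float] = (14.0, 19.0)
    min_replicates: int = 2
    strict_spikein: bool = False
    control_group: str = "HD"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        lo, hi = self.spikein_window
        if not lo < hi:
            raise ValidationError("spike-in window must satisfy low < high")


# ---------------------------------------------------------------------------
# Replicate collapsing and spike-in QC
# ---------------------------------------------------------------------------

def collapse_replicates(ct: CtTable, cfg: ValidationConfig | None = None) -> pd.DataFrame:
    """Mean Ct over determined replicates, per (sample, target).

    Pairs with fewer than ``min_replicates`` determined replicates are
    marked missing (their mean is NaN); missingness is logged.
    """
    cfg = cfg or ValidationConfig()
    grp = ct.records.groupby(["sample_id", "target"], sort=True)["ct"]
    mean_ct = grp.mean()
    n_used = grp.count()
    missing = n_used < cfg.min_replicates
    out = pd.DataFrame({
        "mean_ct": mean_ct.where(~missing),
        "n_replicates_used": n_used,
        "missing": missing,
    }).reset_index()
    for _, r in out[out["missing"]].iterrows():
        logger.info("collapse: %s / %s missing (%d determined replicates < %d)",
                    r["sample_id"], r["target"], r["n_replicates_used"],
                    cfg.min_replicates)
    return out


def spike_in_qc(collapsed: pd.DataFrame, cfg: ValidationConfig | None = None) -> pd.DataFrame:
    """Per-sample spike-in pass/fail against the Ct efficiency window.

    Pass iff the spike-in mean Ct lies inside the window (inclusive).
    Failures are warnings by default; ``strict_spikein`` raises instead.
    """
    cfg = cfg or ValidationConfig()
    lo, hi = cfg.spikein_window
    spike = collapsed[collapsed["target"] == cfg.spikein_target]
    samples = pd.unique(collapsed["sample_id"])
    absent = set(samples) - set(spike["sample_id"])
    if absent:
        msg = f"spike-in {cfg.spikein_target!r} absent for samples {sorted(absent)}"
        if cfg.strict_spikein:
            raise ValidationError(msg)
        logger.warning(msg)
    ok = spike["mean_ct"].between(lo, hi, inclusive="both") & ~spike["missing"]
    qc = pd.DataFrame({
        "sample_id": spike["sample_id"].to_numpy(),
        "spikein_ct": spike["mean_ct"].to_numpy(),
        "passed": ok.to_numpy(),
    })
    for _, r in qc[~qc["passed"]].iterrows():
        msg = (f"spike-in QC fail for sample {r['sample_id']}: "
               f"Ct {r['spikein_ct']} outside [{lo}, {hi}]")
        if cfg.strict_spikein:
            raise ValidationError(msg)
        logger.warning(msg)
    return qc


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def normality_gate(values_by_group: dict[str, np.ndarray | list[float]],
                   alpha: float = 0.05) -> str:
    """Shapiro-Wilk per group; any rejection routes to the nonparametric branch.

    Groups with fewer than 3 values cannot be tested and are skipped with
    a warning; if every group is skipped this is an error.
    """
    tested = 0
    reject = False
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 3:
            logger.warning("normality gate: group %s has %d values, skipped",
                           name, v.size)
            continue
        tested += 1
        p = stats.shapiro(v).pvalue
        logger.info("normality gate: Shapiro-Wilk %s p=%.4g", name, p)
        if p <= alpha:
            reject = True
    if tested == 0:
        raise ValidationError("no group large enough for the normality gate")
    return NONPARAMETRIC if reject else PARAMETRIC


# ---------------------------------------------------------------------------
# Two-group tests
# ---------------------------------------------------------------------------

def two_group_test(a, b, mode: str, alpha: float = 0.05,
                   contrast: str = TWO_GROUP_CONTRAST) -> TestReport:
    """Two-sided two-group comparison.

    Parametric: pooled-variance unpaired t.  Nonparametric: Mann-Whitney,
    exact when both n <= 8 with no ties, otherwise the tie-corrected
    normal approximation without continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty group in two-group test")
    if mode == PARAMETRIC:
        if a.size < 2 or b.size < 2:
            raise ValidationError("parametric two-group test needs n >= 2 per group")
        res = stats.ttest_ind(a, b, equal_var=True)
        return TestReport(contrast, "unpaired t", float(res.statistic),
                          float(res.pvalue), alpha=alpha)
    if mode == NONPARAMETRIC:
        if a.size + b.size < 3:
            raise ValidationError("Mann-Whitney needs combined n >= 3")
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        if a.size <= 8 and b.size <= 8 and no_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=False)
        return TestReport(contrast, "Mann-Whitney", float(res.statistic),
                          float(res.pvalue), alpha=alpha)
    raise ValidationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Multi-group tests and post-hocs
# ---------------------------------------------------------------------------

def dunn_test(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[TestReport]:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie
    groups of size t.  Two-sided normal p-values, Bonferroni-adjusted
    over the number of pairs.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # mean rank per group
    offsets = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = {k: ranks[offsets[i]:offsets[i + 1]].mean()
                  for i, k in enumerate(names)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    reports = []
    for i, j in pairs:
        ni = np.asarray(groups[i]).size
        nj = np.asarray(groups[j]).size
        se = np.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * len(pairs))
        reports.append(TestReport(f"{i} vs {j}", "Dunn", float(z), float(p_adj),
                                  alpha=alpha, adjusted=True))
    return reports


def multi_group_test(groups: dict[str, np.ndarray | list[float]], mode: str,
                     alpha: float = 0.05,
                     omnibus_contrast: str = OMNIBUS_CONTRAST
                     ) -> tuple[TestReport, list[TestReport]]:
    """Omnibus test plus all pairwise post-hocs.

    Parametric: one-way ANOVA then Tukey HSD (studentized-range p-values,
    inherently multiplicity-adjusted).  Nonparametric: tie-corrected
    Kruskal-Wallis then Dunn's z with Bonferroni adjustment.
    """
    clean = {}
    for k, v in groups.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        clean[k] = arr
    if len(clean) < 3:
        raise ValidationError("need >= 3 groups; use two_group_test for two")
    if any(v.size < 2 for v in clean.values()):
        raise ValidationError("each group needs >= 2 values")
    names = list(clean)
    arrays = [clean[k] for k in names]
    if mode == PARAMETRIC:
        f_res = stats.f_oneway(*arrays)
        omnibus = TestReport(omnibus_contrast, "one-way ANOVA",
                             float(f_res.statistic), float(f_res.pvalue),
                             alpha=alpha)
        hsd = stats.tukey_hsd(*arrays)
        pairwise = []
        for ii, jj in itertools.combinations(range(len(names)), 2):
            pairwise.append(TestReport(
                f"{names[ii]} vs {names[jj]}", "Tukey HSD",
                float(hsd.statistic[ii, jj]), float(hsd.pvalue[ii, jj]),
                alpha=alpha, adjusted=True))
        return omnibus, pairwise
    if mode == NONPARAMETRIC:
        h_res = stats.kruskal(*arrays)
        omnibus = TestReport(omnibus_contrast, "Kruskal-Wallis",
                             float(h_res.statistic), float(h_res.pvalue),
                             alpha=alpha)
        return omnibus, dunn_test(clean, alpha=alpha)
    raise ValidationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Verdict
# ---------------------------------------------------------------------------

@dataclass
class Verdict:
    target: str
    stable: bool
    evidence: list[TestReport]


def stability_verdict(reports_by_target: dict[str, list[TestReport]],
                      alpha: float = 0.05,
                      required_contrasts: tuple[str, ...] = (
                          TWO_GROUP_CONTRAST, OMNIBUS_CONTRAST)
                      ) -> dict[str, Verdict]:
    """Stable iff no contrast (omnibus or adjusted pairwise) is significant.

    Every target must carry at least the healthy-vs-patients two-group
    contrast and the per-disease multi-group omnibus.
    """
    verdicts: dict[str, Verdict] = {}
    for target, reports in reports_by_target.items():
        present = {r.contrast for r in reports}
        missing = [c for c in required_contrasts if c not in present]
        if missing:
            raise ValidationError(
                f"target {target}: missing required contrasts {missing}")
        significant = [r for r in reports if r.p_value <= alpha]
        stable = not significant
        if significant:
            logger.info("verdict: %s unstable (%s)", target,
                        "; ".join(f"{r.contrast} p={r.p_value:.3g}"
                                  for r in significant))
        verdicts[target] = Verdict(target, stable, list(reports))
    return verdicts


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def assess_stability(ct: CtTable, sheet: SampleSheet,
                     cfg: ValidationConfig | None = None
                     ) -> dict[str, Verdict]:
    """Full validation: collapse, QC, gated contrasts, verdict per target.

    For each endogenous target: (a) healthy donors vs all patients pooled,
    two-group; (b) all groups (control + each disease) as a multi-group
    family with post-hoc pairwise comparisons.  Each family is routed
    through its own Shapiro-Wilk gate.
    """
    cfg = cfg or ValidationConfig()
    collapsed = collapse_replicates(ct, cfg)
    if cfg.spikein_target in set(collapsed["target"]):
        spike_in_qc(collapsed, cfg)
    sheet.require_samples(list(pd.unique(collapsed["sample_id"])))
    merged = collapsed.merge(
        sheet.table.reset_index().rename(columns={"index": "sample_id"}),
        on="sample_id", how="left")
    reports_by_target: dict[str, list[TestReport]] = {}
    for target, sub in merged.groupby("target", sort=True):
        if target == cfg.spikein_target:
            continue
        sub = sub[~sub["missing"]]
        by_group = {g: d["mean_ct"].to_numpy()
                    for g, d in sub.groupby("group", sort=True)}
        if cfg.control_group not in by_group:
            raise ValidationError(
                f"control group {cfg.control_group!r} absent for {target}")
        control = by_group[cfg.control_group]
        patients = np.concatenate([v for g, v in by_group.items()
                                   if g != cfg.control_group])
        mode2 = normality_gate(
            {cfg.control_group: control, "patients": patients}, cfg.alpha)
        rep2 = two_group_test(control, patients, mode2, cfg.alpha,
                              contrast=TWO_GROUP_CONTRAST)
        modeK = normality_gate(by_group, cfg.alpha)
        omnibus, pairwise = multi_group_test(by_group, modeK, cfg.alpha)
        reports_by_target[target] = [rep2, omnibus, *pairwise]
    return stability_verdict(reports_by_target, cfg.alpha)


def verdicts_to_frame(verdicts: dict[str, Verdict]) -> pd.DataFrame:
    rows = [{"target": v.target, "stable": v.stable,
             "n_significant": sum(r.p_value <= r.alpha for r in v.evidence)}
            for v in verdicts.values()]
    return pd.DataFrame(rows).sort_values("target").reset_index(drop=True)
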
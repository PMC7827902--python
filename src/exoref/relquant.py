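"""ΔCt / ΔΔCt relative quantification against a reference miRNA.

The downstream purpose of reference selection: once a stable endogenous
normalizer is chosen (miR-26a-5p by default), target abundance is
expressed as ΔCt = Ct(target) − Ct(reference) per sample, then as
ΔΔCt = ΔCt − mean calibrator-group ΔCt, and finally as the fold change
2^−ΔΔCt.  Amplification efficiency is fixed at 2 (the classic
formulation); the calibrator aggregate is the arithmetic mean of ΔCt,
i.e. the geometric mean of fold changes, so the calibrator group's
geometric-mean fold is exactly 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import SampleSheet, ValidationError

logger = logging.getLogger("exoref.relquant")

DEFAULT_REFERENCE = "miR-26a-5p"


def delta_ct(collapsed: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-sample ΔCt = mean_ct(sample, target) − mean_ct(sample, reference).

    ``collapsed`` is the output of ``collapse_replicates``.  Samples where
    the reference is missing are excluded with a logged reason; the
    reference itself is not reported as a target.
    """
    if reference not in set(collapsed["target"]):
        raise ValidationError(f"reference {reference!r} absent from the panel")
    ref = collapsed[collapsed["target"] == reference].set_index("sample_id")
    usable = ref.index[~ref["missing"]]
    dropped = sorted(set(ref.index) - set(usable))
    for s in dropped:
        logger.info("delta_ct: sample %s excluded (reference %s missing)",
                    s, reference)
    tgt = collapsed[(collapsed["target"] != reference)
                    & collapsed["sample_id"].isin(usable)
                    & ~collapsed["missing"]]
    out = tgt[["sample_id", "target", "mean_ct"]].copy()
    out["delta_ct"] = (out["mean_ct"].to_numpy()
                       - ref.loc[out["sample_id"], "mean_ct"].to_numpy())
    return out.drop(columns=["mean_ct"]).reset_index(drop=True)


def ddct_fold_change(dct: pd.DataFrame, sheet: SampleSheet,
                     calibrator_group: str = "HD") -> pd.DataFrame:
    """ΔΔCt against the calibrator group's mean ΔCt, and fold = 2^−ΔΔCt."""
    sheet.require_samples(list(pd.unique(dct["sample_id"])))
    groups = sheet.table.loc[dct["sample_id"], "group"].to_numpy()
    df = dct.assign(group=groups)
    cal = df[df["group"] == calibrator_group]
    if cal.empty:
        raise ValidationError(
            f"calibrator group {calibrator_group!r} has no samples")
    cal_mean = cal.groupby("target")["delta_ct"].mean()
    missing = sorted(set(df["target"]) - set(cal_mean.index))
    if missing:
        raise ValidationError(
            f"calibrator group lacks targets {missing}")
    df["delta_delta_ct"] = (df["delta_ct"].to_numpy()
                            - cal_mean.loc[df["target"]].to_numpy())
    df["fold_change"] = np.exp2(-df["delta_delta_ct"])
    return df.reset_index(drop=True)
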
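"""Relative gene expression by the comparative (delta-delta-Ct) method.

Technical replicates are averaged per (sample, gene); dCt = Ct(gene) -
Ct(housekeeping) within each sample; ddCt = dCt(sample) - mean dCt over the
reference-group samples; RQ = 2^(-ddCt).  A single housekeeping gene
normalizes each run (e.g. GUSB for murine panels, GAPDH for human panels);
per-sample RQs are emitted so biological scatter stays visible, and the
group-level RQ is 2^(-mean ddCt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["delta_delta_ct", "load_ct_table"]

_REQUIRED = ("sample_id", "group", "gene", "ct")


def load_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample_id, group, gene, tech_rep, ct."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def delta_delta_ct(ct: pd.DataFrame, housekeeping: str,
                   reference_group: str) -> pd.DataFrame:
    """Per-sample and per-group relative quantification.

    Returns a tidy frame with one row per (sample, gene != housekeeping):
    ``dct``, ``ddct``, ``rq`` plus group-level ``group_rq`` (2^-mean ddCt)
    and the dispersion (SD of per-sample RQ) across biological replicates.
    Missing housekeeping measurements or an empty reference group raise.
    """
    for col in _REQUIRED:
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if housekeeping not in set(ct["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from table")
    if not (ct["group"] == reference_group).any():
        raise ValueError(f"reference group {reference_group!r} is empty")

    # technical replicates averaged per (sample, gene)
    mean_ct = (ct.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
                 .mean().reset_index())
    hk = mean_ct[mean_ct["gene"] == housekeeping] \
        .set_index("sample_id")["ct"]
    targets = mean_ct[mean_ct["gene"] != housekeeping].copy()
    missing_hk = sorted(set(targets["sample_id"]) - set(hk.index))
    if missing_hk:
        raise ValueError(f"samples without housekeeping Ct: {missing_hk[:5]}")
    targets["dct"] = targets["ct"] - targets["sample_id"].map(hk)

    ref = targets[targets["group"] == reference_group]
    ref_dct = ref.groupby("gene")["dct"].mean()
    absent = sorted(set(targets["gene"]) - set(ref_dct.index))
    if absent:
        raise ValueError(f"gene(s) absent in reference group: {absent}")
    targets["ddct"] = targets["dct"] - targets["gene"].map(ref_dct)
    targets["rq"] = np.exp2(-targets["ddct"])

    grp = (targets.groupby(["group", "gene"])
           .agg(mean_ddct=("ddct", "mean"), rq_sd=("rq", "std"),
                n_samples=("sample_id", "nunique"))
           .reset_index())
    grp["group_rq"] = np.exp2(-grp["mean_ddct"])
    return targets.merge(grp, on=["group", "gene"], how="left")
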
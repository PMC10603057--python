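"""Relative qPCR quantification by the Pfaffl method.

Expression of a target gene relative to a reference gene (here Gapdh by
convention), corrected for per-gene amplification efficiency:

    ratio = E_target^(Ct_target,control - Ct_target,sample)
          / E_ref^(Ct_ref,control - Ct_ref,sample)

With both efficiencies at the theoretical maximum of 2 this reduces to
the familiar 2^-ddCt.  Per-sample ratios are computed against the
control group's mean Ct and then normalized so the control group's mean
ratio is exactly 1; condition-level results are reported as mean +- SEM
over samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pfaffl_ratio", "relative_expression"]


def _check_efficiency(e: float, name: str) -> None:
    if not 1.0 < e <= 2.0:
        raise ValueError(
            f"amplification efficiency {name}={e} outside (1, 2] "
            "(fold amplification per cycle)"
        )


def pfaffl_ratio(
    ct_target_control: float,
    ct_target_sample: float,
    ct_ref_control: float,
    ct_ref_sample: float,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float:
    """Efficiency-corrected fold change of a sample vs control.

    ratio = e_target**(dCt_target) / e_ref**(dCt_ref) with
    dCt = Ct_control - Ct_sample per gene.
    """
    _check_efficiency(e_target, "e_target")
    _check_efficiency(e_ref, "e_ref")
    return float(
        e_target ** (ct_target_control - ct_target_sample)
        / e_ref ** (ct_ref_control - ct_ref_sample)
    )


def relative_expression(
    table: pd.DataFrame,
    control_condition: str,
    reference_gene: str = "Gapdh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample Pfaffl ratios normalized to the control group.

    ``table`` follows the Ct-table schema: columns sample, condition_id,
    gene, ct, efficiency (is_reference optional).  For every target
    gene, each sample's Pfaffl ratio is computed against the control
    group's mean Ct (arithmetic mean of cycles, target and reference),
    then divided by the control group's mean ratio so the control mean
    is exactly 1.

    Returns
    -------
    (per_sample, summary)
        per_sample: sample, condition_id, gene, ratio.
        summary: per (gene, condition_id) mean, sem, n over samples.

    Raises
    ------
    ValueError
        If the control condition or reference gene is absent, or a
        sample lacks its reference-gene Ct.
    """
    required = {"sample", "condition_id", "gene", "ct", "efficiency"}
    if missing := required - set(table.columns):
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if control_condition not in set(table["condition_id"]):
        raise ValueError(f"control condition {control_condition!r} not in table")
    if reference_gene not in set(table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not in table")

    ref = table[table["gene"] == reference_gene].set_index("sample")
    if ref.index.duplicated().any():
        raise ValueError("multiple reference-gene wells per sample")
    targets = table[table["gene"] != reference_gene]
    no_ref = sorted(set(targets["sample"]) - set(ref.index))
    if no_ref:
        raise ValueError(f"missing reference-gene Ct for samples: {no_ref}")

    e_ref = float(ref["efficiency"].iloc[0])
    _check_efficiency(e_ref, reference_gene)
    ctrl_ref_ct = float(
        ref.loc[ref["condition_id"] == control_condition, "ct"].mean()
    )

    records = []
    for gene, sub in targets.groupby("gene"):
        e_t = float(sub["efficiency"].iloc[0])
        _check_efficiency(e_t, gene)
        ctrl_ct = sub.loc[sub["condition_id"] == control_condition, "ct"]
        if ctrl_ct.empty:
            raise ValueError(
                f"gene {gene!r} has no wells in the control condition"
            )
        ctrl_ct_mean = float(ctrl_ct.mean())
        for _, row in sub.iterrows():
            ratio = pfaffl_ratio(
                ctrl_ct_mean,
                float(row["ct"]),
                ctrl_ref_ct,
                float(ref.loc[row["sample"], "ct"]),
                e_t,
                e_ref,
            )
            records.append(
                {
                    "sample": row["sample"],
                    "condition_id": row["condition_id"],
                    "gene": gene,
                    "ratio": ratio,
                }
            )
    per_sample = pd.DataFrame(records)

    # renormalize so each gene's control-group mean ratio is exactly 1
    ctrl_mean = (
        per_sample[per_sample["condition_id"] == control_condition]
        .groupby("gene")["ratio"]
        .mean()
    )
    per_sample["ratio"] = per_sample["ratio"] / per_sample["gene"].map(ctrl_mean)

    summary = (
        per_sample.groupby(["gene", "condition_id"])["ratio"]
        .agg(
            mean="mean",
            sem=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x)))
            if len(x) > 1
            else 0.0,
            n="count",
        )
        .reset_index()
    )
    return per_sample, summary
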
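"""Relative gene-expression quantification from qPCR Ct tables.

Implements the comparative threshold-cycle method: per-sample
ΔCt = mean(target Ct) − mean(reference Ct) over replicates, relative
amounts 2^−ΔCt, and fold changes versus a control condition 2^−ΔΔCt.
Replicates are aggregated by arithmetic mean of Ct; equal amplification
efficiency between target and reference genes is assumed (no efficiency
correction is applied).

Tables are long-format DataFrames/CSVs with columns
``sample_id, condition, gene, replicate, Ct``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "condition", "gene", "replicate", "Ct")


def validate_ct_table(table: pd.DataFrame, reference_gene: str | None = None) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {', '.join(missing)}")
    ct = pd.to_numeric(table["Ct"], errors="coerce")
    if ct.isna().any() or np.isinf(ct).any():
        raise ValueError("all Ct values must be finite")
    if (ct < 0).any():
        raise ValueError("Ct values must be non-negative")
    if reference_gene is not None:
        for sample, grp in table.groupby("sample_id"):
            if reference_gene not in set(grp["gene"]):
                raise ValueError(
                    f"reference gene {reference_gene!r} missing for sample "
                    f"{sample!r}"
                )


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_ct_table(table)
    return table


def delta_ct(
    table: pd.DataFrame, target_gene: str, reference_gene: str
) -> pd.Series:
    """Per-sample ΔCt = mean target Ct − mean reference Ct (cycles)."""
    validate_ct_table(table, reference_gene)
    out = {}
    for sample, grp in table.groupby("sample_id"):
        genes = grp.groupby("gene")["Ct"].mean()
        if target_gene not in genes:
            raise ValueError(
                f"target gene {target_gene!r} missing for sample {sample!r}"
            )
        out[sample] = float(genes[target_gene] - genes[reference_gene])
    return pd.Series(out, name="delta_ct").rename_axis("sample_id")


def relative_amount(dct):
    """Relative target amount 2^−ΔCt (1 when target equals reference)."""
    return 2.0 ** (-np.asarray(dct, dtype=float)) if np.ndim(dct) else float(
        2.0 ** (-float(dct))
    )


def ddct_fold_change(dct_condition, dct_control):
    """Fold change of a condition versus control: 2^−(ΔCt_cond − ΔCt_ctrl)."""
    return float(2.0 ** (-(float(dct_condition) - float(dct_control))))


def fold_change_table(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
) -> pd.DataFrame:
    """Condition-level relative expression for every non-reference gene.

    ΔCt is averaged over the samples of each condition; fold change is
    2^−ΔΔCt against the control condition's mean ΔCt.
    """
    validate_ct_table(table, reference_gene)
    if control_condition not in set(table["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent")
    rows = []
    genes = [g for g in table["gene"].unique() if g != reference_gene]
    cond_of_sample = table.groupby("sample_id")["condition"].first()
    for gene in genes:
        dct = delta_ct(table, gene, reference_gene)
        per_cond = dct.groupby(cond_of_sample).mean()
        if control_condition not in per_cond:
            raise ValueError(
                f"no ΔCt for gene {gene!r} in control {control_condition!r}"
            )
        ctrl = per_cond[control_condition]
        for cond, val in per_cond.items():
            rows.append({
                "gene": gene,
                "condition": cond,
                "delta_ct": float(val),
                "relative_amount": relative_amount(float(val)),
                "fold_change_vs_control": ddct_fold_change(val, ctrl),
            })
    return pd.DataFrame(rows)
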
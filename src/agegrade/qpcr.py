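"""qRT-PCR processing: replicate aggregation and logcontrast normalization.

The pipeline starts from called Ct values (cycle at which amplification
fluorescence crosses the detection criterion; Ct calling is instrument-side).
Triplicate wells are averaged per (sample, gene), then each candidate gene is
normalized against the 40S ribosomal protein S7 reference gene as a
logcontrast: x[i,g] = meanCt[i,g] − meanCt[i,ref].  Because Ct is (minus) the
log2 of starting template under full amplification efficiency, this ΔCt is a
log-scale contrast of target against reference expression; any per-sample
additive Ct shift (template amount, pipetting) cancels exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, InputError
from .simulate import DEFAULT_REFERENCE_GENE

MAX_CYCLES = 45  # thermal-cycling programme length


def validate_ct_table(table: pd.DataFrame, max_cycles: float = MAX_CYCLES) -> None:
    """Check the CtTable contract: required columns, positive Ct within the
    cycle budget, unique replicate indices per (sample, gene)."""
    required = {"sample_id", "gene_id", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"CtTable missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise InputError("CtTable is empty")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)):
        raise InputError("CtTable contains non-finite ct values")
    if np.any(ct <= 0) or np.any(ct > max_cycles):
        raise InputError(f"ct values must lie in (0, {max_cycles}]")
    dup = table.duplicated(subset=["sample_id", "gene_id", "replicate"])
    if dup.any():
        first = table.loc[dup.idxmax()]
        raise InputError(
            "duplicate replicate index for "
            f"({first['sample_id']}, {first['gene_id']}, {first['replicate']})"
        )


def aggregate_replicates(
    table: pd.DataFrame, qc_sd_threshold: float = 0.5
) -> pd.DataFrame:
    """Mean Ct per (sample, gene), with replicate SD and a QC flag.

    Returns a frame with columns sample_id, gene_id, mean_ct, sd_ct,
    n_replicates, qc_flag.  ``qc_flag`` marks pairs whose replicate SD exceeds
    ``qc_sd_threshold`` cycles; flagged pairs are retained, not dropped.
    """
    validate_ct_table(table)
    grouped = table.groupby(["sample_id", "gene_id"], sort=False)["ct"]
    out = grouped.agg(mean_ct="mean", sd_ct="std", n_replicates="count").reset_index()
    out["sd_ct"] = out["sd_ct"].fillna(0.0)  # single replicate -> SD 0
    out["qc_flag"] = out["sd_ct"] > qc_sd_threshold
    return out


def logcontrast(
    mean_ct: pd.DataFrame, reference_gene_id: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Reference-normalize mean Ct values into the logcontrast matrix.

    ``mean_ct`` is the output of :func:`aggregate_replicates` (or any frame
    with sample_id, gene_id, mean_ct).  Returns a samples × genes DataFrame of
    ΔCt values with the reference gene excluded from the columns.

    Raises :class:`DataError` naming the sample if the reference gene is
    missing for any sample, or naming the (sample, gene) pair if a candidate
    measurement is absent.
    """
    wide = mean_ct.pivot(index="sample_id", columns="gene_id", values="mean_ct")
    if reference_gene_id not in wide.columns:
        raise DataError(f"reference gene {reference_gene_id!r} absent from table")
    ref = wide[reference_gene_id]
    missing_ref = ref.index[ref.isna()]
    if len(missing_ref) > 0:
        raise DataError(
            f"reference gene {reference_gene_id!r} missing for sample "
            f"{missing_ref[0]!r}"
        )
    x = wide.drop(columns=[reference_gene_id]).sub(ref, axis=0)
    if x.isna().any().any():
        stacked = x.isna().stack()
        sid, gid = stacked[stacked].index[0]
        raise DataError(f"missing Ct for sample {sid!r}, gene {gid!r}")
    x.columns.name = None
    x.index.name = "sample_id"
    return x


def ct_to_logcontrast(
    table: pd.DataFrame,
    reference_gene_id: str = DEFAULT_REFERENCE_GENE,
    qc_sd_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: aggregate replicates then logcontrast-normalize.

    Returns ``(logcontrast_matrix, qc_table)``.
    """
    agg = aggregate_replicates(table, qc_sd_threshold=qc_sd_threshold)
    return logcontrast(agg, reference_gene_id), agg
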
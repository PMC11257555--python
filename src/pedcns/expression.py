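"""Expression-matrix support: symbol collapse, cohort z-scores, flags.

Input matrices carry one row per (Ensembl gene id, gene symbol) and one
column per sample (TPM / FPKM / expected count). Collapse keeps, for each
symbol, the row with the maximal mean across samples after discarding
all-zero rows, so downstream modules can treat symbols as unique keys.
Z-scores are computed per gene within a cohort group (cancer group x RNA
library type, to avoid batch effects) on log2(x+1)-transformed values
using the population standard deviation; constant genes get z = 0.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .model import Thresholds


def collapse_to_symbol(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene symbols to the row with maximal mean.

    ``matrix`` has columns ``gene_id``, ``gene_symbol`` plus sample
    columns. Rows whose values are all zero are dropped first; ties on the
    row mean are broken by lexicographic Ensembl gene id. The result is
    indexed by unique gene symbol.
    """
    value_cols = [c for c in matrix.columns if c not in ("gene_id", "gene_symbol")]
    values = matrix[value_cols].to_numpy(dtype=float)
    nonzero = values.sum(axis=1) > 0
    kept = matrix.loc[nonzero].copy()
    kept["_row_mean"] = kept[value_cols].mean(axis=1)
    # stable pick: highest mean, then lexicographically smallest gene_id
    kept = kept.sort_values(
        ["gene_symbol", "_row_mean", "gene_id"], ascending=[True, False, True]
    )
    collapsed = kept.drop_duplicates("gene_symbol", keep="first")
    out = collapsed.set_index("gene_symbol")[value_cols]
    out.index.name = "gene_symbol"
    return out


def cohort_zscore(
    matrix: pd.DataFrame, grouping: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Per-gene z-scores within each cohort group.

    ``matrix`` is genes x samples (collapsed). Values are log2(x+1)
    transformed, then standardized per gene within each group of
    ``grouping`` (sample id -> cohort label; one cohort when omitted)
    using the population (n) standard deviation. Genes constant within a
    cohort — including single-sample cohorts — get z = 0.
    """
    if grouping is None:
        grouping = {s: "all" for s in matrix.columns}
    logged = np.log2(matrix.astype(float) + 1.0)
    z = pd.DataFrame(0.0, index=matrix.index, columns=matrix.columns)
    groups: Dict[str, list] = {}
    for sample in matrix.columns:
        groups.setdefault(grouping.get(sample, "all"), []).append(sample)
    for samples in groups.values():
        block = logged[samples]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        centered = block.sub(mean, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = centered.div(sd.replace(0.0, np.nan), axis=0)
        z[samples] = scaled.fillna(0.0)
    return z


def expression_flag(
    zscores: pd.DataFrame,
    gene: str,
    direction: str,
    thresholds: Thresholds = Thresholds(),
) -> pd.Series:
    """Boolean per sample: over-expression (z >= 2) or under (z < -2).

    The under-expression boundary is strict (z = -2 exactly is not
    flagged), matching the strict inequality of the subtyping criteria.
    """
    if gene not in zscores.index:
        return pd.Series(False, index=zscores.columns)
    z = zscores.loc[gene]
    if direction == "over":
        return z >= thresholds.zscore_high
    if direction == "under":
        return z < thresholds.zscore_low
    raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
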
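"""Combine per-timepoint differential-expression results into one gene list.

A gene tested at several timepoints keeps the row with its lowest FDR; the
combined list is then filtered on FDR and absolute log2 fold change before
network construction.  The DE tables themselves come from an upstream tool
(e.g. an edgeR quasi-likelihood fit); this module only consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DETableError

DE_COLUMNS = ["gene_id", "log2_fc", "p_value", "fdr"]

COMBINED_COLUMNS = [
    "gene_id",
    "min_fdr",
    "log2_fc",
    "direction",
    "comparison",
    "n_comparisons",
]


@dataclass
class DETable:
    """One comparison's differential-expression results.

    Parameters
    ----------
    label
        Comparison label (e.g. ``"1_month"``).
    frame
        Table with columns ``gene_id, log2_fc, p_value, fdr``.  ``fdr`` is a
        Benjamini–Hochberg adjusted p-value and may be smaller than
        ``p_value`` only through rounding; no ordering between the two is
        enforced.
    """

    label: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DETableError(f"table {self.label!r} missing columns {missing}")
        frame = self.frame.loc[:, DE_COLUMNS].reset_index(drop=True)
        if frame["gene_id"].duplicated().any():
            dups = frame.loc[frame["gene_id"].duplicated(), "gene_id"].tolist()
            raise DETableError(
                f"table {self.label!r} has duplicate gene_ids: {dups[:5]}"
            )
        for col in ("log2_fc", "p_value", "fdr"):
            values = pd.to_numeric(frame[col], errors="coerce").to_numpy(float)
            if not np.all(np.isfinite(values)):
                raise DETableError(f"table {self.label!r}: non-finite {col}")
            frame[col] = values
        for col in ("p_value", "fdr"):
            vals = frame[col].to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise DETableError(f"table {self.label!r}: {col} outside [0, 1]")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)


def combine_timepoints(tables: list[DETable]) -> pd.DataFrame:
    """Merge DE tables into one record per gene, keeping the lowest FDR.

    Ties on FDR are broken by larger ``|log2_fc|``, then by lexicographically
    smaller comparison label, so the result is deterministic.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene_id, min_fdr, log2_fc, direction, comparison,
        n_comparisons`` sorted by ``gene_id``.  ``log2_fc`` and
        ``comparison`` are taken from the row achieving the minimum FDR;
        ``n_comparisons`` counts the tables in which the gene appears.
    """
    if not tables:
        raise DETableError("combine_timepoints requires at least one DE table")
    frames = []
    for table in tables:
        frame = table.frame.copy()
        frame["comparison"] = table.label
        frames.append(frame)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["_abs_lfc"] = pooled["log2_fc"].abs()
    pooled = pooled.sort_values(
        ["fdr", "_abs_lfc", "comparison", "gene_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    n_comparisons = pooled.groupby("gene_id", sort=False)["comparison"].size()
    best = pooled.drop_duplicates("gene_id", keep="first").set_index("gene_id")
    out = pd.DataFrame(
        {
            "gene_id": best.index,
            "min_fdr": best["fdr"].to_numpy(),
            "log2_fc": best["log2_fc"].to_numpy(),
            "direction": np.where(best["log2_fc"] > 0, "up", "down"),
            "comparison": best["comparison"].to_numpy(),
            "n_comparisons": n_comparisons.reindex(best.index).to_numpy(),
        }
    )
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def _check_thresholds(fdr_max: float, min_abs_log2fc: float) -> None:
    if not (0 < fdr_max <= 1):
        raise ValueError(f"fdr_max must be in (0, 1], got {fdr_max}")
    if min_abs_log2fc < 0:
        raise ValueError(f"min_abs_log2fc must be >= 0, got {min_abs_log2fc}")


def filter_significant(
    records: pd.DataFrame,
    fdr_max: float = 1e-5,
    min_abs_log2fc: float = 0.59,
) -> pd.DataFrame:
    """Keep combined records with ``min_fdr <= fdr_max`` and
    ``|log2_fc| >= min_abs_log2fc`` (fold change >= 2**min_abs_log2fc).

    Row order is preserved.  The defaults are the stringent network-stage
    thresholds (FDR <= 1e-5, fold change >= 1.5).
    """
    _check_thresholds(fdr_max, min_abs_log2fc)
    mask = (records["min_fdr"] <= fdr_max) & (
        records["log2_fc"].abs() >= min_abs_log2fc
    )
    return records.loc[mask].reset_index(drop=True)


def summarize_counts(
    tables: list[DETable],
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 0.59,
) -> pd.DataFrame:
    """Per-comparison counts of significant genes, split by direction.

    Returns one row per comparison with columns
    ``comparison, total, up, down`` where ``total == up + down``.
    """
    _check_thresholds(fdr_max, min_abs_log2fc)
    rows = []
    for table in tables:
        frame = table.frame
        passing = frame[
            (frame["fdr"] <= fdr_max) & (frame["log2_fc"].abs() >= min_abs_log2fc)
        ]
        up = int((passing["log2_fc"] > 0).sum())
        down = len(passing) - up
        rows.append(
            {"comparison": table.label, "total": len(passing), "up": up, "down": down}
        )
    return pd.DataFrame(rows, columns=["comparison", "total", "up", "down"])
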
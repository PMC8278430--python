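"""Ct-table ingestion, duplicate QC, spike-in normalization and ddCt.

Implements the Livak relative-quantification workflow for duplicate-well
qRT-PCR data: duplicate pairs whose Ct values differ by 0.2 cycles or more
(inclusive boundary) are excluded, retained pairs are collapsed to their
arithmetic mean Ct, per-sample dCt is taken against an exogenous spike-in
reference assay, and group contrasts are summarized as ddCt and
2^-ddCt relative quantities.  A sample whose spike-in pair fails QC loses
all of its markers (the reference is per-extraction, so nothing downstream
of it is interpretable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, InsufficientDataError, SchemaError
from .simulate import CT_COLUMNS, GROUP_CASE, GROUP_CONTROL

logger = logging.getLogger(__name__)

#: default duplicate-QC threshold in cycles; pairs with |Ct1 - Ct2| >= this
#: are excluded (the rule is inclusive)
DEFAULT_QC_THRESHOLD = 0.2

# Ct values are decimal readings; compare the pair difference after rounding
# so that e.g. 20.20 - 20.00 trips an inclusive 0.2 threshold despite binary
# float representation.
_DIFF_DECIMALS = 9

EXPR_COLUMNS = ["sample_id", "group", "marker", "delta_ct"]
EXCLUSION_COLUMNS = ["sample_id", "assay", "reason", "ct_diff"]


@dataclass
class MarkerComparison:
    """Group contrast of one marker on the dCt scale plus its fold change."""

    marker: str
    n_case: int
    n_control: int
    delta_delta_ct: float
    rq: float
    fold_display: str
    rq_method: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct table (CSV, or TSV for ``.tsv`` paths).

    Required columns: ``sample_id, group, assay, replicate, ct``.  Empty or
    unparsable ``ct`` fields become missing (NaN).  Group labels other than
    ``case``/``control`` are rejected.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            dtype={"sample_id": str, "group": str, "assay": str},
            float_precision="round_trip",  # exact read-back of written Ct values
        )
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty") from None
    missing_cols = [c for c in CT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing_cols)}")
    if len(df) == 0:
        raise InputError(f"{path}: no data rows")
    bad_groups = set(df["group"].unique()) - {GROUP_CASE, GROUP_CONTROL}
    if bad_groups:
        raise SchemaError(
            f"{path}: unknown group label(s) {sorted(bad_groups)}; "
            f"expected '{GROUP_CASE}' or '{GROUP_CONTROL}'"
        )
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df[CT_COLUMNS].copy()


def qc_filter_replicates(
    records: pd.DataFrame, threshold: float = DEFAULT_QC_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the duplicate-concordance rule per sample × assay pair.

    A pair is excluded when |Ct1 − Ct2| >= ``threshold`` (reason
    ``replicate_discordance``), when any replicate is missing
    (``missing_ct``), or when the pair does not consist of exactly two
    wells (``replicate_count``).  Retained pairs collapse to their mean Ct.

    Returns ``(collapsed, exclusions)``: collapsed has columns
    ``sample_id, group, assay, mean_ct``; exclusions has
    ``sample_id, assay, reason, ct_diff``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    retained: list[tuple] = []
    excluded: list[tuple] = []
    for (sample_id, assay), grp in records.groupby(["sample_id", "assay"], sort=False):
        cts = grp["ct"].to_numpy(dtype=float)
        group_label = grp["group"].iloc[0]
        if len(cts) != 2:
            excluded.append((sample_id, assay, "replicate_count", np.nan))
            continue
        if np.isnan(cts).any():
            excluded.append((sample_id, assay, "missing_ct", np.nan))
            continue
        diff = round(abs(cts[0] - cts[1]), _DIFF_DECIMALS)
        if diff >= threshold:
            excluded.append((sample_id, assay, "replicate_discordance", diff))
            continue
        retained.append((sample_id, group_label, assay, float(cts.mean())))
    collapsed = pd.DataFrame(retained, columns=["sample_id", "group", "assay", "mean_ct"])
    exclusions = pd.DataFrame(excluded, columns=EXCLUSION_COLUMNS)
    if len(exclusions):
        for row in exclusions.itertuples(index=False):
            logger.warning(
                "QC exclusion: sample=%s assay=%s reason=%s ct_diff=%s",
                row.sample_id, row.assay, row.reason, row.ct_diff,
            )
    return collapsed, exclusions


def normalize_to_spikein(
    collapsed: pd.DataFrame, spikein_assay: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample dCt = marker mean Ct − spike-in mean Ct.

    Samples with no retained spike-in pair are dropped wholesale for every
    marker and reported in the second return value (columns
    ``sample_id, assay, reason, ct_diff``, reason ``spikein_failed``).
    Lower dCt means higher expression.
    """
    if spikein_assay not in set(collapsed["assay"]):
        raise ConfigurationError(
            f"spike-in assay {spikein_assay!r} absent from the retained data"
        )
    spike = collapsed[collapsed["assay"] == spikein_assay].set_index("sample_id")["mean_ct"]
    markers = collapsed[collapsed["assay"] != spikein_assay].copy()
    has_spike = markers["sample_id"].isin(spike.index)
    dropped_rows = markers.loc[~has_spike]
    dropped = pd.DataFrame(
        {
            "sample_id": dropped_rows["sample_id"],
            "assay": dropped_rows["assay"],
            "reason": "spikein_failed",
            "ct_diff": np.nan,
        },
        columns=EXCLUSION_COLUMNS,
    ).astype({"ct_diff": float}).reset_index(drop=True)
    for sample_id in dropped["sample_id"].unique():
        logger.warning("sample %s dropped: spike-in pair failed QC", sample_id)
    markers = markers.loc[has_spike].copy()
    markers["delta_ct"] = (
        markers["mean_ct"].to_numpy() - spike.loc[markers["sample_id"]].to_numpy()
    )
    expr = markers.rename(columns={"assay": "marker"})[EXPR_COLUMNS].reset_index(drop=True)
    return expr, dropped


def _group_values(expr: pd.DataFrame, marker: str) -> tuple[np.ndarray, np.ndarray]:
    sub = expr[expr["marker"] == marker]
    case = sub.loc[sub["group"] == GROUP_CASE, "delta_ct"].to_numpy(dtype=float)
    control = sub.loc[sub["group"] == GROUP_CONTROL, "delta_ct"].to_numpy(dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise InsufficientDataError(
            f"marker {marker!r}: need at least one sample in each group "
            f"(case n={len(case)}, control n={len(control)})"
        )
    return case, control


def delta_delta_ct(expr: pd.DataFrame, marker: str) -> float:
    """ddCt = mean(dCt | case) − mean(dCt | control); negative ⇒ upregulated
    in cases."""
    case, control = _group_values(expr, marker)
    return float(case.mean() - control.mean())


def delta_delta_ct_interval(
    expr: pd.DataFrame, marker: str, level: float = 0.95
) -> tuple[float, float]:
    """Welch t confidence interval for ddCt (difference of group dCt means)."""
    case, control = _group_values(expr, marker)
    res = stats.ttest_ind(case, control, equal_var=False)
    ci = res.confidence_interval(confidence_level=level)
    return float(ci.low), float(ci.high)


def fold_display(rq: float) -> str:
    """Human-readable signed fold change: '4.0-fold up' / '3.1-fold down'."""
    if rq >= 1:
        return f"{rq:.1f}-fold up"
    return f"{1.0 / rq:.1f}-fold down"


def relative_quantity(
    expr: pd.DataFrame, marker: str, method: str = "pooled"
) -> MarkerComparison:
    """Relative quantity (RQ) of a marker in cases vs controls.

    ``pooled``: RQ = 2^(−ddCt) on the group-mean contrast (plain Livak).
    ``per_sample_mean``: each case sample is expressed as 2^(−(dCt_i −
    mean control dCt)) and the per-sample RQs are averaged; by Jensen's
    inequality this is ≥ the pooled RQ whenever case dCt values vary.
    """
    if method not in ("pooled", "per_sample_mean"):
        raise ValueError(f"unknown RQ method {method!r}")
    case, control = _group_values(expr, marker)
    ddct = float(case.mean() - control.mean())
    if method == "pooled":
        rq = float(2.0 ** (-ddct))
    else:
        rq = float(np.mean(2.0 ** (-(case - control.mean()))))
    return MarkerComparison(
        marker=marker,
        n_case=len(case),
        n_control=len(control),
        delta_delta_ct=ddct,
        rq=rq,
        fold_display=fold_display(rq),
        rq_method=method,
    )
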
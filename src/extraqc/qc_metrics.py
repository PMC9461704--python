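"""The three benchmark QC metrics: LOD coverage, replicate CV, and SOC.

For each tissue-by-protocol group the pipeline asks three questions of
decreasing granularity:

* **Coverage** — how many metabolites are reliably detectable?  A metabolite
  counts as *above LOD* in a group when at least ``min_above`` (default 2)
  of its replicates have a valid measurement exceeding the metabolite's
  limit of detection.
* **Repeatability** — how consistent are the replicate concentrations?  The
  coefficient of variation (sample sd / mean, raw concentration scale) is
  computed per metabolite; groups are summarised by the count of
  metabolites with CV below a threshold (default 30%) and by the
  median +- MAD of the CV distribution.
* **Global yield** — the sum of concentrations (SOC) per replicate, whose
  CV across replicates integrates the variability of the whole multi-step
  extraction.  SOCs are never pooled across unit bases (per-1e6-cells vs
  per-mg), mirroring the fact that tissue and cell-suspension inputs are
  not directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import QuantDataset, Status

__all__ = [
    "QCSummary",
    "UnitMixError",
    "above_lod_mask",
    "aggregate_lod_status",
    "lod_status_table",
    "count_above_lod",
    "summarize_above_lod",
    "coefficient_of_variation",
    "cv_table",
    "cv_summary",
    "cv_histogram",
    "sum_of_concentrations",
    "class_composition",
    "qc_summaries",
]

MAD_NORMAL_CONSTANT = 1.4826  # consistency constant for a normal distribution


class UnitMixError(ValueError):
    """Raised when a computation would pool concentrations across unit bases."""


@dataclass
class QCSummary:
    """Per tissue-by-protocol QC aggregate."""

    tissue: str
    protocol: str
    n_above_lod_total: int
    n_above_lod_by_class: dict[str, int]
    n_cv_below_threshold: int
    cv_median: float
    cv_mad: float
    soc_per_replicate: dict[int, float]
    soc_cv: float


def above_lod_mask(long: pd.DataFrame) -> pd.Series:
    """Per-record detectability: a valid measurement strictly above the LOD."""
    return (long["status"] == Status.VALID.value) & (
        long["concentration"] > long["lod_value"]
    )


def aggregate_lod_status(per_replicate: Sequence[bool], min_above: int = 2) -> str:
    """Aggregate per-replicate detectability to ``"above"`` / ``"below"``.

    A metabolite is *above LOD* in a replicate group when at least
    ``min_above`` replicates individually pass the per-record criterion.
    """
    flags = list(per_replicate)
    if not flags:
        raise ValueError("aggregate_lod_status: empty replicate group")
    return "above" if sum(bool(f) for f in flags) >= min_above else "below"


def lod_status_table(dataset: QuantDataset, min_above: int = 2) -> pd.DataFrame:
    """Aggregate LOD status per (tissue, protocol, metabolite).

    Returns columns ``tissue, protocol, metabolite_id, class, above`` with
    ``above`` boolean.
    """
    long = dataset.to_long()
    long = long.assign(_pass=above_lod_mask(long))
    grouped = (
        long.groupby(["tissue", "protocol", "metabolite_id", "class"], sort=True, observed=True)["_pass"]
        .sum()
        .reset_index()
    )
    grouped["above"] = grouped["_pass"] >= min_above
    return grouped.drop(columns="_pass")


def count_above_lod(dataset: QuantDataset, min_above: int = 2) -> pd.DataFrame:
    """Above-LOD metabolite counts per (tissue, protocol, class).

    The per-group totals are the stacked-bar heights of a coverage figure;
    classes with zero detectable metabolites in a group are omitted.
    """
    status = lod_status_table(dataset, min_above=min_above)
    counts = (
        status[status["above"]]
        .groupby(["tissue", "protocol", "class"], sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


def summarize_above_lod(counts: pd.DataFrame) -> pd.DataFrame:
    """Median and range of per-protocol above-LOD totals, per tissue."""
    totals = (
        counts.groupby(["tissue", "protocol"], observed=True)["count"].sum().reset_index()
    )
    out = (
        totals.groupby("tissue", observed=True)["count"]
        .agg(median="median", min="min", max="max")
        .reset_index()
    )
    return out


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV: sd (n-1 denominator) over mean, on the raw scale.

    Returns NaN (with a warning) for fewer than two values or a zero mean,
    where the ratio is undefined.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        warnings.warn("CV undefined for fewer than 2 values; returning NaN")
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        warnings.warn("CV undefined for zero mean; returning NaN")
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def cv_table(dataset: QuantDataset, min_above: int = 2) -> pd.DataFrame:
    """Per (tissue, protocol, metabolite) replicate CV, with LOD status.

    CVs are computed across all replicate concentrations of a metabolite in
    a group (censored values included at their exported numeric value);
    groups whose replicate vector has zero mean or fewer than two entries
    yield NaN.
    """
    long = dataset.to_long()
    long = long.assign(_pass=above_lod_mask(long))

    def _cv(x: pd.Series) -> float:
        arr = x.to_numpy(dtype=float)
        if arr.size < 2 or arr.mean() == 0:
            return float("nan")
        return float(arr.std(ddof=1) / arr.mean())

    grouped = long.groupby(["tissue", "protocol", "metabolite_id", "class"], sort=True, observed=True)
    out = grouped.agg(cv=("concentration", _cv), n_pass=("_pass", "sum")).reset_index()
    out["above_lod"] = out["n_pass"] >= min_above
    return out.drop(columns="n_pass")


def cv_summary(
    dataset: QuantDataset,
    threshold: float = 0.30,
    above_lod_only: bool = True,
    min_above: int = 2,
    mad_scale: float = MAD_NORMAL_CONSTANT,
) -> pd.DataFrame:
    """Group-level CV summary: count below threshold, median and MAD of CVs.

    ``above_lod_only`` restricts the summary (and the histogram companion)
    to metabolites above LOD in that group; including censored metabolites
    mostly populates the high-CV tail.  ``mad_scale`` defaults to the
    normal-consistency constant 1.4826 (R ``mad()`` convention); pass 1 for
    the plain median absolute deviation.
    """
    cvs = cv_table(dataset, min_above=min_above)
    if above_lod_only:
        cvs = cvs[cvs["above_lod"]]
    cvs = cvs.dropna(subset=["cv"])

    def _summary(group: pd.DataFrame) -> pd.Series:
        arr = group["cv"].to_numpy()
        med = float(np.median(arr)) if arr.size else float("nan")
        mad = float(mad_scale * np.median(np.abs(arr - med))) if arr.size else float("nan")
        return pd.Series(
            {
                "n_cv_below_threshold": int((arr < threshold).sum()),
                "cv_median": med,
                "cv_mad": mad,
                "n_metabolites": int(arr.size),
            }
        )

    out = (
        cvs.groupby(["tissue", "protocol"], sort=True, observed=True)[["cv"]]
        .apply(_summary)
        .reset_index()
    )
    out["n_cv_below_threshold"] = out["n_cv_below_threshold"].astype(int)
    out["n_metabolites"] = out["n_metabolites"].astype(int)
    return out


def cv_histogram(
    cv_long: pd.DataFrame, bin_width: float = 0.1, max_cv: float = 2.0
) -> pd.DataFrame:
    """Histogram of CVs per (tissue, protocol); last bin absorbs CV > max_cv."""
    edges = np.arange(0.0, max_cv + bin_width, bin_width)
    rows = []
    for (tissue, protocol), grp in cv_long.dropna(subset=["cv"]).groupby(
        ["tissue", "protocol"], observed=True
    ):
        clipped = np.minimum(grp["cv"].to_numpy(), max_cv - 1e-12)
        counts, _ = np.histogram(clipped, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {
                    "tissue": tissue,
                    "protocol": protocol,
                    "bin_low": float(lo),
                    "bin_high": float(hi),
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows)


def sum_of_concentrations(
    dataset: QuantDataset, include: str = "valid_only"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample SOC and its CV across replicates per (tissue, protocol).

    ``include='valid_only'`` (default) sums only measurements flagged valid;
    ``'all_measured'`` sums every exported numeric value except
    not-measured cells.  Returns ``(soc_per_sample, soc_cv_per_group)``;
    raises :class:`UnitMixError` if a replicate group mixes unit bases.
    """
    if include not in {"valid_only", "all_measured"}:
        raise ValueError(f"unknown include mode {include!r}")
    long = dataset.to_long()
    if include == "valid_only":
        keep = long["status"] == Status.VALID.value
    else:
        keep = long["status"] != Status.NOT_MEASURED.value
    long = long[keep]

    soc = (
        long.groupby(
            ["tissue", "protocol", "replicate_index", "sample_id", "unit_basis"],
            sort=True, observed=True,
        )["concentration"]
        .sum()
        .rename("soc")
        .reset_index()
    )

    mixed = soc.groupby(["tissue", "protocol"], observed=True)["unit_basis"].nunique()
    if (mixed > 1).any():
        bad = list(mixed[mixed > 1].index)
        raise UnitMixError(f"replicate groups mixing unit bases: {bad}")

    def _cv(x: pd.Series) -> float:
        arr = x.to_numpy(dtype=float)
        if arr.size < 2 or arr.mean() == 0:
            return float("nan")
        return float(arr.std(ddof=1) / arr.mean())

    soc_cv = (
        soc.groupby(["tissue", "protocol", "unit_basis"], sort=True, observed=True)["soc"]
        .agg(soc_cv=_cv, n_replicates="size")
        .reset_index()
    )
    return soc, soc_cv


def class_composition(metabolites: pd.DataFrame) -> pd.DataFrame:
    """Panel composition: count and percentage per metabolite class.

    Percentages are 100*count/total rounded half-up to one decimal; e.g.
    242 triacylglycerols of a 630-metabolite panel is 38.4%.
    """
    if len(metabolites) == 0:
        raise ValueError("class_composition: empty annotation set")
    counts = metabolites.groupby("class", observed=True).size().rename("count").reset_index()
    total = int(counts["count"].sum())
    counts["percent"] = [
        float(
            (Decimal(100 * int(c)) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for c in counts["count"]
    ]
    counts = counts.sort_values("count", ascending=False).reset_index(drop=True)
    return counts


def qc_summaries(
    dataset: QuantDataset,
    cv_threshold: float = 0.30,
    min_above: int = 2,
    soc_include: str = "valid_only",
) -> list[QCSummary]:
    """Assemble one :class:`QCSummary` per tissue-by-protocol group."""
    counts = count_above_lod(dataset, min_above=min_above)
    cv_sum = cv_summary(dataset, threshold=cv_threshold, min_above=min_above)
    soc, soc_cv = sum_of_concentrations(dataset, include=soc_include)

    summaries: list[QCSummary] = []
    groups = dataset.samples[["tissue", "protocol"]].drop_duplicates()
    for _, (tissue, protocol) in groups.iterrows():
        sel = (counts["tissue"] == tissue) & (counts["protocol"] == protocol)
        by_class = dict(zip(counts.loc[sel, "class"], counts.loc[sel, "count"].astype(int)))
        sel_cv = (cv_sum["tissue"] == tissue) & (cv_sum["protocol"] == protocol)
        row = cv_sum.loc[sel_cv]
        sel_soc = (soc["tissue"] == tissue) & (soc["protocol"] == protocol)
        per_rep = dict(
            zip(soc.loc[sel_soc, "replicate_index"].astype(int), soc.loc[sel_soc, "soc"])
        )
        sel_scv = (soc_cv["tissue"] == tissue) & (soc_cv["protocol"] == protocol)
        summaries.append(
            QCSummary(
                tissue=tissue,
                protocol=protocol,
                n_above_lod_total=int(sum(by_class.values())),
                n_above_lod_by_class=by_class,
                n_cv_below_threshold=int(row["n_cv_below_threshold"].iloc[0]) if len(row) else 0,
                cv_median=float(row["cv_median"].iloc[0]) if len(row) else float("nan"),
                cv_mad=float(row["cv_mad"].iloc[0]) if len(row) else float("nan"),
                soc_per_replicate=per_rep,
                soc_cv=float(soc_cv.loc[sel_scv, "soc_cv"].iloc[0]) if sel_scv.any() else float("nan"),
            )
        )
    return summaries
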
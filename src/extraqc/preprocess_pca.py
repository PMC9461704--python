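"""Preprocessing chain, PCA, and component-factor association.

The fixed preprocessing order is: drop metabolites below LOD in every
group -> replace zeros by 120% of the smallest positive value per
metabolite -> log2 -> Pareto scaling (mean-centre, divide by the square
root of the sample standard deviation).  Pareto scaling is the usual
metabolomics compromise between no scaling (large-concentration lipids
dominate) and unit-variance scaling (noise near the LOD is inflated).

PCA is a plain SVD of the preprocessed matrix with a deterministic sign
convention (the largest-magnitude loading of each component is positive).
Components are associated with experimental factors — tissue, protocol,
and binary solvent-content indicators — by Kruskal-Wallis tests with
Benjamini-Hochberg correction across the whole component-by-factor table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_model import ProtocolDescriptor, QuantDataset, Status
from .qc_metrics import lod_status_table

__all__ = [
    "PCAOutput",
    "EmptyMatrixError",
    "build_matrix",
    "filter_all_below_lod",
    "impute_zeros",
    "log2_transform",
    "pareto_scale",
    "preprocess",
    "run_pca",
    "top_loadings",
    "kruskal_wallis",
    "bh_adjust",
    "associate_components",
]


class EmptyMatrixError(ValueError):
    """Filtering removed every metabolite column."""


@dataclass
class PCAOutput:
    """Scores, loadings, explained-variance fractions and factor associations."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components
    explained_variance_fraction: pd.Series  # per component, sums to <= 1
    assoc: pd.DataFrame | None = None


def build_matrix(dataset: QuantDataset, censored_to_zero: bool = True) -> pd.DataFrame:
    """Samples-by-metabolites concentration matrix from a dataset.

    With ``censored_to_zero`` (default) every non-valid measurement is set
    to 0, reproducing exports that blank censored cells; the zeros are then
    handled by :func:`impute_zeros`.
    """
    rec = dataset.records.copy()
    if censored_to_zero:
        rec.loc[rec["status"] != Status.VALID.value, "concentration"] = 0.0
    matrix = rec.pivot(index="sample_id", columns="metabolite_id", values="concentration")
    matrix = matrix.loc[
        dataset.samples["sample_id"], dataset.metabolites["metabolite_id"]
    ]
    return matrix


def filter_all_below_lod(matrix: pd.DataFrame, lod_status: pd.DataFrame) -> pd.DataFrame:
    """Drop metabolites that are below LOD in every group present.

    ``lod_status`` is the table from :func:`extraqc.qc_metrics.lod_status_table`
    (columns ``tissue, protocol, metabolite_id, above``).  A metabolite is
    kept iff it is above LOD in at least one group.
    """
    status = lod_status[lod_status["metabolite_id"].isin(matrix.columns)]
    above_any = status.groupby("metabolite_id", observed=True)["above"].any()
    keep = [m for m in matrix.columns if bool(above_any.get(m, False))]
    if not keep:
        raise EmptyMatrixError("all metabolites are below LOD in every group")
    return matrix[keep]


def impute_zeros(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros by 120% of the column's smallest positive value."""
    out = matrix.copy().astype(float)
    for col in out.columns:
        vals = out[col].to_numpy()
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError(
                f"column {col!r} has no positive values; filter all-below-LOD metabolites first"
            )
        vals = np.where(vals == 0, 1.2 * positive.min(), vals)
        out[col] = vals
    return out


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; every entry must be positive (impute first)."""
    arr = matrix.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("log2_transform requires strictly positive entries")
    return pd.DataFrame(np.log2(arr), index=matrix.index, columns=matrix.columns)


def pareto_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-centre each column and divide by sqrt(sample sd).

    Constant columns scale to all zeros (with a warning) rather than
    raising, so fully uninformative metabolites degrade gracefully.
    """
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    centered = arr - mean
    out = np.zeros_like(centered)
    nonconst = sd > 0
    if (~nonconst).any():
        cols = list(matrix.columns[~nonconst])
        warnings.warn(f"constant columns scaled to zeros: {cols}")
    out[:, nonconst] = centered[:, nonconst] / np.sqrt(sd[nonconst])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess(dataset: QuantDataset, min_above: int = 2) -> pd.DataFrame:
    """Full chain: build -> LOD filter -> impute -> log2 -> Pareto."""
    matrix = build_matrix(dataset)
    matrix = filter_all_below_lod(matrix, lod_status_table(dataset, min_above=min_above))
    matrix = impute_zeros(matrix)
    matrix = log2_transform(matrix)
    return pareto_scale(matrix)


def run_pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAOutput:
    """PCA by SVD of the (already centred and scaled) matrix.

    Components are ordered by decreasing explained variance; loadings are
    unit-norm right singular vectors.  Sign convention: the entry of
    largest magnitude in each loading vector is positive, which makes
    results reproducible across linear-algebra backends and sample
    orderings.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_rank = min(matrix.shape[0] - 1, matrix.shape[1])
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds usable rank {max_rank}")

    X = matrix.to_numpy(dtype=float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    for j in range(min(n_components, Vt.shape[0])):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1

    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=matrix.index, columns=comps
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=matrix.columns, columns=comps)
    evf = pd.Series(
        (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components),
        index=comps,
        name="explained_variance_fraction",
    )
    return PCAOutput(scores=scores, loadings=loadings, explained_variance_fraction=evf)


def top_loadings(output: PCAOutput, component: str, k: int = 15) -> pd.DataFrame:
    """The k metabolites with largest |loading| on a component, descending.

    Sign is retained; ties are broken by metabolite id (lexicographic).
    """
    if component not in output.loadings.columns:
        raise KeyError(f"unknown component {component!r}")
    col = output.loadings[component]
    order = sorted(col.index, key=lambda m: (-abs(col[m]), str(m)))
    top = order[:k]
    return pd.DataFrame(
        {"metabolite_id": top, "loading": [float(col[m]) for m in top]}
    )


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis rank test: tie-corrected H and a chi-squared p-value.

    ``H = 12/(N(N+1)) * sum_j R_j^2/n_j - 3(N+1)`` on mid-ranks, divided by
    the tie-correction factor ``1 - sum(t^3-t)/(N^3-N)``; p from the
    chi-squared distribution with (k-1) degrees of freedom.  When every
    observation is identical the statistic is defined as 0 (p = 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    if any((groups == g).sum() == 0 for g in labels):  # pragma: no cover - unreachable
        raise ValueError("empty group")
    n = values.size
    ranks = sps.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        (ranks[groups == g].sum()) ** 2 / (groups == g).sum() for g in labels
    ) - 3.0 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0:  # all observations identical
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, len(labels) - 1))
    return float(h), p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _solvent_indicators(
    samples: pd.DataFrame, protocols: Mapping[str, ProtocolDescriptor]
) -> pd.DataFrame:
    tags = sorted({s for p in protocols.values() for s in p.solvents})
    data = {}
    for tag in tags:
        with_tag = {pid for pid, p in protocols.items() if tag in p.solvents}
        data[f"solvent_{tag}"] = samples["protocol"].isin(with_tag).map({True: "yes", False: "no"})
    return pd.DataFrame(data, index=samples.index)


def associate_components(
    output: PCAOutput,
    samples: pd.DataFrame,
    protocols: Mapping[str, ProtocolDescriptor] | None = None,
    factors: Sequence[str] | None = None,
    alpha: float = 0.05,
    max_components: int = 10,
) -> pd.DataFrame:
    """Kruskal-Wallis association of each component with each factor.

    Factors default to tissue, protocol, and one binary contains/doesn't
    indicator per solvent tag (when protocol descriptors are supplied).
    BH correction is applied jointly across the whole component-by-factor
    table, restricted to the first ``max_components`` components;
    ``significant`` means adjusted p < alpha.  Constant factors are skipped
    with a warning.
    """
    meta = samples.set_index("sample_id").loc[output.scores.index].reset_index()
    frame = meta[["tissue", "protocol"]].copy()
    if protocols:
        frame = pd.concat([frame, _solvent_indicators(meta, protocols)], axis=1)
    if factors is not None:
        frame = frame[[f for f in frame.columns if f in set(factors)]]

    comps = list(output.scores.columns[:max_components])
    rows = []
    for factor in frame.columns:
        labels = frame[factor].to_numpy()
        if len(pd.unique(labels)) < 2:
            warnings.warn(f"factor {factor!r} is constant; skipped")
            continue
        for comp in comps:
            h, p = kruskal_wallis(output.scores[comp].to_numpy(), labels)
            rows.append({"component": comp, "factor": factor, "statistic": h, "p_value": p})
    assoc = pd.DataFrame(rows, columns=["component", "factor", "statistic", "p_value"])
    if len(assoc):
        assoc["p_adjusted"] = bh_adjust(assoc["p_value"].to_numpy())
        assoc["significant"] = assoc["p_adjusted"] < alpha
    else:
        assoc["p_adjusted"] = []
        assoc["significant"] = []
    output.assoc = assoc
    return assoc
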
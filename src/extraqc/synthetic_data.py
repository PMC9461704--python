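"""Benchmark-shaped synthetic datasets with known ground truth.

The generator emulates the design of an extraction-protocol benchmark:
four sample types (one per-mg tissue, three cell suspensions), ten
extraction protocols distinguished by their solvent mixtures, three
replicates each, and a 630-metabolite targeted panel spanning 23 classes
dominated by triacylglycerols.

The concentration model is log-normal, matching the log2 analysis scale
and the orders-of-magnitude spread of real targeted panels:

    log2 C(m, t, p, r) = mu_m + tau_{m,t} + pi_{p, class(m)} + eps

with per-metabolite baselines ``mu_m`` uniform over a configurable range,
tissue effects ``tau`` normal with sd ``tissue_effect_sd`` (drawn once per
metabolite-tissue pair), deterministic class-specific protocol effects
``pi``, and replicate noise ``eps``.  Each metabolite's LOD is set to the
exact analytic ``lod_quantile`` of its marginal concentration distribution
(a mixture of normals over protocols on the log2 scale), so the expected
censoring fraction equals ``lod_quantile``.  Measurements below the LOD
keep their true value but are flagged ``below_lod``, exercising the
parse-time decision that censoring is applied downstream, never at load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_model import (
    ProtocolDescriptor,
    QuantDataset,
    Status,
    UnitBasis,
    load_class_vocabulary,
)

__all__ = [
    "SyntheticSpec",
    "default_protocols",
    "default_protocol_effects",
    "generate_kit_annotations",
    "generate_dataset",
]

LIPID_CLASSES = (
    "Acylcarnitines",
    "Ceramides",
    "Cholesteryl Esters",
    "Diacylglycerols",
    "Dihydroceramides",
    "Glycerophospholipids",
    "Glycosylceramides",
    "Sphingomyelins",
    "Triacylglycerols",
)


def default_protocols() -> dict[str, ProtocolDescriptor]:
    """The ten benchmark extraction protocols with their solvent tags."""
    defs = [
        ("P01", "100/30 IPA", {"IPA", "H2O"}, None),
        ("P02", "100 IPA", {"IPA"}, None),
        ("P03", "MeOH/ACN/H2O", {"MeOH", "ACN", "H2O"}, None),
        ("P04", "MeOH/ACN", {"MeOH", "ACN"}, None),
        ("P05", "EtOH/PP", {"EtOH", "PP"}, None),
        ("P06", "100/20 MeOH", {"MeOH", "H2O"}, None),
        ("P07", "75 EtOH/MTBE A", {"EtOH", "MTBE"}, 120.0),
        ("P08", "75 EtOH/MTBE B", {"EtOH", "MTBE"}, 60.0),
        ("P09", "MeOH/ACN/H2O bi", {"MeOH", "ACN", "H2O"}, None),
        ("P10", "MeOH/ChCl3", {"MeOH", "ChCl3"}, None),
    ]
    return {
        pid: ProtocolDescriptor(pid, label, frozenset(solv), vol)
        for pid, label, solv, vol in defs
    }


def default_protocol_effects(
    protocols: Mapping[str, ProtocolDescriptor],
    classes: Sequence[str],
    lipid_boost: float = 1.0,
    methanol_penalty: float = 0.75,
) -> dict[tuple[str, str], float]:
    """Solvent-driven class-specific log2 effects.

    Apolar-solvent protocols (IPA or MTBE) gain ``lipid_boost`` log2 units
    on lipid classes; methanol-containing protocols lose
    ``methanol_penalty`` on lipids — a caricature of solvent polarity
    determining lipid extraction efficiency.  Small-molecule classes are
    solvent-insensitive (effect 0).
    """
    effects: dict[tuple[str, str], float] = {}
    for pid, proto in protocols.items():
        for cls in classes:
            eff = 0.0
            if cls in LIPID_CLASSES:
                if proto.solvents & {"IPA", "MTBE"}:
                    eff += lipid_boost
                if "MeOH" in proto.solvents:
                    eff -= methanol_penalty
            effects[(pid, cls)] = eff
    return effects


def _default_proportions() -> dict[str, float]:
    vocab = load_class_vocabulary()
    total = sum(vocab.default_counts.values())
    return {c: n / total for c, n in vocab.default_counts.items()}


@dataclass
class SyntheticSpec:
    """Design and effect-size description of one synthetic benchmark.

    Defaults mirror the benchmark study shape: 630 metabolites in 23
    classes, 4 tissues x 10 protocols x 3 replicates, tissue as the
    dominant variance factor (sd 2 log2 units), solvent-driven lipid
    effects of about 1 log2 unit, replicate noise 0.5 log2 units, and 25%
    of measurements censored at the LOD.
    """

    n_metabolites: int = 630
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    tissues: tuple[str, ...] = ("liver", "bone_marrow", "HEK", "HL60")
    protocols: dict[str, ProtocolDescriptor] = field(default_factory=default_protocols)
    n_replicates: int = 3
    baseline_log2_mean_range: tuple[float, float] = (-4.0, 14.0)
    tissue_effect_sd: float = 2.0
    protocol_effect: dict[tuple[str, str], float] | None = None
    replicate_sd: float = 0.5
    lod_quantile: float = 0.25
    per_mg_tissues: tuple[str, ...] = ("liver",)
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.tissue_effect_sd < 0 or self.replicate_sd < 0:
            raise ValueError("effect standard deviations must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not 0.0 <= self.lod_quantile <= 1.0:
            raise ValueError("lod_quantile must lie in [0, 1]")
        if self.protocol_effect is None:
            self.protocol_effect = default_protocol_effects(
                self.protocols, tuple(self.class_proportions)
            )


def _class_counts(spec: SyntheticSpec) -> dict[str, int]:
    """Largest-remainder apportionment of n_metabolites across classes."""
    items = list(spec.class_proportions.items())
    raw = [spec.n_metabolites * frac for _, frac in items]
    counts = [int(np.floor(x)) for x in raw]
    shortfall = spec.n_metabolites - sum(counts)
    remainders = sorted(
        range(len(items)), key=lambda i: (-(raw[i] - counts[i]), items[i][0])
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return {cls: c for (cls, _), c in zip(items, counts) if c > 0}


def _metabolite_params(spec: SyntheticSpec) -> pd.DataFrame:
    """Deterministic per-metabolite class, baseline mu, and analytic LOD."""
    counts = _class_counts(spec)
    classes = [cls for cls, c in counts.items() for _ in range(c)]
    ids = [f"M{i + 1:04d}" for i in range(spec.n_metabolites)]

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    lo, hi = spec.baseline_log2_mean_range
    mu = rng.uniform(lo, hi, size=spec.n_metabolites)

    sigma = float(np.hypot(spec.tissue_effect_sd, spec.replicate_sd))
    pids = list(spec.protocols)
    lod = np.zeros(spec.n_metabolites)
    if spec.lod_quantile > 0:
        for i, (m_mu, cls) in enumerate(zip(mu, classes)):
            offsets = np.array([spec.protocol_effect[(p, cls)] for p in pids]) + m_mu
            lod[i] = 2.0 ** _mixture_quantile(offsets, sigma, spec.lod_quantile)
    return pd.DataFrame(
        {"metabolite_id": ids, "class": classes, "mu": mu, "lod_value": lod}
    )


def _mixture_quantile(means: np.ndarray, sigma: float, q: float) -> float:
    """Quantile of an equal-weight normal mixture (point masses if sigma=0)."""
    if sigma == 0:
        return float(np.quantile(means, q, method="inverted_cdf"))
    lo = means.min() - 10 * sigma
    hi = means.max() + 10 * sigma
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if norm.cdf((mid - means) / sigma).mean() < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_kit_annotations(spec: SyntheticSpec) -> pd.DataFrame:
    """Metabolite annotation table (id, class, LOD) for the synthetic panel.

    Class counts follow largest-remainder rounding of the spec proportions
    (so they conserve the total), and each LOD is placed at the
    ``lod_quantile`` of that metabolite's marginal concentration
    distribution.
    """
    return _metabolite_params(spec)[["metabolite_id", "class", "lod_value"]]


def generate_dataset(spec: SyntheticSpec) -> tuple[QuantDataset, pd.DataFrame]:
    """Simulate a full benchmark dataset plus its ground-truth effect table.

    Returns ``(dataset, truth)`` where ``truth`` has one row per
    (metabolite, protocol) with the true log2 protocol effect and a flag
    marking the protocols attaining the per-metabolite maximum (the true
    optimal set, identical across tissues since protocol effects are
    class- but not tissue-specific).  Deterministic given ``spec.seed``.
    """
    params = _metabolite_params(spec)
    pids = list(spec.protocols)
    n_m, n_t, n_p, n_r = (
        spec.n_metabolites,
        len(spec.tissues),
        len(pids),
        spec.n_replicates,
    )

    rng_tau = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rng_eps = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    tau = rng_tau.normal(0.0, spec.tissue_effect_sd, size=(n_m, n_t))
    eps = rng_eps.normal(0.0, spec.replicate_sd, size=(n_m, n_t, n_p, n_r))

    pi = np.array(
        [[spec.protocol_effect[(p, cls)] for p in pids] for cls in params["class"]]
    )  # n_m x n_p

    log2c = (
        params["mu"].to_numpy()[:, None, None, None]
        + tau[:, :, None, None]
        + pi[:, None, :, None]
        + eps
    )
    conc = 2.0**log2c
    lod = params["lod_value"].to_numpy()
    below = conc < lod[:, None, None, None]

    sample_ids = np.array(
        [
            f"{t}_{p}_r{r + 1}"
            for t in spec.tissues
            for p in pids
            for r in range(n_r)
        ]
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": [t for t in spec.tissues for _ in range(n_p * n_r)],
            "protocol": [p for _ in spec.tissues for p in pids for _ in range(n_r)],
            "replicate_index": [r + 1 for _ in spec.tissues for _ in pids for r in range(n_r)],
        }
    )
    samples["unit_basis"] = [
        UnitBasis.PER_MG.value if t in spec.per_mg_tissues else UnitBasis.PER_1E6_CELLS.value
        for t in samples["tissue"]
    ]

    # records in sample-major order: (tissue, protocol, replicate) x metabolite
    conc_flat = conc.transpose(1, 2, 3, 0).reshape(-1)
    below_flat = below.transpose(1, 2, 3, 0).reshape(-1)
    records = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_m),
            "metabolite_id": np.tile(params["metabolite_id"].to_numpy(), n_t * n_p * n_r),
            "concentration": conc_flat,
            "status": np.where(below_flat, Status.BELOW_LOD.value, Status.VALID.value),
        }
    )

    dataset = QuantDataset(
        records=records,
        metabolites=params[["metabolite_id", "class", "lod_value"]].copy(),
        samples=samples,
        protocols=dict(spec.protocols),
    )

    best = pi.max(axis=1)
    truth = pd.DataFrame(
        {
            "metabolite_id": np.repeat(params["metabolite_id"].to_numpy(), n_p),
            "class": np.repeat(params["class"].to_numpy(), n_p),
            "protocol": np.tile(np.array(pids), n_m),
            "true_log2_effect": pi.reshape(-1),
            "is_true_optimal": (pi == best[:, None]).reshape(-1),
        }
    )
    return dataset, truth
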
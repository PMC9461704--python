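"""Domain types, validation and unit semantics for extraction-benchmark data.

A benchmark dataset pairs a samples-by-metabolites concentration matrix
(exported by targeted-quantification software such as MetIDQ) with three
annotation layers: per-cell measurement status flags, per-metabolite class
and limit-of-detection (LOD) values, and per-sample design metadata (tissue,
extraction protocol, replicate index, unit basis).  :class:`QuantDataset`
bundles these as tidy :class:`pandas.DataFrame` tables and is the exchange
object every downstream stage consumes.

Concentrations are reported either per million cells (cell suspensions) or
per milligram of input tissue; the unit basis travels as metadata and is
never converted implicitly.  :func:`mass_to_cell_equivalents` is the one
sanctioned bridge between the two bases: it converts a tissue input mass to
a cell-count equivalent via a cellularity figure (cells per gram), e.g.
hepatocellularity for liver.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Status",
    "UnitBasis",
    "DEFAULT_STATUS_FLAGS",
    "ProtocolDescriptor",
    "TissueCellularity",
    "QuantDataset",
    "Violation",
    "ClassVocabulary",
    "load_class_vocabulary",
    "apply_class_merge",
    "validate_dataset",
    "mass_to_cell_equivalents",
]


class Status(str, enum.Enum):
    """Per-measurement status flag as emitted by the quantification export."""

    VALID = "valid"
    BELOW_LOD = "below_lod"
    BELOW_LLOQ = "below_lloq"
    ABOVE_ULOQ = "above_uloq"
    INVALID = "invalid"
    NOT_MEASURED = "not_measured"


class UnitBasis(str, enum.Enum):
    PER_1E6_CELLS = "per_1e6_cells"
    PER_MG = "per_mg"


#: Default mapping from raw export flag spellings to the status enum.  Flag
#: spellings vary across software versions; unknown flags are a validation
#: violation rather than a silent pass-through.
DEFAULT_STATUS_FLAGS: dict[str, Status] = {
    "Valid": Status.VALID,
    "valid": Status.VALID,
    "< LOD": Status.BELOW_LOD,
    "<LOD": Status.BELOW_LOD,
    "below_lod": Status.BELOW_LOD,
    "< LLOQ": Status.BELOW_LLOQ,
    "<LLOQ": Status.BELOW_LLOQ,
    "below_lloq": Status.BELOW_LLOQ,
    "> ULOQ": Status.ABOVE_ULOQ,
    ">ULOQ": Status.ABOVE_ULOQ,
    "above_uloq": Status.ABOVE_ULOQ,
    "Invalid": Status.INVALID,
    "invalid": Status.INVALID,
    "": Status.NOT_MEASURED,
    "not_measured": Status.NOT_MEASURED,
}

RECORD_COLUMNS = ("sample_id", "metabolite_id", "concentration", "status")
METABOLITE_COLUMNS = ("metabolite_id", "class", "lod_value")
SAMPLE_COLUMNS = ("sample_id", "tissue", "protocol", "replicate_index", "unit_basis")


@dataclass(frozen=True)
class ProtocolDescriptor:
    """An extraction protocol: label plus the solvent tags it uses.

    Solvent tags (e.g. IPA, MTBE, ACN, EtOH, MeOH, ChCl3, H2O, PP) drive the
    solvent-association analysis; ``resolve_volume_ul`` distinguishes
    protocol variants that differ only in reconstitution volume.
    """

    protocol_id: str
    label: str
    solvents: frozenset[str]
    resolve_volume_ul: float | None = None

    def __post_init__(self) -> None:
        if not self.solvents:
            raise ValueError(f"protocol {self.protocol_id!r}: solvents must be non-empty")
        object.__setattr__(self, "solvents", frozenset(self.solvents))


@dataclass(frozen=True)
class TissueCellularity:
    """Cells per gram of tissue, as a published range and/or mean +- sd."""

    cells_per_gram_low: float
    cells_per_gram_high: float
    cells_per_gram_mean: float
    cells_per_gram_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.cells_per_gram_low > self.cells_per_gram_high:
            raise ValueError("cellularity: low bound exceeds high bound")
        if min(self.cells_per_gram_low, self.cells_per_gram_mean) <= 0:
            raise ValueError("cellularity values must be positive")
        if self.cells_per_gram_sd < 0:
            raise ValueError("cellularity sd must be non-negative")


@dataclass(frozen=True)
class Violation:
    """One validation failure: the invariant broken and the offending ids."""

    invariant: str
    offenders: tuple[str, ...]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.invariant}] {self.message}"


@dataclass
class QuantDataset:
    """Measurement records joined to metabolite, sample and protocol metadata.

    Parameters
    ----------
    records
        One row per (sample, metabolite) measurement with columns
        ``sample_id, metabolite_id, concentration, status``.  Concentrations
        flagged non-valid keep their exported numeric value (possibly 0);
        censoring decisions are made downstream, per analysis stage.
    metabolites
        ``metabolite_id, class, lod_value`` (LOD in the metabolite's
        concentration units).
    samples
        ``sample_id, tissue, protocol, replicate_index, unit_basis``.
    protocols
        Optional mapping ``protocol label -> ProtocolDescriptor``; required
        only for solvent-level analyses.
    """

    records: pd.DataFrame
    metabolites: pd.DataFrame
    samples: pd.DataFrame
    protocols: dict[str, ProtocolDescriptor] | None = None

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.metabolites = self.metabolites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        for frame, cols, name in (
            (self.records, RECORD_COLUMNS, "records"),
            (self.metabolites, METABOLITE_COLUMNS, "metabolites"),
            (self.samples, SAMPLE_COLUMNS, "samples"),
        ):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"{name} table missing columns: {sorted(missing)}")

    # -- convenience -------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Records joined to both annotation tables (one tidy row per cell)."""
        out = self.records.merge(self.samples, on="sample_id", how="left")
        out = out.merge(self.metabolites, on="metabolite_id", how="left")
        return out

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.samples["tissue"]))

    @property
    def protocol_labels(self) -> list[str]:
        return list(pd.unique(self.samples["protocol"]))

    def equals(self, other: "QuantDataset") -> bool:
        """Order-insensitive equality of records and annotations."""

        def norm(df: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
            return df.sort_values(list(keys)).reset_index(drop=True)

        try:
            pd.testing.assert_frame_equal(
                norm(self.records, ["sample_id", "metabolite_id"]),
                norm(other.records, ["sample_id", "metabolite_id"]),
                check_like=True,
            )
            pd.testing.assert_frame_equal(
                norm(self.metabolites, ["metabolite_id"]),
                norm(other.metabolites, ["metabolite_id"]),
                check_like=True,
            )
            pd.testing.assert_frame_equal(
                norm(self.samples, ["sample_id"]),
                norm(other.samples, ["sample_id"]),
                check_like=True,
            )
        except AssertionError:
            return False
        return True


@dataclass(frozen=True)
class ClassVocabulary:
    """Controlled metabolite-class vocabulary plus the raw->merged class map."""

    classes: tuple[str, ...]
    default_counts: Mapping[str, int]
    class_merge: Mapping[str, str] = field(default_factory=dict)


def load_class_vocabulary(path: str | None = None) -> ClassVocabulary:
    """Load the class vocabulary from YAML (packaged default if no path).

    The packaged default describes a 630-metabolite targeted panel with 14
    small-molecule and 9 lipid classes, including the vendor-side merges of
    lyso-/phosphatidylcholines into glycerophospholipids and the three
    glycosylated ceramide classes into glycosylceramides.
    """
    if path is None:
        text = resources.files("extraqc.data").joinpath("quant500_classes.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    counts: dict[str, int] = {}
    counts.update(raw.get("small_molecule_classes", {}))
    counts.update(raw.get("lipid_classes", {}))
    return ClassVocabulary(
        classes=tuple(counts),
        default_counts=counts,
        class_merge=dict(raw.get("class_merge", {})),
    )


def apply_class_merge(
    metabolites: pd.DataFrame, merge: Mapping[str, str]
) -> pd.DataFrame:
    """Replace raw class labels with their merged targets (e.g. LPC+PC -> GP)."""
    out = metabolites.copy()
    out["class"] = out["class"].map(lambda c: merge.get(c, c))
    return out


def validate_dataset(
    dataset: QuantDataset, vocabulary: ClassVocabulary | None = None
) -> list[Violation]:
    """Check every dataset invariant; return an empty list iff all hold.

    Reported invariants: referential integrity of sample/metabolite ids,
    uniqueness of (sample_id, metabolite_id), finite non-negative
    concentrations, known status values, non-negative LODs, class membership
    in the vocabulary (when one is given), positive replicate indices, a
    known unit basis, and a single unit basis per tissue.
    """
    v: list[Violation] = []
    rec, met, sam = dataset.records, dataset.metabolites, dataset.samples

    dup = rec.duplicated(subset=["sample_id", "metabolite_id"])
    if dup.any():
        pairs = rec.loc[dup, ["sample_id", "metabolite_id"]].astype(str).agg("/".join, axis=1)
        v.append(Violation("unique_measurement", tuple(pairs), "duplicate (sample, metabolite) pairs"))

    known_samples = set(sam["sample_id"])
    known_mets = set(met["metabolite_id"])
    bad = sorted(set(rec["sample_id"]) - known_samples)
    if bad:
        v.append(Violation("referential_integrity", tuple(bad), f"records reference unknown sample_id: {bad}"))
    bad = sorted(set(rec["metabolite_id"]) - known_mets)
    if bad:
        v.append(Violation("referential_integrity", tuple(bad), f"records reference unknown metabolite_id: {bad}"))

    conc = pd.to_numeric(rec["concentration"], errors="coerce")
    mask = ~np.isfinite(conc) | (conc < 0)
    if mask.any():
        ids = tuple(rec.loc[mask, "sample_id"].astype(str))
        v.append(Violation("concentration_non_negative_finite", ids, "negative or non-finite concentrations"))

    valid_status = {s.value for s in Status}
    mask = ~rec["status"].isin(valid_status)
    if mask.any():
        flags = tuple(sorted(set(rec.loc[mask, "status"].astype(str))))
        v.append(Violation("known_status", flags, f"unknown status values: {list(flags)}"))

    lod = pd.to_numeric(met["lod_value"], errors="coerce")
    mask = ~np.isfinite(lod) | (lod < 0)
    if mask.any():
        ids = tuple(met.loc[mask, "metabolite_id"].astype(str))
        v.append(Violation("lod_non_negative", ids, "negative or non-finite LOD values"))

    if vocabulary is not None:
        mask = ~met["class"].isin(vocabulary.classes)
        if mask.any():
            labels = tuple(sorted(set(met.loc[mask, "class"].astype(str))))
            v.append(Violation("class_vocabulary", labels, f"classes outside vocabulary: {list(labels)}"))

    rep = pd.to_numeric(sam["replicate_index"], errors="coerce")
    mask = ~np.isfinite(rep) | (rep < 1) | (rep != rep.round())
    if mask.any():
        ids = tuple(sam.loc[mask, "sample_id"].astype(str))
        v.append(Violation("replicate_index_positive", ids, "replicate_index must be a positive integer"))

    valid_units = {u.value for u in UnitBasis}
    mask = ~sam["unit_basis"].isin(valid_units)
    if mask.any():
        ids = tuple(sam.loc[mask, "sample_id"].astype(str))
        v.append(Violation("known_unit_basis", ids, "unknown unit_basis values"))

    per_tissue = sam.groupby("tissue")["unit_basis"].nunique()
    mixed = per_tissue[per_tissue > 1]
    if len(mixed):
        v.append(
            Violation(
                "unit_basis_constant_per_tissue",
                tuple(mixed.index.astype(str)),
                f"tissues with mixed unit bases: {list(mixed.index)}",
            )
        )

    if dataset.protocols is not None:
        bad = sorted(set(sam["protocol"]) - set(dataset.protocols))
        if bad:
            v.append(Violation("referential_integrity", tuple(bad), f"samples reference unknown protocols: {bad}"))

    return v


def mass_to_cell_equivalents(
    mass_mg: float,
    cellularity_cells_per_g: float,
    cellularity_sd: float | None = None,
) -> float | tuple[float, float]:
    """Convert a tissue input mass to its cell-count equivalent.

    ``cells = mass_mg * 1e-3 g/mg * cellularity_cells_per_g``.  With a
    hepatocellularity of 139e6 cells/g, 30 mg of liver corresponds to
    4.17e6 cells — directly comparable to the 3e6-cell inputs used for cell
    suspensions.

    Parameters
    ----------
    mass_mg
        Input mass in milligrams (>= 0).
    cellularity_cells_per_g
        Cells per gram of tissue (>= 0).
    cellularity_sd
        Optional standard deviation of the cellularity; when given, the
        uncertainty is propagated linearly and ``(value, sd)`` is returned.
    """
    if mass_mg < 0 or cellularity_cells_per_g < 0:
        raise ValueError("mass and cellularity must be non-negative")
    value = mass_mg * 1e-3 * cellularity_cells_per_g
    if cellularity_sd is None:
        return value
    if cellularity_sd < 0:
        raise ValueError("cellularity sd must be non-negative")
    return value, mass_mg * 1e-3 * cellularity_sd
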
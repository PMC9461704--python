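import numpy as np
import pandas as pd
import pytest

from extraqc.core_model import ProtocolDescriptor, QuantDataset
from extraqc.synthetic_data import SyntheticSpec, generate_dataset


def make_dataset(records, metabolites, samples, protocols=None) -> QuantDataset:
    return QuantDataset(
        records=pd.DataFrame(records),
        metabolites=pd.DataFrame(metabolites),
        samples=pd.DataFrame(samples),
        protocols=protocols,
    )


@pytest.fixture
def tiny_dataset() -> QuantDataset:
    """2 samples x 2 metabolites, fully valid, hand-checkable numbers."""
    return make_dataset(
        records=[
            {"sample_id": "s1", "metabolite_id": "m1", "concentration": 2.0, "status": "valid"},
            {"sample_id": "s1", "metabolite_id": "m2", "concentration": 4.0, "status": "valid"},
            {"sample_id": "s2", "metabolite_id": "m1", "concentration": 3.0, "status": "valid"},
            {"sample_id": "s2", "metabolite_id": "m2", "concentration": 0.0, "status": "below_lod"},
        ],
        metabolites=[
            {"metabolite_id": "m1", "class": "Amino Acids", "lod_value": 0.5},
            {"metabolite_id": "m2", "class": "Triacylglycerols", "lod_value": 1.0},
        ],
        samples=[
            {"sample_id": "s1", "tissue": "liver", "protocol": "P01",
             "replicate_index": 1, "unit_basis": "per_mg"},
            {"sample_id": "s2", "tissue": "liver", "protocol": "P01",
             "replicate_index": 2, "unit_basis": "per_mg"},
        ],
    )


@pytest.fixture
def small_benchmark() -> QuantDataset:
    """Small but complete benchmark: 2 tissues x 3 protocols x 3 reps x 12 metabolites."""
    spec = SyntheticSpec(
        n_metabolites=12,
        class_proportions={"Amino Acids": 0.5, "Triacylglycerols": 0.5},
        tissues=("liver", "HEK"),
        protocols={
            pid: ProtocolDescriptor(pid, pid, frozenset(solv))
            for pid, solv in [
                ("P01", {"IPA"}),
                ("P02", {"MeOH", "ACN"}),
                ("P03", {"EtOH", "MTBE"}),
            ]
        },
        lod_quantile=0.2,
        seed=7,
    )
    dataset, _ = generate_dataset(spec)
    return dataset


def replicate_group_dataset(concentrations_by_metabolite, lods=None, statuses=None,
                            tissue="liver", protocol="P01", unit_basis="per_mg"):
    """One tissue x protocol group with n replicates per metabolite."""
    mets = list(concentrations_by_metabolite)
    n_rep = len(next(iter(concentrations_by_metabolite.values())))
    lods = lods or {m: 0.0 for m in mets}
    records = []
    for r in range(n_rep):
        for m in mets:
            conc = concentrations_by_metabolite[m][r]
            status = statuses[m][r] if statuses else "valid"
            records.append(
                {"sample_id": f"s{r + 1}", "metabolite_id": m,
                 "concentration": conc, "status": status}
            )
    return make_dataset(
        records=records,
        metabolites=[{"metabolite_id": m, "class": "Amino Acids", "lod_value": lods[m]} for m in mets],
        samples=[
            {"sample_id": f"s{r + 1}", "tissue": tissue, "protocol": protocol,
             "replicate_index": r + 1, "unit_basis": unit_basis}
            for r in range(n_rep)
        ],
    )
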
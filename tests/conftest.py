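import numpy as np
import pandas as pd
import pytest

from twindiscord import simulate as sim
from twindiscord.core import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
)


@pytest.fixture(scope="session")
def small_cohort():
    """4 twin sets (one triplet), 2 collections, 2 replicates, planted DMPs."""
    cfg = sim.TwinSimConfig(
        n_twin_sets=4,
        triplet_sets=(4,),
        n_probes=500,
        n_planted_dmps_shared=10,
        delta_beta=0.3,
        n_collections=2,
        n_replicates=2,
        replicate_sd=0.02,
        biological_sd=0.02,
        seed=11,
    )
    return sim.simulate_twin_methylomes(cfg)


@pytest.fixture
def tiny_sheet():
    rows = []
    for set_no, indivs in ((1, 2), (2, 2)):
        for j in range(indivs):
            sid = f"t{set_no}{j}"
            rows.append({
                "sample_id": sid,
                "individual_id": f"set{set_no}_i{j + 1}",
                "twin_set_id": f"set{set_no}",
                "disease_status": "affected" if j == 0 else "unaffected",
                "sex": "M",
                "age_at_collection": 50.0,
                "collection_index": 1,
                "replicate_group": sid,
                "cohort": "twin",
            })
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def tiny_beta(tiny_sheet):
    rng = np.random.default_rng(0)
    probes = [f"cg{i:03d}" for i in range(1, 11)]
    data = pd.DataFrame(
        rng.uniform(0.1, 0.9, (10, len(tiny_sheet))),
        index=probes,
        columns=tiny_sheet.sample_ids,
    )
    return BetaMatrix(data)


@pytest.fixture
def tiny_annotation(tiny_beta):
    probes = tiny_beta.probe_ids
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": probes,
        "chromosome": "chr1",
        "position": np.arange(1, len(probes) + 1) * 50,
        "genes": ["geneA"] * 5 + [""] * 5,
        "distance_to_tss": 100,
        "hil_category": ["HC", "IC", "ICshore", "LC"] * 2 + ["HC", "HC"],
        "cross_hybridising": False,
        "sex_chromosome": False,
        "snp_overlap": False,
    }))
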
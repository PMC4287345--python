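import numpy as np
import pandas as pd
import pytest

from edrug.association import CohortDataset, DrugActivityTable
from edrug.regions import MissenseMutation, Pfr, ProteinIsoform


@pytest.fixture
def two_region_isoform() -> ProteinIsoform:
    return ProteinIsoform(gene_id="GENE1", isoform_id="GENE1.1", sequence="A" * 100)


def make_mutation(sample: str, position: int, gene="GENE1", iso="GENE1.1") -> MissenseMutation:
    return MissenseMutation(
        sample_id=sample, gene_id=gene, isoform_id=iso,
        position=position, ref_aa="A", alt_aa="V",
    )


def make_dataset(
    region_a_samples,
    region_b_samples,
    activity: dict[str, dict[str, float]],
    seq_len: int = 100,
) -> CohortDataset:
    """Cohort with one gene, two regions (1-40 and 51-90) and given activity.

    ``region_a_samples`` / ``region_b_samples`` get one mutation inside
    the respective region; ``activity`` maps drug -> {sample: value}.
    """
    iso = ProteinIsoform(gene_id="GENE1", isoform_id="GENE1.1", sequence="A" * seq_len)
    regions = [
        Pfr("RA", "GENE1", "GENE1.1", "pfam", 1, 40, "domA"),
        Pfr("RB", "GENE1", "GENE1.1", "pfam", 51, 90, "domB"),
    ]
    mutations = [make_mutation(s, 10) for s in region_a_samples]
    mutations += [make_mutation(s, 60) for s in region_b_samples]
    frame = pd.DataFrame(activity).astype(float)
    return CohortDataset(
        isoforms=[iso], regions=regions, mutations=mutations,
        activity=DrugActivityTable(frame),
    )
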
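import pytest

from liquidmrd.io import (
    CosmicAnnotation,
    CosmicTable,
    Material,
    SampleRecord,
    Timepoint,
    VariantKey,
    VariantObservation,
)

PLASMA_TPS = (
    Timepoint.BASELINE,
    Timepoint.D14,
    Timepoint.POST_ICI,
    Timepoint.PREOP,
    Timepoint.POSTOP,
)


def make_manifest(patient_id="P1", timepoints=PLASMA_TPS, with_wbc=True):
    days = {
        Timepoint.BASELINE: 0,
        Timepoint.D14: 14,
        Timepoint.POST_ICI: 28,
        Timepoint.PREOP: 70,
        Timepoint.POSTOP: 112,
    }
    records = [
        SampleRecord(f"{patient_id}_{tp.value}", patient_id, Material.PLASMA, tp, days[tp])
        for tp in timepoints
    ]
    if with_wbc:
        records.append(
            SampleRecord(f"{patient_id}_WBC", patient_id, Material.WBC, Timepoint.BASELINE, 0)
        )
    return records


def make_key(pos=1000, ref="A", alt="T", chrom="chr1", gene="TP53"):
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene)


def make_obs(key, sample_id, maf, patient_id="P1", coverage=2000, smc=0):
    return VariantObservation(
        key=key,
        patient_id=patient_id,
        sample_id=sample_id,
        maf=maf,
        distinct_coverage=coverage,
        super_mutant_count=smc,
    )


def annotation(key, total=0, heme=0):
    return CosmicAnnotation(key=key, total_occurrences=total, heme_lymphoid_occurrences=heme)


@pytest.fixture
def manifest_one_patient():
    return make_manifest()


@pytest.fixture
def empty_cosmic():
    return CosmicTable()
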
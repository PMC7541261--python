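from __future__ import annotations

import pytest

from quadrec.cohort import (
    AnnotatedVariant,
    Effect,
    Genotype,
    Quad,
    Role,
    Sample,
    Sex,
)
from quadrec.synthetic import CohortSpec, simulate_cohort


@pytest.fixture
def quad():
    """One quad with a male proband and a female sibling."""
    return Quad(
        family_id="FAM1",
        proband=Sample("p1", "FAM1", Role.PROBAND, Sex.MALE),
        sibling=Sample("s1", "FAM1", Role.SIBLING, Sex.FEMALE),
        father=Sample("fa1", "FAM1", Role.FATHER, Sex.MALE),
        mother=Sample("mo1", "FAM1", Role.MOTHER, Sex.FEMALE),
    )


@pytest.fixture
def male_quad():
    """One quad with two male children."""
    return Quad(
        family_id="FAM2",
        proband=Sample("p2", "FAM2", Role.PROBAND, Sex.MALE),
        sibling=Sample("s2", "FAM2", Role.SIBLING, Sex.MALE),
        father=Sample("fa2", "FAM2", Role.FATHER, Sex.MALE),
        mother=Sample("mo2", "FAM2", Role.MOTHER, Sex.FEMALE),
    )


def make_variant(
    *,
    chrom="1",
    pos=1000,
    gene="GENEA",
    effect=Effect.STOP_GAIN,
    reve=None,
    gnomad_af=0.0001,
    cohort_af=0.0001,
    gnomad_male_carriers=0,
    clinvar_benign=False,
    depth_ok=True,
    gq_ok=True,
    callrate_ok=True,
    genotypes=None,
    ref="A",
    alt="T",
) -> AnnotatedVariant:
    return AnnotatedVariant(
        variant_id=f"{chrom}:{pos}:{ref}:{alt}",
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, effect=effect,
        reve_score=reve, gnomad_af=gnomad_af, cohort_af=cohort_af,
        gnomad_male_carriers=gnomad_male_carriers,
        clinvar_benign=clinvar_benign, depth_ok=depth_ok, gq_ok=gq_ok,
        callrate_ok=callrate_ok, genotypes=genotypes or {},
    )


def gts(quad: Quad, child=Genotype.HOM_REF, sibling=Genotype.HOM_REF,
        father=Genotype.HOM_REF, mother=Genotype.HOM_REF) -> dict:
    return {
        quad.proband.sample_id: child,
        quad.sibling.sample_id: sibling,
        quad.father.sample_id: father,
        quad.mother.sample_id: mother,
    }


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic cohort reused by read-only tests."""
    return simulate_cohort(CohortSpec(n_quads=400, seed=101))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_sim):
    """The same cohort written to disk once per session."""
    from quadrec.synthetic import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    files = write_cohort(small_sim, out)
    return files
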
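"""Biallelic and hemizygous inherited-event calling and shared-event removal.

The exhaustive-oracle test enumerates every quad genotype configuration with
up to three variants per gene and compares the caller against a brute-force
enumeration of parental-origin assignments.
"""

from __future__ import annotations

import itertools
import random

import pytest

from quadrec.cohort import Effect, Genotype
from quadrec.inheritance import (
    CallDiagnostics,
    EventGroup,
    EventMode,
    Origin,
    call_biallelic,
    call_x_hemizygous,
    maf_filter,
    remove_shared,
)

from .conftest import gts, make_variant
from .oracles import brute_force_biallelic, brute_force_x_hemizygous

PTV = dict(effect=Effect.STOP_GAIN, reve=None)
DMIS = dict(effect=Effect.MISSENSE, reve=0.9)
SYN = dict(effect=Effect.SYNONYMOUS, reve=None)


class TestMafFilter:
    @pytest.mark.parametrize(
        "chrom,cohort,gnomad,expected",
        [
            ("1", 0.005, 0.009, True),
            ("1", 0.005, 0.011, False),   # reference side above 1%
            ("1", 0.02, 0.001, False),    # cohort side above 1%
            ("1", 0.01, 0.01, True),      # boundary inclusive
            ("X", 0.0005, 0.0009, True),
            ("X", 0.002, 0.0009, False),  # both sources must pass on X
            ("X", 0.0005, 0.002, False),
            ("X", 0.001, 0.001, True),
        ],
    )
    def test_thresholds(self, chrom, cohort, gnomad, expected):
        v = make_variant(chrom=chrom, cohort_af=cohort, gnomad_af=gnomad)
        assert maf_filter(v) is expected


class TestCallBiallelic:
    def test_canonical_homozygote(self, quad):
        v = make_variant(**PTV, genotypes=gts(
            quad, child=Genotype.HOM_ALT, father=Genotype.HET, mother=Genotype.HET))
        events = call_biallelic(quad, [v])
        assert len(events) == 1
        e = events[0]
        assert e.mode is EventMode.BIALLELIC_HOM
        assert e.group is EventGroup.BIALLELIC_PTV
        assert dict(e.parental_origin)[v.variant_id] is Origin.EITHER

    def test_ptv_dmis_in_trans_is_biallelic_ptv(self, quad):
        a = make_variant(pos=100, **PTV, genotypes=gts(
            quad, child=Genotype.HET, father=Genotype.HET))
        b = make_variant(pos=200, **DMIS, genotypes=gts(
            quad, child=Genotype.HET, mother=Genotype.HET))
        events = call_biallelic(quad, [a, b])
        assert len(events) == 1
        e = events[0]
        assert e.mode is EventMode.BIALLELIC_CHET
        assert e.group is EventGroup.BIALLELIC_PTV
        origins = dict(e.parental_origin)
        assert origins[a.variant_id] is Origin.FATHER
        assert origins[b.variant_id] is Origin.MOTHER

    def test_cis_pair_excluded_and_tallied(self, quad):
        """Two child hets carried only by the mother: cis or unphaseable."""
        a = make_variant(pos=100, **PTV, genotypes=gts(
            quad, child=Genotype.HET, mother=Genotype.HET))
        b = make_variant(pos=200, **PTV, genotypes=gts(
            quad, child=Genotype.HET, mother=Genotype.HET))
        diags = CallDiagnostics()
        assert call_biallelic(quad, [a, b], diags) == []
        assert diags.phase_ambiguous == 1

    def test_parent_carrying_both_is_ambiguous(self, quad):
        a = make_variant(pos=100, **PTV, genotypes=gts(
            quad, child=Genotype.HET, father=Genotype.HET, mother=Genotype.HET))
        b = make_variant(pos=200, **PTV, genotypes=gts(
            quad, child=Genotype.HET, mother=Genotype.HET))
        diags = CallDiagnostics()
        assert call_biallelic(quad, [a, b], diags) == []
        assert diags.phase_ambiguous == 1

    def test_mendelian_inconsistency_rejected(self, quad):
        v = make_variant(**PTV, genotypes=gts(quad, child=Genotype.HOM_ALT,
                                              father=Genotype.HET))
        diags = CallDiagnostics()
        assert call_biallelic(quad, [v], diags) == []
        assert diags.mendelian_rejected == 1

    def test_ptv_synonymous_pair_does_not_qualify(self, quad):
        a = make_variant(pos=100, **PTV, genotypes=gts(
            quad, child=Genotype.HET, father=Genotype.HET))
        b = make_variant(pos=200, **SYN, genotypes=gts(
            quad, child=Genotype.HET, mother=Genotype.HET))
        assert call_biallelic(quad, [a, b]) == []

    def test_strongest_group_kept_per_gene(self, quad):
        hom_syn = make_variant(pos=100, **SYN, genotypes=gts(
            quad, child=Genotype.HOM_ALT, father=Genotype.HET, mother=Genotype.HET))
        a = make_variant(pos=200, **PTV, genotypes=gts(
            quad, child=Genotype.HET, father=Genotype.HET))
        b = make_variant(pos=300, **PTV, genotypes=gts(
            quad, child=Genotype.HET, mother=Genotype.HET))
        events = call_biallelic(quad, [hom_syn, a, b])
        assert len(events) == 1
        assert events[0].group is EventGroup.BIALLELIC_PTV

    def test_order_invariance(self, quad):
        a = make_variant(pos=100, **PTV, genotypes=gts(
            quad, child=Genotype.HET, father=Genotype.HET))
        b = make_variant(pos=200, **DMIS, genotypes=gts(
            quad, child=Genotype.HET, mother=Genotype.HET))
        c = make_variant(pos=300, **SYN, genotypes=gts(
            quad, child=Genotype.HOM_ALT, father=Genotype.HET, mother=Genotype.HET))
        base = call_biallelic(quad, [a, b, c])
        for perm in itertools.permutations([a, b, c]):
            assert call_biallelic(quad, list(perm)) == base


class TestCallXHemizygous:
    def test_maternal_hemizygous_ptv(self, quad):
        v = make_variant(chrom="X", **PTV, genotypes=gts(
            quad, child=Genotype.HEMI_ALT, mother=Genotype.HET))
        events = call_x_hemizygous(quad, [v])
        assert len(events) == 1
        e = events[0]
        assert e.group is EventGroup.X_PTV
        assert dict(e.parental_origin)[v.variant_id] is Origin.MOTHER

    def test_female_child_produces_no_event(self, quad):
        v = make_variant(chrom="X", **PTV, genotypes=gts(
            quad, sibling=Genotype.HET, mother=Genotype.HET))
        assert call_x_hemizygous(quad, [v]) == []

    def test_non_inherited_counted_as_de_novo(self, quad):
        v = make_variant(chrom="X", **PTV, genotypes=gts(quad, child=Genotype.HEMI_ALT))
        diags = CallDiagnostics()
        assert call_x_hemizygous(quad, [v], diags) == []
        assert diags.x_de_novo == 1

    def test_carrier_father_rejected_as_genotype_error(self, quad):
        v = make_variant(chrom="X", **PTV, genotypes=gts(
            quad, child=Genotype.HEMI_ALT, father=Genotype.HEMI_ALT,
            mother=Genotype.HET))
        diags = CallDiagnostics()
        assert call_x_hemizygous(quad, [v], diags) == []
        assert diags.x_father_carrier == 1


class TestRemoveShared:
    def test_identical_chet_removed_both(self, quad):
        a = make_variant(pos=100, **PTV, genotypes=gts(
            quad, child=Genotype.HET, sibling=Genotype.HET, father=Genotype.HET))
        b = make_variant(pos=200, **PTV, genotypes=gts(
            quad, child=Genotype.HET, sibling=Genotype.HET, mother=Genotype.HET))
        events = call_biallelic(quad, [a, b])
        assert len(events) == 2  # one per child
        diags = CallDiagnostics()
        retained = remove_shared(events, [quad], diags)
        assert retained == []
        assert diags.shared_removed == {EventGroup.BIALLELIC_PTV: 1}

    def test_proband_only_event_retained(self, quad):
        v = make_variant(**PTV, genotypes=gts(
            quad, child=Genotype.HOM_ALT, father=Genotype.HET, mother=Genotype.HET))
        events = call_biallelic(quad, [v])
        retained = remove_shared(events, [quad])
        assert len(retained) == 1
        assert retained[0].child_id == quad.proband.sample_id

    def test_x_sharing_requires_two_males(self, male_quad):
        v = make_variant(chrom="X", **PTV, genotypes=gts(
            male_quad, child=Genotype.HEMI_ALT, sibling=Genotype.HEMI_ALT,
            mother=Genotype.HET))
        events = call_x_hemizygous(male_quad, [v])
        assert len(events) == 2
        diags = CallDiagnostics()
        assert remove_shared(events, [male_quad], diags) == []
        assert diags.shared_removed == {EventGroup.X_PTV: 1}

    def test_x_event_kept_with_carrier_sister(self, quad):
        # female sibling carries the same variant het: no male-male sharing
        v = make_variant(chrom="X", **PTV, genotypes=gts(
            quad, child=Genotype.HEMI_ALT, sibling=Genotype.HET,
            mother=Genotype.HET))
        events = call_x_hemizygous(quad, [v])
        assert len(events) == 1
        assert remove_shared(events, [quad]) == events


GT3 = ["ref", "het", "hom"]
CATS = ["PTV", "Dmis", "synonymous"]
_GT = {"ref": Genotype.HOM_REF, "het": Genotype.HET, "hom": Genotype.HOM_ALT}


def _run_oracle_case(quad, child_gts, father_gts, mother_gts, categories):
    cat_kwargs = {"PTV": PTV, "Dmis": DMIS, "synonymous": SYN}
    variants = [
        make_variant(pos=100 * (i + 1), **cat_kwargs[c], genotypes=gts(
            quad, child=_GT[cg], father=_GT[fg], mother=_GT[mg]))
        for i, (cg, fg, mg, c) in enumerate(
            zip(child_gts, father_gts, mother_gts, categories))
    ]
    events = [e for e in call_biallelic(quad, variants)
              if e.child_id == quad.proband.sample_id]
    got = {
        (e.mode.value, e.group.value,
         tuple(sorted(int(v.split(":")[1]) // 100 - 1 for v in e.variant_ids)))
        for e in events
    }
    want = brute_force_biallelic(list(child_gts), list(father_gts),
                                 list(mother_gts), list(categories))
    want = {(m, g, tuple(sorted(idx))) for m, g, idx in want}
    assert got == want, (child_gts, father_gts, mother_gts, categories)


def test_exhaustive_oracle_single_and_pairs(quad):
    """All 1- and 2-variant quad genotype configurations match brute force."""
    for n, cats in [(1, [("PTV",), ("Dmis",), ("synonymous",)]),
                    (2, [("PTV", "PTV"), ("PTV", "Dmis"), ("Dmis", "synonymous"),
                         ("synonymous", "synonymous")])]:
        for categories in cats:
            for config in itertools.product(
                itertools.product(GT3, repeat=n),
                itertools.product(GT3, repeat=n),
                itertools.product(GT3, repeat=n),
            ):
                child, father, mother = config
                _run_oracle_case(quad, child, father, mother, categories)


def test_exhaustive_oracle_three_variants_sampled(quad):
    """Random slice of the 3-variant configuration space vs brute force."""
    rng = random.Random(17)
    space = list(itertools.product(GT3, repeat=3))
    for _ in range(400):
        child = rng.choice(space)
        father = rng.choice(space)
        mother = rng.choice(space)
        categories = tuple(rng.choice(CATS) for _ in range(3))
        _run_oracle_case(quad, child, father, mother, categories)


def test_x_oracle_exhaustive(male_quad):
    """All 1- and 2-variant X configurations for a male child vs brute force."""
    child_opts = ["ref", "hemi"]
    father_opts = ["ref", "hemi"]
    mother_opts = ["ref", "het", "hom"]
    xgt = {"ref": Genotype.HOM_REF, "hemi": Genotype.HEMI_ALT,
           "het": Genotype.HET, "hom": Genotype.HOM_ALT}
    cat_kwargs = {"PTV": PTV, "Dmis": DMIS, "synonymous": SYN}
    for n in (1, 2):
        for categories in itertools.product(CATS, repeat=n):
            for child in itertools.product(child_opts, repeat=n):
                for father in itertools.product(father_opts, repeat=n):
                    for mother in itertools.product(mother_opts, repeat=n):
                        variants = [
                            make_variant(chrom="X", pos=100 * (i + 1),
                                         **cat_kwargs[c],
                                         genotypes=gts(male_quad,
                                                       child=xgt[cg],
                                                       father=xgt[fg],
                                                       mother=xgt[mg]))
                            for i, (cg, fg, mg, c) in enumerate(
                                zip(child, father, mother, categories))
                        ]
                        events = [e for e in call_x_hemizygous(male_quad, variants)
                                  if e.child_id == male_quad.proband.sample_id]
                        got = {
                            (e.mode.value, e.group.value,
                             tuple(sorted(int(v.split(":")[1]) // 100 - 1
                                          for v in e.variant_ids)))
                            for e in events
                        }
                        want = brute_force_x_hemizygous(
                            list(child), list(father), list(mother),
                            list(categories))
                        assert got == want, (child, father, mother, categories)
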
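import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import genoderive as gd
from genoderive import filtering as flt
from genoderive.model import (
    Allele,
    ENDOGENOUS,
    ExpressedGene,
    MOUSE,
    TARGETED,
    TRANSGENIC,
)


def _allele(method=TRANSGENIC, attrs=(), cargo=0, wild_type=False, aid="A:1"):
    return Allele(
        aid,
        aid,
        method,
        attributes=frozenset(attrs),
        mutated_markers=frozenset({"M:1"}),
        expressed_genes=tuple(
            ExpressedGene(f"C:{i}", MOUSE) for i in range(cargo)
        ),
        is_wild_type=wild_type,
    )


@pytest.mark.parametrize(
    "allele, conditional, verdict, reason",
    [
        # cre-only transgene in a conditional genotype is a tool
        (_allele(attrs={"recombinase"}), True, flt.EXCLUDE, flt.CONDITIONAL_RECOMBINASE),
        # same allele outside a conditional genotype may be causative
        (_allele(attrs={"recombinase"}), False, flt.RETAIN, flt.NOT_APPLICABLE),
        # knock-in recombinase is also excludable when conditional
        (
            _allele(TARGETED, attrs={"recombinase", "null_knockout"}),
            True,
            flt.EXCLUDE,
            flt.CONDITIONAL_RECOMBINASE,
        ),
        # recombinase expressing additional cargo genes is retained
        (_allele(attrs={"recombinase"}, cargo=2), True, flt.RETAIN, flt.NOT_APPLICABLE),
        (_allele(attrs={"recombinase"}, cargo=1), True, flt.RETAIN, flt.NOT_APPLICABLE),
        # transactivator transgene without cargo is a tool; with cargo it is not
        (_allele(attrs={"transactivator"}), False, flt.EXCLUDE, flt.TRANSGENIC_TRANSACTIVATOR),
        (_allele(attrs={"transactivator"}, cargo=1), False, flt.RETAIN, flt.NOT_APPLICABLE),
        # reporter-only transgene is a tool; reporter with cargo attribute is not
        (_allele(attrs={"reporter"}), False, flt.EXCLUDE, flt.TRANSGENIC_REPORTER),
        (
            _allele(attrs={"reporter", "inserted_expressed_sequence"}, cargo=1),
            False,
            flt.RETAIN,
            flt.NOT_APPLICABLE,
        ),
        # knock-in transactivators and reporters are always retained
        (_allele(TARGETED, attrs={"transactivator"}), False, flt.RETAIN, flt.NOT_APPLICABLE),
        (_allele(TARGETED, attrs={"reporter"}), True, flt.RETAIN, flt.NOT_APPLICABLE),
        # wild-type alleles are always tools
        (_allele(ENDOGENOUS, wild_type=True), False, flt.EXCLUDE, flt.WILD_TYPE),
    ],
)
def test_classification_table(allele, conditional, verdict, reason):
    result = gd.classify_allele_causality(allele, conditional)
    assert (result.verdict, result.reason) == (verdict, reason)
    assert result.allele_id == allele.id


def test_verdict_reason_consistency(catalog):
    for allele in catalog.alleles.values():
        for conditional in (False, True):
            v = gd.classify_allele_causality(allele, conditional)
            assert (v.verdict == flt.RETAIN) == (v.reason == flt.NOT_APPLICABLE)


def test_conditional_insertion_genotype_removes_cre_and_wild_type(catalog):
    genotype = catalog.genotypes["MGI:4429149"]
    retained, verdicts = gd.filter_noncausative(genotype, catalog)
    excluded = {v.allele_id: v.reason for v in verdicts if v.excluded}
    assert excluded == {
        "MGI:4429152": flt.CONDITIONAL_RECOMBINASE,
        "MGI:4429151": flt.WILD_TYPE,
    }
    assert [a.id for a in retained] == ["MGI:4429150"]


def test_transgene_same_gene_genotype_removes_nothing(catalog):
    genotype = catalog.genotypes["MGI:3836994"]
    retained, verdicts = gd.filter_noncausative(genotype, catalog)
    assert not any(v.excluded for v in verdicts)
    assert len(retained) == len(genotype.distinct_allele_ids())


def test_all_tool_genotype_yields_empty_retained_set(catalog):
    wt = gd.Allele(
        "A:WT", "wt", ENDOGENOUS,
        mutated_markers=frozenset({"MGI:97769"}),
        is_wild_type=True,
    )
    cat = gd.Catalog.build(
        catalog.markers.values(), list(catalog.alleles.values()) + [wt]
    )
    genotype = gd.Genotype("G:WT", (gd.AllelePair("A:WT", "A:WT"),))
    retained, verdicts = gd.filter_noncausative(genotype, cat)
    assert retained == []
    assert [v.reason for v in verdicts] == [flt.WILD_TYPE]


_attrs = st.frozensets(
    st.sampled_from(sorted(gd.model.ALLELE_ATTRIBUTES)), max_size=3
)
_alleles = st.builds(
    _allele,
    method=st.sampled_from([TARGETED, TRANSGENIC, ENDOGENOUS, "other"]),
    attrs=_attrs,
    cargo=st.integers(min_value=0, max_value=3),
    wild_type=st.booleans(),
)


@settings(max_examples=200, deadline=None)
@given(allele=_alleles)
def test_conditional_toggle_only_affects_recombinase_alleles(allele):
    unconditional = gd.classify_allele_causality(allele, False)
    conditional = gd.classify_allele_causality(allele, True)
    if unconditional != conditional:
        assert "recombinase" in allele.attributes
        assert conditional.reason == flt.CONDITIONAL_RECOMBINASE


@settings(max_examples=100, deadline=None)
@given(allele=_alleles, conditional=st.booleans())
def test_classification_is_deterministic(allele, conditional):
    first = gd.classify_allele_causality(allele, conditional)
    assert first == gd.classify_allele_causality(allele, conditional)


def test_filtering_is_order_invariant_and_idempotent(catalog):
    for genotype in catalog.genotypes.values():
        retained, verdicts = gd.filter_noncausative(genotype, catalog)
        reversed_genotype = gd.Genotype(
            genotype.id,
            tuple(
                gd.AllelePair(p.allele2, p.allele1) if p.allele2 else p
                for p in reversed(genotype.allele_pairs)
            ),
            genotype.is_conditional,
            genotype.strain_background,
        )
        retained_rev, verdicts_rev = gd.filter_noncausative(reversed_genotype, catalog)
        assert {a.id for a in retained} == {a.id for a in retained_rev}
        assert set(verdicts) == set(verdicts_rev)
        # idempotence: refiltering a genotype built from the retained set
        # removes nothing further
        if retained:
            refiltered = gd.Genotype(
                genotype.id,
                tuple(gd.AllelePair(a.id) for a in retained),
                genotype.is_conditional,
            )
            retained2, _ = gd.filter_noncausative(refiltered, catalog)
            assert {a.id for a in retained2} == {a.id for a in retained}
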
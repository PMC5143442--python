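import random

import pytest

import genoderive as gd
from genoderive import derivation as dv
from genoderive.model import (
    AllelePair,
    Catalog,
    CrossReferenceError,
    Genotype,
    PHENOTYPE,
    SourceAnnotation,
)


def test_every_example_genotype_resolves_as_documented(fixture_set):
    for gid, expected in fixture_set.expected.items():
        trace = gd.resolve_genotype(fixture_set.catalog.genotypes[gid], fixture_set.catalog)
        res = trace.resolution
        assert res.terminal_box == expected.terminal_box, gid
        assert res.annotate_markers == expected.annotate_markers, gid
        assert res.exclusion_reason == expected.exclusion_reason, gid


def test_trace_structure(fixture_set):
    trace = gd.resolve_genotype(
        fixture_set.catalog.genotypes["MGI:4429149"], fixture_set.catalog
    )
    assert trace.loci_after.members <= trace.loci_before.members
    assert len(trace.verdicts) == 3
    assert trace.resolution.annotate_markers == frozenset()
    assert trace.resolution.exclusion_reason == dv.NON_MOUSE_EXPRESSED


def test_single_locus_genotype_skips_filtering(fixture_set):
    trace = gd.resolve_genotype(
        fixture_set.catalog.genotypes["MGI:3039435"], fixture_set.catalog
    )
    assert trace.resolution.terminal_box == dv.B1_SINGLE
    assert trace.verdicts == ()
    assert trace.loci_after == trace.loci_before


def test_exclusion_and_annotation_are_mutually_exclusive(sim_run):
    _, _, _, traces = sim_run
    for trace in traces:
        res = trace.resolution
        if res.annotate_markers:
            assert res.exclusion_reason is None
            assert res.terminal_box != dv.EXCLUDED
        else:
            assert res.terminal_box == dv.EXCLUDED
            assert res.exclusion_reason in dv.EXCLUSION_REASONS


def test_annotated_markers_come_from_post_filter_loci(sim_run):
    _, _, _, traces = sim_run
    for trace in traces:
        assert trace.resolution.annotate_markers <= trace.loci_after.members
        assert trace.loci_after.members <= trace.loci_before.members


def test_fanout_same_gene_transgene_pair(fixture_set):
    anns = [a for a in fixture_set.annotations if a.genotype_id == "MGI:3836994"]
    derived, traces = gd.derive_annotations(anns, fixture_set.catalog)
    assert len(derived) == 2
    assert {d.marker_id for d in derived} == {"MGI:3836986", "MGI:97769"}
    assert {d.term_id for d in derived} == {anns[0].term_id}
    assert all(d.terminal_boxes == {dv.B9_TRANSGENE_ENDOGENOUS_MATCH} for d in derived)
    assert len(traces) == 1


def test_dedup_merges_source_genotypes(fixture_set):
    cat = fixture_set.catalog
    allele = cat.alleles["MGI:1857941"]  # single-gene targeted knockout
    genotypes = [
        Genotype("G:D1", (AllelePair(allele.id, allele.id),)),
        Genotype("G:D2", (AllelePair(allele.id, None),)),
    ]
    merged = Catalog.build(cat.markers.values(), cat.alleles.values(), genotypes)
    anns = [
        SourceAnnotation("G:D1", "MP:9799001", PHENOTYPE),
        SourceAnnotation("G:D2", "MP:9799001", PHENOTYPE),
    ]
    derived, _ = gd.derive_annotations(anns, merged)
    assert len(derived) == 1
    assert derived[0].source_genotype_ids == {"G:D1", "G:D2"}


def test_empty_annotation_table(fixture_set):
    derived, traces = gd.derive_annotations([], fixture_set.catalog)
    assert derived == []
    assert traces == []


def test_unannotated_genotypes_are_not_resolved(fixture_set):
    anns = [a for a in fixture_set.annotations if a.genotype_id == "MGI:5502689"]
    _, traces = gd.derive_annotations(anns, fixture_set.catalog)
    assert [t.genotype_id for t in traces] == ["MGI:5502689"]


def test_unknown_genotype_id_is_an_error(fixture_set):
    with pytest.raises(CrossReferenceError, match="MGI:0000000"):
        gd.derive_annotations(
            [SourceAnnotation("MGI:0000000", "MP:9700001", PHENOTYPE)],
            fixture_set.catalog,
        )


def test_conservation_of_fanout(sim_run):
    catalog, annotations, derived, traces = sim_run
    anns_by_genotype = {}
    for ann in annotations:
        anns_by_genotype.setdefault(ann.genotype_id, []).append(ann)
    resolution = {t.genotype_id: t.resolution for t in traces}

    expected_keys = {}
    for gid, res in resolution.items():
        for ann in anns_by_genotype[gid]:
            for marker in res.annotate_markers:
                expected_keys.setdefault((marker, ann.term_id, ann.ontology), set()).add(gid)

    got = {(d.marker_id, d.term_id, d.ontology): set(d.source_genotype_ids) for d in derived}
    assert got == expected_keys


def test_suppressed_docking_site_never_annotated(sim_run):
    _, _, derived, traces = sim_run
    for d in derived:
        assert d.marker_id not in gd.DEFAULT_CONFIG.never_self_annotate_ids
    for t in traces:
        assert not (
            t.resolution.annotate_markers & gd.DEFAULT_CONFIG.never_self_annotate_ids
        )


def test_tool_exclusion_soundness(sim_run):
    """A marker contributed only by excluded alleles is never annotated."""
    catalog, _, _, traces = sim_run
    for trace in traces:
        excluded_ids = {v.allele_id for v in trace.verdicts if v.excluded}
        if not excluded_ids:
            continue
        genotype = catalog.genotypes[trace.genotype_id]
        retained = [
            catalog.alleles[a]
            for a in genotype.distinct_allele_ids()
            if a not in excluded_ids
        ]
        retained_loci = gd.genotype_loci(genotype, retained, catalog).members
        only_via_excluded = trace.loci_before.members - retained_loci
        assert not (trace.resolution.annotate_markers & only_via_excluded)


def test_resolution_is_permutation_invariant(sim_run):
    catalog, _, _, traces = sim_run
    rng = random.Random(7)
    for trace in rng.sample(traces, 200):
        genotype = catalog.genotypes[trace.genotype_id]
        pairs = [
            AllelePair(p.allele2, p.allele1) if p.allele2 is not None else p
            for p in genotype.allele_pairs
        ]
        rng.shuffle(pairs)
        shuffled = Genotype(
            genotype.id, tuple(pairs), genotype.is_conditional, genotype.strain_background
        )
        assert gd.resolve_genotype(shuffled, catalog).resolution == trace.resolution


def test_derive_is_invariant_under_annotation_order(fixture_set):
    anns = list(fixture_set.annotations)
    derived, _ = gd.derive_annotations(anns, fixture_set.catalog)
    derived_rev, _ = gd.derive_annotations(anns[::-1], fixture_set.catalog)
    assert derived == derived_rev


def test_custom_docking_config_changes_outcome(fixture_set):
    # with the intergenic insertion site registered as a docking site, the
    # documented false negative becomes an annotation to the cargo gene
    cat = fixture_set.catalog
    config = gd.DerivationConfig(
        docking_site_ids=gd.DEFAULT_CONFIG.docking_site_ids | {"MGI:5314543"},
        never_self_annotate_ids=gd.DEFAULT_CONFIG.never_self_annotate_ids,
    )
    trace = gd.resolve_genotype(cat.genotypes["MGI:5544092"], cat, config)
    assert trace.resolution.terminal_box == dv.B10_DOCKING_SITE
    assert trace.resolution.annotate_markers == {"MGI:105923"}
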
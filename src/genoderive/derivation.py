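"""Resolution engine: map each genotype to the marker(s) whose mutation is
causative, and fan genotype-level annotations out to those markers.

A genotype is processed in stages:

1. Count the loci contributed by all of its alleles. A single locus is
   resolved immediately (unless it is a never-self-annotate docking site
   such as Gt(ROSA)26Sor, which receives no derived annotations).
2. Otherwise exclude non-causative tool alleles and recount.
3. A single remaining locus is resolved; a locus that is both the
   endogenous mutated gene and the inserted expressed gene resolves via
   the self-expressed branch.
4. A single multi-genic region marker plus (a subset of) its region genes
   resolves to the region marker alone; two region markers, or a region
   marker plus any outside locus, exclude the genotype.
5. Multiple remaining loci with no inserted expressed gene exclude the
   genotype.
6. Multiple inserted expressed genes resolve to a sole transgene when no
   endogenous mutated gene remains, else exclude.
7. A single inserted expressed non-mouse gene excludes the genotype.
8-9. A sole transgene plus its single expressed mouse gene resolve to
   both, whether or not the same endogenous gene is also mutated.
10. A docking site plus a single expressed mouse gene resolve to the
   expressed gene only.
11. Anything else is excluded.

Every resolution carries a full :class:`DecisionTrace` for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .filtering import CausalityVerdict, filter_noncausative
from .locus_accounting import (
    EXPRESSED,
    LocusSet,
    MUTATED,
    genotype_loci,
)
from .model import (
    Catalog,
    CrossReferenceError,
    DEFAULT_CONFIG,
    DerivationConfig,
    GENE,
    Genotype,
    MULTI_GENIC_REGION,
    SourceAnnotation,
    TRANSGENE,
)

# terminal flow-chart boxes
B1_SINGLE = "B1_SINGLE"
B3_SINGLE_AFTER_FILTER = "B3_SINGLE_AFTER_FILTER"
B4_MULTIGENIC_MARKER = "B4_MULTIGENIC_MARKER"
B6_TRANSGENE_ONLY = "B6_TRANSGENE_ONLY"
B8_TRANSGENE_PLUS_GENE = "B8_TRANSGENE_PLUS_GENE"
B9_TRANSGENE_ENDOGENOUS_MATCH = "B9_TRANSGENE_ENDOGENOUS_MATCH"
B10_DOCKING_SITE = "B10_DOCKING_SITE"
B11_SELF_EXPRESSED = "B11_SELF_EXPRESSED"
EXCLUDED = "EXCLUDED"
TERMINAL_BOXES = frozenset(
    {
        B1_SINGLE,
        B3_SINGLE_AFTER_FILTER,
        B4_MULTIGENIC_MARKER,
        B6_TRANSGENE_ONLY,
        B8_TRANSGENE_PLUS_GENE,
        B9_TRANSGENE_ENDOGENOUS_MATCH,
        B10_DOCKING_SITE,
        B11_SELF_EXPRESSED,
        EXCLUDED,
    }
)

# exclusion reasons
MULTIPLE_MULTIGENIC = "multiple_multigenic"
MULTIGENIC_PLUS_OUTSIDE = "multigenic_plus_outside"
MULTI_MARKER_NO_EXPRESSED = "multi_marker_no_expressed"
MULTI_EXPRESSED_NOT_SINGLE_TRANSGENE = "multi_expressed_not_single_transgene"
NON_MOUSE_EXPRESSED = "non_mouse_expressed"
UNRESOLVED_MULTI = "unresolved_multi"
ALL_ALLELES_EXCLUDED = "all_alleles_excluded"
ROSA_SUPPRESSED = "rosa_suppressed"
EXCLUSION_REASONS = frozenset(
    {
        MULTIPLE_MULTIGENIC,
        MULTIGENIC_PLUS_OUTSIDE,
        MULTI_MARKER_NO_EXPRESSED,
        MULTI_EXPRESSED_NOT_SINGLE_TRANSGENE,
        NON_MOUSE_EXPRESSED,
        UNRESOLVED_MULTI,
        ALL_ALLELES_EXCLUDED,
        ROSA_SUPPRESSED,
    }
)


@dataclass(frozen=True)
class Resolution:
    genotype_id: str
    terminal_box: str
    annotate_markers: frozenset[str] = frozenset()
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class DecisionTrace:
    genotype_id: str
    verdicts: tuple[CausalityVerdict, ...]
    loci_before: LocusSet
    loci_after: LocusSet
    resolution: Resolution


@dataclass(frozen=True)
class DerivedAnnotation:
    marker_id: str
    term_id: str
    ontology: str
    source_genotype_ids: frozenset[str]
    terminal_boxes: frozenset[str]


def _resolution(
    genotype_id: str,
    box: str,
    markers: Iterable[str] = (),
    reason: Optional[str] = None,
    config: DerivationConfig = DEFAULT_CONFIG,
) -> Resolution:
    markers = frozenset(markers)
    # Never-self-annotate docking sites are suppressed on every path.
    if markers & config.never_self_annotate_ids:
        markers = markers - config.never_self_annotate_ids
        if not markers:
            return Resolution(genotype_id, EXCLUDED, frozenset(), ROSA_SUPPRESSED)
    if box == EXCLUDED:
        return Resolution(genotype_id, EXCLUDED, frozenset(), reason)
    return Resolution(genotype_id, box, markers, None)


def resolve_genotype(
    genotype: Genotype,
    catalog: Catalog,
    config: DerivationConfig = DEFAULT_CONFIG,
) -> DecisionTrace:
    """Run one genotype through the staged resolution rules."""
    all_alleles = [
        catalog.allele(aid, referrer=genotype.id)
        for aid in genotype.distinct_allele_ids()
    ]
    loci_before = genotype_loci(genotype, all_alleles, catalog)

    def finish(
        box: str,
        markers: Iterable[str] = (),
        reason: Optional[str] = None,
        verdicts: tuple[CausalityVerdict, ...] = (),
        loci_after: Optional[LocusSet] = None,
    ) -> DecisionTrace:
        res = _resolution(genotype.id, box, markers, reason, config)
        return DecisionTrace(
            genotype.id,
            verdicts,
            loci_before,
            loci_before if loci_after is None else loci_after,
            res,
        )

    # stage 1: single-locus genotypes resolve without filtering
    if len(loci_before) == 1:
        (only,) = loci_before.members
        return finish(B1_SINGLE, {only})

    # stage 2: remove tool alleles and recount
    retained, verdicts_list = filter_noncausative(genotype, catalog)
    verdicts = tuple(verdicts_list)
    loci_after = genotype_loci(genotype, retained, catalog)
    if not loci_after.members:
        return finish(
            EXCLUDED, reason=ALL_ALLELES_EXCLUDED, verdicts=verdicts, loci_after=loci_after
        )

    def done(box: str, markers: Iterable[str] = (), reason: Optional[str] = None):
        return finish(box, markers, reason, verdicts=verdicts, loci_after=loci_after)

    members = loci_after.members

    # stage 3 / 11: single remaining locus
    if len(members) == 1:
        (only,) = members
        tags = loci_after.tags(only)
        if MUTATED in tags and EXPRESSED in tags and only not in loci_after.non_mouse:
            return done(B11_SELF_EXPRESSED, {only})
        return done(B3_SINGLE_AFTER_FILTER, {only})

    def marker_class(mid: str) -> Optional[str]:
        m = catalog.markers.get(mid)
        return None if m is None else m.marker_class

    # stage 4: multi-genic region markers
    region_markers = sorted(
        m for m in members if marker_class(m) == MULTI_GENIC_REGION
    )
    if len(region_markers) >= 2:
        return done(EXCLUDED, reason=MULTIPLE_MULTIGENIC)
    if len(region_markers) == 1:
        region = region_markers[0]
        outside = members - {region} - catalog.markers[region].region_genes
        if outside:
            return done(EXCLUDED, reason=MULTIGENIC_PLUS_OUTSIDE)
        return done(B4_MULTIGENIC_MARKER, {region})

    # stage 5: inserted expressed genes
    expressed = loci_after.tagged(EXPRESSED)
    if not expressed:
        return done(EXCLUDED, reason=MULTI_MARKER_NO_EXPRESSED)

    transgenes = frozenset(m for m in members if marker_class(m) == TRANSGENE)

    # stage 6: multiple inserted expressed genes
    if len(expressed) > 1:
        endogenous_mutated = frozenset(
            m
            for m in members
            if marker_class(m) == GENE and MUTATED in loci_after.tags(m)
        )
        if len(transgenes) == 1 and not endogenous_mutated:
            return done(B6_TRANSGENE_ONLY, transgenes)
        return done(EXCLUDED, reason=MULTI_EXPRESSED_NOT_SINGLE_TRANSGENE)

    # stage 7: single inserted expressed gene — must be a mouse gene
    (gene,) = expressed
    if gene in loci_after.non_mouse:
        return done(EXCLUDED, reason=NON_MOUSE_EXPRESSED)

    # stages 8-10: exactly two loci, the expressed gene plus one carrier
    if len(members) == 2:
        (other,) = members - {gene}
        if other in transgenes:
            if MUTATED in loci_after.tags(gene):
                return done(B9_TRANSGENE_ENDOGENOUS_MATCH, {other, gene})
            return done(B8_TRANSGENE_PLUS_GENE, {other, gene})
        if other in config.docking_site_ids:
            return done(B10_DOCKING_SITE, {gene})

    return done(EXCLUDED, reason=UNRESOLVED_MULTI)


def derive_annotations(
    source_annotations: Iterable[SourceAnnotation],
    catalog: Catalog,
    config: DerivationConfig = DEFAULT_CONFIG,
) -> tuple[list[DerivedAnnotation], list[DecisionTrace]]:
    """Resolve every annotated genotype and fan annotations out to markers.

    Each genotype with at least one source annotation is resolved exactly
    once; each of its annotations yields one derived annotation per
    causative marker; results are deduplicated on (marker, term, ontology)
    with merged provenance. Genotypes without annotations are not touched.
    """
    by_genotype: dict[str, list[SourceAnnotation]] = {}
    for ann in source_annotations:
        if ann.genotype_id not in catalog.genotypes:
            raise CrossReferenceError(ann.genotype_id, ann.genotype_id, "genotype")
        by_genotype.setdefault(ann.genotype_id, []).append(ann)

    traces: list[DecisionTrace] = []
    merged: dict[tuple[str, str, str], tuple[set[str], set[str]]] = {}
    for gid in sorted(by_genotype):
        trace = resolve_genotype(catalog.genotypes[gid], catalog, config)
        traces.append(trace)
        res = trace.resolution
        if not res.annotate_markers:
            continue
        for ann in by_genotype[gid]:
            for marker_id in res.annotate_markers:
                key = (marker_id, ann.term_id, ann.ontology)
                sources, boxes = merged.setdefault(key, (set(), set()))
                sources.add(gid)
                boxes.add(res.terminal_box)

    derived = [
        DerivedAnnotation(m, t, o, frozenset(src), frozenset(boxes))
        for (m, t, o), (src, boxes) in sorted(merged.items())
    ]
    return derived, traces
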
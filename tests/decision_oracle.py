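"""Independent brute-force re-derivation of the resolution rules.

This is a deliberately flat, table-style reimplementation used only to
cross-check the staged engine: loci are enumerated with plain loops into
tag dictionaries and the outcome is decided by one ordered chain of
locus-pattern predicates. It shares no code with the package engine.
"""

from collections import defaultdict

MUT, EXP, SELF, REG = "mut", "exp", "self", "reg"


def _tool_reason(allele, conditional):
    if allele.is_wild_type:
        return "wild_type"
    transgenic = allele.generation_method == "transgenic"
    cargo = len(allele.expressed_genes)
    if transgenic and "transactivator" in allele.attributes and cargo == 0:
        return "transgenic_transactivator"
    if (
        transgenic
        and "reporter" in allele.attributes
        and "inserted_expressed_sequence" not in allele.attributes
    ):
        return "transgenic_reporter"
    if "recombinase" in allele.attributes and conditional and cargo == 0:
        return "conditional_recombinase"
    return None


def _loci(alleles, catalog):
    tags = defaultdict(set)
    non_mouse = set()
    for allele in alleles:
        for mid in allele.mutated_markers:
            marker = catalog.markers[mid]
            if marker.marker_class == "transgene":
                tags[mid].add(SELF)
            else:
                tags[mid].add(MUT)
            if marker.marker_class == "multi_genic_region":
                for gid in marker.region_genes:
                    tags[gid].add(REG)
        for eg in allele.expressed_genes:
            tags[eg.gene_id].add(EXP)
            if eg.species != "mouse":
                non_mouse.add(eg.gene_id)
    return dict(tags), non_mouse


def _klass(catalog, mid):
    marker = catalog.markers.get(mid)
    return None if marker is None else marker.marker_class


def oracle_resolve(genotype, catalog, docking_sites, never_self):
    """Return (terminal_box, annotate_markers frozenset, exclusion_reason)."""
    alleles = [catalog.alleles[aid] for aid in genotype.distinct_allele_ids()]

    def suppress(box, markers):
        keep = frozenset(markers) - frozenset(never_self)
        if not keep:
            return ("EXCLUDED", frozenset(), "rosa_suppressed")
        return (box, keep, None)

    before, _ = _loci(alleles, catalog)
    if len(before) == 1:
        return suppress("B1_SINGLE", before)

    kept = [a for a in alleles if _tool_reason(a, genotype.is_conditional) is None]
    after, non_mouse = _loci(kept, catalog)
    if not after:
        return ("EXCLUDED", frozenset(), "all_alleles_excluded")

    members = set(after)
    regions = {m for m in members if _klass(catalog, m) == "multi_genic_region"}
    transgenes = {m for m in members if _klass(catalog, m) == "transgene"}
    expressed = {m for m, t in after.items() if EXP in t}
    mutated_genes = {
        m for m, t in after.items() if MUT in t and _klass(catalog, m) == "gene"
    }

    # flat decision table, first matching pattern wins
    if len(members) == 1:
        (m,) = members
        if MUT in after[m] and EXP in after[m] and m not in non_mouse:
            return suppress("B11_SELF_EXPRESSED", {m})
        return suppress("B3_SINGLE_AFTER_FILTER", {m})
    if len(regions) > 1:
        return ("EXCLUDED", frozenset(), "multiple_multigenic")
    if len(regions) == 1:
        (r,) = regions
        if members <= {r} | set(catalog.markers[r].region_genes):
            return suppress("B4_MULTIGENIC_MARKER", {r})
        return ("EXCLUDED", frozenset(), "multigenic_plus_outside")
    if not expressed:
        return ("EXCLUDED", frozenset(), "multi_marker_no_expressed")
    if len(expressed) > 1:
        if len(transgenes) == 1 and not mutated_genes:
            return suppress("B6_TRANSGENE_ONLY", transgenes)
        return ("EXCLUDED", frozenset(), "multi_expressed_not_single_transgene")
    (g,) = expressed
    if g in non_mouse:
        return ("EXCLUDED", frozenset(), "non_mouse_expressed")
    if len(members) == 2 and len(transgenes) == 1 and members == transgenes | {g}:
        if MUT in after[g]:
            return suppress("B9_TRANSGENE_ENDOGENOUS_MATCH", members)
        return suppress("B8_TRANSGENE_PLUS_GENE", members)
    if len(members) == 2 and members - {g} <= set(docking_sites):
        return suppress("B10_DOCKING_SITE", {g})
    return ("EXCLUDED", frozenset(), "unresolved_multi")
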
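"""Locus accounting: which genetic loci does an allele or genotype touch.

The loci associated with an allele are (a) the markers its mutation
disrupts (for a transgenic allele, the transgene marker itself), (b) for a
multi-genic region marker, every endogenous gene inside the region, and
(c) every gene the allele expresses. Each locus carries provenance tags
recording how it entered the set; the resolution engine branches on those
tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import (
    Allele,
    Catalog,
    CrossReferenceError,
    Genotype,
    MULTI_GENIC_REGION,
    NON_MOUSE,
    TRANSGENE,
)

# contribution kinds
MUTATED = "mutated"
EXPRESSED = "expressed"
TRANSGENE_SELF = "transgene_self"
REGION_GENE = "region_gene"
CONTRIBUTION_KINDS = frozenset({MUTATED, EXPRESSED, TRANSGENE_SELF, REGION_GENE})


@dataclass(frozen=True)
class LocusSet:
    """Set of loci with per-locus provenance.

    ``provenance`` maps marker id -> contribution kinds; ``non_mouse``
    lists members that are expressed non-mouse genes (present so the
    engine can detect them — they are never annotation subjects and may
    not resolve to catalog markers).
    """

    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)
    non_mouse: frozenset[str] = frozenset()

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.provenance)

    def tags(self, marker_id: str) -> frozenset[str]:
        return self.provenance.get(marker_id, frozenset())

    def tagged(self, kind: str) -> frozenset[str]:
        return frozenset(m for m, kinds in self.provenance.items() if kind in kinds)

    def __len__(self) -> int:
        return len(self.provenance)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.provenance


def merge(locus_sets: Iterable[LocusSet]) -> LocusSet:
    provenance: dict[str, set[str]] = {}
    non_mouse: set[str] = set()
    for ls in locus_sets:
        for mid, kinds in ls.provenance.items():
            provenance.setdefault(mid, set()).update(kinds)
        non_mouse.update(ls.non_mouse)
    return LocusSet(
        {mid: frozenset(kinds) for mid, kinds in provenance.items()},
        frozenset(non_mouse),
    )


def allele_loci(allele: Allele, catalog: Catalog) -> LocusSet:
    """All loci an allele contributes, tagged with how they contribute.

    Raises :class:`CrossReferenceError` naming the allele if a mutated
    marker is missing from the catalog.
    """
    provenance: dict[str, set[str]] = {}
    non_mouse: set[str] = set()
    for mid in allele.mutated_markers:
        marker = catalog.marker(mid, referrer=allele.id)
        if marker.marker_class == TRANSGENE:
            provenance.setdefault(mid, set()).add(TRANSGENE_SELF)
        else:
            provenance.setdefault(mid, set()).add(MUTATED)
        if marker.marker_class == MULTI_GENIC_REGION:
            for gid in marker.region_genes:
                provenance.setdefault(gid, set()).add(REGION_GENE)
    for eg in allele.expressed_genes:
        provenance.setdefault(eg.gene_id, set()).add(EXPRESSED)
        if eg.species == NON_MOUSE:
            non_mouse.add(eg.gene_id)
    return LocusSet(
        {mid: frozenset(kinds) for mid, kinds in provenance.items()},
        frozenset(non_mouse),
    )


def genotype_loci(
    genotype: Genotype, alleles: Iterable[Allele], catalog: Catalog
) -> LocusSet:
    """Union of :func:`allele_loci` over the given alleles of a genotype.

    Idempotent under duplicate alleles: a homozygous pair contributes the
    same loci as either of its copies alone.
    """
    genotype_allele_ids = set(genotype.distinct_allele_ids())
    seen: set[str] = set()
    parts: list[LocusSet] = []
    for allele in alleles:
        if allele.id not in genotype_allele_ids:
            raise ValueError(
                f"allele {allele.id!r} does not belong to genotype {genotype.id!r}"
            )
        if allele.id in seen:
            continue
        seen.add(allele.id)
        parts.append(allele_loci(allele, catalog))
    return merge(parts)
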
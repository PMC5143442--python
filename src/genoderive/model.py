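"""Domain model for genotype-to-marker annotation derivation.

The model mirrors how a model-organism database curates mouse mutants:

* a :class:`MarkerRef` is a genetic locus (gene, transgene, or a single
  marker standing for a multi-genic mutation region);
* an :class:`Allele` is a mutation event with exactly one generation
  method, zero-to-many curated attributes, the endogenous loci it
  disrupts, and the genes whose products it expresses;
* a :class:`Genotype` is a list of allele pairs plus a curated
  conditional flag and a strain background;
* a :class:`SourceAnnotation` attaches a phenotype or disease term to a
  genotype.

Catalog integrity is checked by :func:`validate_catalog`, which returns
violations as data rather than raising, so a partially broken catalog can
still be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

# --- closed vocabularies -------------------------------------------------

GENE = "gene"
TRANSGENE = "transgene"
MULTI_GENIC_REGION = "multi_genic_region"
MARKER_CLASSES = frozenset({GENE, TRANSGENE, MULTI_GENIC_REGION})

TARGETED = "targeted"
TRANSGENIC = "transgenic"
ENDOGENOUS = "endogenous"
OTHER = "other"
GENERATION_METHODS = frozenset({TARGETED, TRANSGENIC, ENDOGENOUS, OTHER})

REPORTER = "reporter"
RECOMBINASE = "recombinase"
TRANSACTIVATOR = "transactivator"
INSERTED_EXPRESSED_SEQUENCE = "inserted_expressed_sequence"
NULL_KNOCKOUT = "null_knockout"
HYPOMORPH = "hypomorph"
MODIFIED_ISOFORM = "modified_isoform"
ALLELE_ATTRIBUTES = frozenset(
    {
        REPORTER,
        RECOMBINASE,
        TRANSACTIVATOR,
        INSERTED_EXPRESSED_SEQUENCE,
        NULL_KNOCKOUT,
        HYPOMORPH,
        MODIFIED_ISOFORM,
    }
)

MOUSE = "mouse"
NON_MOUSE = "non_mouse"
SPECIES = frozenset({MOUSE, NON_MOUSE})

PHENOTYPE = "phenotype"
DISEASE = "disease"
ONTOLOGIES = frozenset({PHENOTYPE, DISEASE})
TERM_PREFIX_ONTOLOGY = {"MP:": PHENOTYPE, "OMIM:": DISEASE}

# Catalog ids for the three endogenous loci routinely used as insertion
# docking sites (Gt(ROSA)26Sor, Col1a1, Hprt).
ROSA26_ID = "MGI:104735"
COL1A1_ID = "MGI:88467"
HPRT_ID = "MGI:96217"
DEFAULT_DOCKING_SITE_IDS = frozenset({ROSA26_ID, COL1A1_ID, HPRT_ID})
DEFAULT_NEVER_SELF_ANNOTATE_IDS = frozenset({ROSA26_ID})


class CrossReferenceError(KeyError):
    """An entity references an id that does not exist in the catalog."""

    def __init__(self, entity_id: str, dangling_id: str, context: str = ""):
        self.entity_id = entity_id
        self.dangling_id = dangling_id
        msg = f"{entity_id}: unresolved reference to {dangling_id!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep msg readable
        return self.args[0]


# --- entities ------------------------------------------------------------


@dataclass(frozen=True)
class MarkerRef:
    """A genetic locus that can be the subject of a derived annotation."""

    id: str
    symbol: str
    marker_class: str
    region_genes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ExpressedGene:
    """A gene whose product an allele expresses.

    ``species = mouse`` means the id resolves to a catalog gene marker;
    ``non_mouse`` ids are opaque (the gene lives outside the catalog).
    """

    gene_id: str
    species: str = MOUSE


@dataclass(frozen=True)
class Allele:
    id: str
    symbol: str
    generation_method: str
    attributes: frozenset[str] = frozenset()
    mutated_markers: frozenset[str] = frozenset()
    expressed_genes: tuple[ExpressedGene, ...] = ()
    is_wild_type: bool = False


@dataclass(frozen=True)
class AllelePair:
    """One allele pair of a genotype; ``allele2 = None`` for hemizygous or
    indeterminate second alleles. Pair order carries no meaning."""

    allele1: str
    allele2: Optional[str] = None

    def allele_ids(self) -> tuple[str, ...]:
        if self.allele2 is None:
            return (self.allele1,)
        return (self.allele1, self.allele2)


@dataclass(frozen=True)
class Genotype:
    id: str
    allele_pairs: tuple[AllelePair, ...]
    is_conditional: bool = False
    strain_background: str = ""

    def distinct_allele_ids(self) -> tuple[str, ...]:
        """Distinct allele ids in order of first appearance (homozygous
        pairs count once)."""
        seen: dict[str, None] = {}
        for pair in self.allele_pairs:
            for aid in pair.allele_ids():
                seen.setdefault(aid)
        return tuple(seen)


@dataclass(frozen=True)
class SourceAnnotation:
    genotype_id: str
    term_id: str
    ontology: str
    qualifier: Optional[str] = None
    reference: str = ""


def ontology_for_term(term_id: str) -> Optional[str]:
    for prefix, ontology in TERM_PREFIX_ONTOLOGY.items():
        if term_id.startswith(prefix):
            return ontology
    return None


@dataclass(frozen=True)
class DerivationConfig:
    """Docking-site configuration for the resolution engine.

    ``never_self_annotate_ids`` are docking sites that never receive
    derived annotations even as a genotype's sole locus (the Rosa26
    behaviour); it must be a subset of ``docking_site_ids``.
    """

    docking_site_ids: frozenset[str] = DEFAULT_DOCKING_SITE_IDS
    never_self_annotate_ids: frozenset[str] = DEFAULT_NEVER_SELF_ANNOTATE_IDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "docking_site_ids", frozenset(self.docking_site_ids))
        object.__setattr__(
            self, "never_self_annotate_ids", frozenset(self.never_self_annotate_ids)
        )
        if not self.never_self_annotate_ids <= self.docking_site_ids:
            raise ValueError(
                "never_self_annotate_ids must be a subset of docking_site_ids"
            )


DEFAULT_CONFIG = DerivationConfig()


# --- catalog -------------------------------------------------------------


@dataclass
class Catalog:
    """In-memory catalog of markers, alleles and genotypes.

    Entities are keyed by id; duplicate ids encountered while building are
    recorded (last record wins) and surfaced by :func:`validate_catalog`.
    """

    markers: dict[str, MarkerRef] = field(default_factory=dict)
    alleles: dict[str, Allele] = field(default_factory=dict)
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    duplicate_ids: tuple[tuple[str, str], ...] = ()

    @classmethod
    def build(
        cls,
        markers: Iterable[MarkerRef],
        alleles: Iterable[Allele],
        genotypes: Iterable[Genotype] = (),
    ) -> "Catalog":
        catalog = cls()
        dupes: list[tuple[str, str]] = []
        for kind, items, table in (
            ("marker", markers, catalog.markers),
            ("allele", alleles, catalog.alleles),
            ("genotype", genotypes, catalog.genotypes),
        ):
            for item in items:
                if item.id in table:
                    dupes.append((kind, item.id))
                table[item.id] = item
        catalog.duplicate_ids = tuple(dupes)
        return catalog

    def marker(self, marker_id: str, referrer: str = "") -> MarkerRef:
        try:
            return self.markers[marker_id]
        except KeyError:
            raise CrossReferenceError(referrer or "?", marker_id, "marker") from None

    def allele(self, allele_id: str, referrer: str = "") -> Allele:
        try:
            return self.alleles[allele_id]
        except KeyError:
            raise CrossReferenceError(referrer or "?", allele_id, "allele") from None

    def genotype(self, genotype_id: str) -> Genotype:
        try:
            return self.genotypes[genotype_id]
        except KeyError:
            raise CrossReferenceError("?", genotype_id, "genotype") from None


# --- validation ----------------------------------------------------------


@dataclass(frozen=True, order=True)
class Violation:
    entity_id: str
    rule: str
    message: str


def _violations_for_marker(marker: MarkerRef, catalog: Catalog) -> list[Violation]:
    out = []
    if marker.marker_class not in MARKER_CLASSES:
        out.append(
            Violation(
                marker.id,
                "marker_class_unknown",
                f"unknown marker_class {marker.marker_class!r}",
            )
        )
    if marker.marker_class == MULTI_GENIC_REGION:
        if not marker.region_genes:
            out.append(
                Violation(
                    marker.id,
                    "region_genes_required",
                    "multi_genic_region marker must list its region genes",
                )
            )
        for gid in marker.region_genes:
            member = catalog.markers.get(gid)
            if member is None:
                out.append(
                    Violation(
                        marker.id,
                        "region_gene_unresolved",
                        f"region gene {gid!r} not in catalog",
                    )
                )
            elif member.marker_class != GENE:
                out.append(
                    Violation(
                        marker.id,
                        "region_gene_not_gene",
                        f"region gene {gid!r} has class {member.marker_class!r}",
                    )
                )
    elif marker.region_genes:
        out.append(
            Violation(
                marker.id,
                "region_genes_forbidden",
                "region_genes only allowed on multi_genic_region markers",
            )
        )
    return out


def _violations_for_allele(allele: Allele, catalog: Catalog) -> list[Violation]:
    out = []
    if allele.generation_method not in GENERATION_METHODS:
        out.append(
            Violation(
                allele.id,
                "generation_method_unknown",
                f"unknown generation_method {allele.generation_method!r}",
            )
        )
    for attr in sorted(allele.attributes - ALLELE_ATTRIBUTES):
        out.append(
            Violation(allele.id, "attribute_unknown", f"unknown attribute {attr!r}")
        )
    if not allele.mutated_markers:
        out.append(
            Violation(
                allele.id,
                "no_mutated_marker",
                "allele must reference at least one mutated marker",
            )
        )
    resolved: list[MarkerRef] = []
    for mid in sorted(allele.mutated_markers):
        marker = catalog.markers.get(mid)
        if marker is None:
            out.append(
                Violation(
                    allele.id,
                    "mutated_marker_unresolved",
                    f"mutated marker {mid!r} not in catalog",
                )
            )
        else:
            resolved.append(marker)
    if allele.is_wild_type:
        if allele.attributes:
            out.append(
                Violation(
                    allele.id,
                    "wild_type_with_attributes",
                    "wild-type allele must not carry attributes",
                )
            )
        if allele.expressed_genes:
            out.append(
                Violation(
                    allele.id,
                    "wild_type_with_expressed_genes",
                    "wild-type allele must not express genes",
                )
            )
        if len(allele.mutated_markers) != 1:
            out.append(
                Violation(
                    allele.id,
                    "wild_type_marker_count",
                    "wild-type allele must reference exactly one marker",
                )
            )
    if allele.generation_method == TRANSGENIC:
        transgenes = [m for m in resolved if m.marker_class == TRANSGENE]
        if len(allele.mutated_markers) != 1 or len(transgenes) != 1:
            out.append(
                Violation(
                    allele.id,
                    "transgenic_marker_shape",
                    "transgenic allele must reference exactly one transgene marker",
                )
            )
    for eg in allele.expressed_genes:
        if eg.species not in SPECIES:
            out.append(
                Violation(
                    allele.id,
                    "expressed_species_unknown",
                    f"unknown species {eg.species!r} for expressed gene {eg.gene_id!r}",
                )
            )
        elif eg.species == MOUSE:
            target = catalog.markers.get(eg.gene_id)
            if target is None:
                out.append(
                    Violation(
                        allele.id,
                        "expressed_gene_unresolved",
                        f"mouse expressed gene {eg.gene_id!r} not in catalog",
                    )
                )
            elif target.marker_class != GENE:
                out.append(
                    Violation(
                        allele.id,
                        "expressed_gene_not_gene",
                        f"mouse expressed gene {eg.gene_id!r} has class "
                        f"{target.marker_class!r}",
                    )
                )
    return out


def _violations_for_genotype(genotype: Genotype, catalog: Catalog) -> list[Violation]:
    out = []
    if not genotype.allele_pairs:
        out.append(
            Violation(
                genotype.id,
                "genotype_no_allele_pairs",
                "genotype must contain at least one allele pair",
            )
        )
    for aid in genotype.distinct_allele_ids():
        if aid not in catalog.alleles:
            out.append(
                Violation(
                    genotype.id,
                    "allele_unresolved",
                    f"allele {aid!r} not in catalog",
                )
            )
    return out


def validate_catalog(catalog: Catalog) -> list[Violation]:
    """Check every invariant of the catalog.

    Returns a deterministic, sorted list of violations; an empty list
    means the catalog is internally consistent and the derivation engine
    will never hit a cross-reference error on it.
    """
    out: list[Violation] = []
    for kind, dup_id in catalog.duplicate_ids:
        out.append(Violation(dup_id, "duplicate_id", f"duplicate {kind} id"))
    for marker in catalog.markers.values():
        out.extend(_violations_for_marker(marker, catalog))
    for allele in catalog.alleles.values():
        out.extend(_violations_for_allele(allele, catalog))
    for genotype in catalog.genotypes.values():
        out.extend(_violations_for_genotype(genotype, catalog))
    return sorted(set(out))
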
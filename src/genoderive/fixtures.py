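"""Packaged example catalogs and a seeded synthetic-catalog generator.

``example_catalog`` reconstructs a set of published mouse genotypes that
together exercise every branch of the resolution engine, each with its
documented expected outcome (including documented false positives such as
the Sell/NOD diabetes annotation and false negatives such as the Igs1
intergenic docking site — the expectations encode the algorithm's actual
behaviour, not biological truth).

``simulate_catalog`` generates reproducible random catalogs from a
mixture over genotype archetypes; at the default mixture every terminal
box and every exclusion reason is reachable.

``summarize_run`` tabulates a derive run into a breakdown report
(genotype counts by outcome and tool-allele removals by class).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from . import derivation as dv
from . import filtering as flt
from .derivation import DecisionTrace, Resolution
from .model import (
    Allele,
    AllelePair,
    Catalog,
    COL1A1_ID,
    DISEASE,
    ENDOGENOUS,
    ExpressedGene,
    GENE,
    Genotype,
    HPRT_ID,
    INSERTED_EXPRESSED_SEQUENCE,
    MOUSE,
    MULTI_GENIC_REGION,
    MarkerRef,
    NON_MOUSE,
    NULL_KNOCKOUT,
    PHENOTYPE,
    RECOMBINASE,
    REPORTER,
    ROSA26_ID,
    SourceAnnotation,
    TARGETED,
    TRANSACTIVATOR,
    TRANSGENE,
    TRANSGENIC,
)


@dataclass(frozen=True)
class ExpectedResolution:
    terminal_box: str
    annotate_markers: frozenset[str] = frozenset()
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class FixtureSet:
    catalog: Catalog
    annotations: tuple[SourceAnnotation, ...]
    expected: Mapping[str, ExpectedResolution]


def _gene(mid: str, symbol: str) -> MarkerRef:
    return MarkerRef(mid, symbol, GENE)


def _tg(mid: str, symbol: str) -> MarkerRef:
    return MarkerRef(mid, symbol, TRANSGENE)


def example_catalog() -> FixtureSet:  # noqa: C901 - one long literal table
    """Catalog of published worked examples with expected resolutions."""
    markers = [
        _gene("MGI:97350", "Notch4"),
        _gene("MGI:97769", "Prnp"),
        _gene("MGI:99960", "Ewsr1"),
        _gene("MGI:96569", "Kcnj11"),
        _gene("MGI:108075", "Smo"),
        _gene("MGI:101791", "Isl1"),
        _gene("MGI:88057", "Apoe"),
        _gene("MGI:99255", "Fasl"),
        _gene(ROSA26_ID, "Gt(ROSA)26Sor"),
        _gene(COL1A1_ID, "Col1a1"),
        _gene(HPRT_ID, "Hprt"),
        _gene("MGI:98297", "Snca"),
        _gene("MGI:95664", "Foxg1"),
        _gene("MGI:95848", "Gsx2"),
        _gene("MGI:98880", "Tyr"),
        _gene("MGI:104659", "Mitf"),
        _gene("MGI:108360", "Epn1"),
        _gene("MGI:108359", "Epn2"),
        _gene("MGI:98279", "Sell"),
        _gene("MGI:5314543", "Igs1"),
        _gene("MGI:105923", "Edn2"),
        _gene("MGI:88276", "Ctnnb1"),
        _gene("MGI:104752", "Nfkbia"),
        _tg("MGI:4431198", "Tg(tetO-Notch4*)1Rwng"),
        _tg("MGI:4431199", "Tg(Tek-tTA)1Rwng"),
        _tg("MGI:3836986", "Tg(Prnp*D177N*M128V)A21Rchi"),
        _tg("MGI:5571090", "Tg(Drd2-EGFP)S118Gsat"),
        _tg("MGI:4429148", "Tg(CAG-cre/Esr1*)5Amc"),
        _tg("MGI:4430412", "Tg(Ins2-cre)23Herr"),
        _tg("MGI:4412089", "Tg(tetO-Gsx2,-EGFP)1Kcam"),
    ]
    # 39 endogenous genes inside the engineered deletion Del(7Coro1a-Spn)
    del_region = [f"MGI:77000{i:02d}" for i in range(1, 40)]
    markers += [_gene(mid, f"Del7g{i + 1}") for i, mid in enumerate(del_region)]
    markers.append(
        MarkerRef(
            "MGI:5569506",
            "Del(7Coro1a-Spn)1Dolm",
            MULTI_GENIC_REGION,
            frozenset(del_region),
        )
    )

    def wt(aid: str, symbol: str, marker: str) -> Allele:
        return Allele(
            aid, symbol, ENDOGENOUS, mutated_markers=frozenset({marker}),
            is_wild_type=True,
        )

    alleles = [
        # hemizygous transgene expressing mouse Notch4 under tetO control
        Allele(
            "MGI:4431200", "Tg(tetO-Notch4*)1Rwng", TRANSGENIC,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
            mutated_markers=frozenset({"MGI:4431198"}),
            expressed_genes=(ExpressedGene("MGI:97350", MOUSE),),
        ),
        # tTA transactivator transgene, no cargo genes
        Allele(
            "MGI:4431201", "Tg(Tek-tTA)1Rwng", TRANSGENIC,
            attributes=frozenset({TRANSACTIVATOR}),
            mutated_markers=frozenset({"MGI:4431199"}),
        ),
        # targeted Prnp knockout
        Allele(
            "MGI:1888773", "Prnp<tm1Cwe>", TARGETED,
            attributes=frozenset({NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:97769"}),
        ),
        # transgene expressing a mutant form of mouse Prnp
        Allele(
            "MGI:3836987", "Tg(Prnp*D177N*M128V)A21Rchi", TRANSGENIC,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
            mutated_markers=frozenset({"MGI:3836986"}),
            expressed_genes=(ExpressedGene("MGI:97769", MOUSE),),
        ),
        # engineered deletion spanning 39 genes
        Allele(
            "MGI:5569507", "Del(7Coro1a-Spn)1Dolm", TARGETED,
            attributes=frozenset({NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:5569506"}),
        ),
        wt("MGI:5569508", "Del(7Coro1a-Spn)1Dolm<+>", "MGI:5569506"),
        # EGFP-only reporter transgene (EGFP has no mouse ortholog)
        Allele(
            "MGI:5571092", "Tg(Drd2-EGFP)S118Gsat", TRANSGENIC,
            attributes=frozenset({REPORTER}),
            mutated_markers=frozenset({"MGI:5571090"}),
        ),
        # knock-in of human FLI1 into Ewsr1
        Allele(
            "MGI:4429150", "Ewsr1<tm2(FLI1*)Sblee>", TARGETED,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE, NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:99960"}),
            expressed_genes=(ExpressedGene("FLI1", NON_MOUSE),),
        ),
        wt("MGI:4429151", "Ewsr1<+>", "MGI:99960"),
        # tamoxifen-inducible cre transgene, no cargo
        Allele(
            "MGI:4429152", "Tg(CAG-cre/Esr1*)5Amc", TRANSGENIC,
            attributes=frozenset({RECOMBINASE}),
            mutated_markers=frozenset({"MGI:4429148"}),
        ),
        # inducible knock-in of mutant mouse Kcnj11 at the Rosa26 docking site
        Allele(
            "MGI:4430414", "Gt(ROSA)26Sor<tm1(Kcnj11*)>", TARGETED,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
            mutated_markers=frozenset({ROSA26_ID}),
            expressed_genes=(ExpressedGene("MGI:96569", MOUSE),),
        ),
        # pancreatic cre transgene
        Allele(
            "MGI:4430415", "Tg(Ins2-cre)23Herr", TRANSGENIC,
            attributes=frozenset({RECOMBINASE}),
            mutated_markers=frozenset({"MGI:4430412"}),
        ),
        # two targeted Smo alleles (one floxed, one null)
        Allele(
            "MGI:2176256", "Smo<tm1Amc>", TARGETED,
            attributes=frozenset({NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:108075"}),
        ),
        Allele(
            "MGI:2176257", "Smo<tm2Amc>", TARGETED,
            mutated_markers=frozenset({"MGI:108075"}),
        ),
        # cre knocked into Isl1 (knock-in recombinase, no cargo)
        Allele(
            "MGI:2447758", "Isl1<tm1(cre)Sev>", TARGETED,
            attributes=frozenset({RECOMBINASE, NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:101791"}),
        ),
        wt("MGI:2447759", "Isl1<+>", "MGI:101791"),
        Allele(
            "MGI:1857029", "Apoe<tm1Unc>", TARGETED,
            attributes=frozenset({NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:88057"}),
        ),
        Allele(
            "MGI:1856334", "Fasl<gld>", ENDOGENOUS,
            mutated_markers=frozenset({"MGI:99255"}),
        ),
        # Rosa26 knock-in expressing a viral gene with no mouse ortholog;
        # the cargo is not recorded, so the allele carries zero expressed genes
        Allele(
            "MGI:5004724", "Gt(ROSA)26Sor<tm1(gp80,EGFP)Eces>", TARGETED,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE, REPORTER}),
            mutated_markers=frozenset({ROSA26_ID}),
        ),
        # Col1a1 knock-in with no recorded expressed gene (RNAi insertion)
        Allele(
            "MGI:9200001", "Col1a1<tm1(shRNA)>", TARGETED,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
            mutated_markers=frozenset({COL1A1_ID}),
        ),
        # Hprt knock-in expressing mouse Snca
        Allele(
            "MGI:9200002", "Hprt<tm1(CAG-Snca)>", TARGETED,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
            mutated_markers=frozenset({HPRT_ID}),
            expressed_genes=(ExpressedGene("MGI:98297", MOUSE),),
        ),
        # knock-in transactivator (cannot be excluded by the rules)
        Allele(
            "MGI:3575096", "Foxg1<tm1(tTA)Lai>", TARGETED,
            attributes=frozenset({TRANSACTIVATOR, NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:95664"}),
        ),
        wt("MGI:3575097", "Foxg1<+>", "MGI:95664"),
        # tetO responder transgene expressing mouse Gsx2 plus EGFP
        Allele(
            "MGI:4412091", "Tg(tetO-Gsx2,-EGFP)1Kcam", TRANSGENIC,
            attributes=frozenset({REPORTER, INSERTED_EXPRESSED_SEQUENCE}),
            mutated_markers=frozenset({"MGI:4412089"}),
            expressed_genes=(ExpressedGene("MGI:95848", MOUSE),),
        ),
        # knock-in using mouse Tyr as a coat-colour reporter
        Allele(
            "MGI:9200003", "Mitf<tm1(Tyr)>", TARGETED,
            attributes=frozenset({REPORTER, INSERTED_EXPRESSED_SEQUENCE, NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:104659"}),
            expressed_genes=(ExpressedGene("MGI:98880", MOUSE),),
        ),
        Allele(
            "MGI:3510419", "Epn1<tm1Ocr>", TARGETED,
            attributes=frozenset({NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:108360"}),
        ),
        Allele(
            "MGI:3510420", "Epn2<tm1Ocr>", TARGETED,
            attributes=frozenset({NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:108359"}),
        ),
        Allele(
            "MGI:1857941", "Sell<tm1Flv>", TARGETED,
            attributes=frozenset({NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:98279"}),
        ),
        # knock-in at the intergenic Igs1 site expressing mouse Edn2;
        # Igs1 is NOT a configured docking site, so no annotation is derived
        Allele(
            "MGI:5544093", "Igs1<tm11(CAG-Bgeo,-Edn2)Nat>", TARGETED,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE, REPORTER}),
            mutated_markers=frozenset({"MGI:5314543"}),
            expressed_genes=(ExpressedGene("MGI:105923", MOUSE),),
        ),
        # knock-in of mouse Nfkbia into Ctnnb1
        Allele(
            "MGI:3039783", "Ctnnb1<tm1(Nfkbia)Rsu>", TARGETED,
            attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE, NULL_KNOCKOUT}),
            mutated_markers=frozenset({"MGI:88276"}),
            expressed_genes=(ExpressedGene("MGI:104752", MOUSE),),
        ),
        wt("MGI:3039784", "Ctnnb1<+>", "MGI:88276"),
    ]

    def gt(
        gid: str,
        pairs: list[tuple[str, Optional[str]]],
        conditional: bool = False,
        strain: str = "involves: 129",
    ) -> Genotype:
        return Genotype(
            gid, tuple(AllelePair(a, b) for a, b in pairs), conditional, strain
        )

    genotypes = [
        gt("MGI:5502689", [("MGI:4431200", None), ("MGI:4431201", None)]),
        gt(
            "MGI:3836994",
            [("MGI:1888773", "MGI:1888773"), ("MGI:3836987", "MGI:3836987")],
        ),
        gt("MGI:5571091", [("MGI:5569507", "MGI:5569508"), ("MGI:5571092", None)]),
        gt(
            "MGI:4429149",
            [("MGI:4429150", "MGI:4429151"), ("MGI:4429152", None)],
            conditional=True,
        ),
        gt(
            "MGI:4430413",
            [("MGI:4430414", "MGI:4430414"), ("MGI:4430415", None)],
            conditional=True,
        ),
        gt(
            "MGI:3689403",
            [("MGI:2176256", "MGI:2176257"), ("MGI:2447758", "MGI:2447759")],
            conditional=True,
        ),
        gt(
            "MGI:5514345",
            [("MGI:1857029", "MGI:1857029"), ("MGI:1856334", "MGI:1856334")],
            strain="C57BL/6",
        ),
        gt("MGI:9300001", [("MGI:5004724", "MGI:5004724")]),
        gt("MGI:9300002", [("MGI:9200001", "MGI:9200001")]),
        gt("MGI:9300003", [("MGI:9200002", None)]),
        gt("MGI:4412090", [("MGI:3575096", "MGI:3575097"), ("MGI:4412091", None)]),
        gt("MGI:9300004", [("MGI:9200003", "MGI:9200003")]),
        gt(
            "MGI:4356019",
            [("MGI:3510419", "MGI:3510419"), ("MGI:3510420", "MGI:3510420")],
        ),
        gt("MGI:3039435", [("MGI:1857941", "MGI:1857941")], strain="NOD"),
        gt("MGI:5544092", [("MGI:5544093", "MGI:5544093")]),
        gt("MGI:9300005", [("MGI:3039783", "MGI:3039784")]),
    ]

    catalog = Catalog.build(markers, alleles, genotypes)

    ann = SourceAnnotation
    annotations = (
        ann("MGI:5502689", "MP:9710001", PHENOTYPE, reference="J:0001"),
        ann("MGI:3836994", "MP:9710002", PHENOTYPE, reference="J:0002"),
        ann("MGI:5571091", "MP:9710003", PHENOTYPE, reference="J:0003"),
        ann("MGI:4429149", "MP:9710004", PHENOTYPE, reference="J:0004"),
        # decreased insulin secretion / permanent neonatal diabetes mellitus
        ann("MGI:4430413", "MP:0003059", PHENOTYPE, reference="J:0005"),
        ann("MGI:4430413", "OMIM:606176", DISEASE, reference="J:0005"),
        # perinatal lethality
        ann("MGI:3689403", "MP:0002081", PHENOTYPE, reference="J:0006"),
        # systemic lupus erythematosus
        ann("MGI:5514345", "OMIM:152700", DISEASE, reference="J:0007"),
        ann("MGI:9300001", "MP:9710005", PHENOTYPE, reference="J:0008"),
        ann("MGI:9300002", "MP:9710006", PHENOTYPE, reference="J:0009"),
        ann("MGI:9300003", "MP:9710007", PHENOTYPE, reference="J:0010"),
        ann("MGI:4412090", "MP:9710008", PHENOTYPE, reference="J:0011"),
        ann("MGI:9300004", "MP:9710009", PHENOTYPE, reference="J:0012"),
        ann("MGI:4356019", "MP:9710010", PHENOTYPE, reference="J:0013"),
        # insulin-dependent diabetes mellitus (documented false positive:
        # the NOD strain background, not Sell, causes the disease)
        ann("MGI:3039435", "OMIM:222100", DISEASE, reference="J:0014"),
        ann("MGI:5544092", "MP:9710011", PHENOTYPE, reference="J:0015"),
        ann("MGI:9300005", "MP:9710012", PHENOTYPE, reference="J:0016"),
    )

    E = ExpectedResolution
    fs = frozenset
    expected = {
        "MGI:5502689": E(dv.B8_TRANSGENE_PLUS_GENE, fs({"MGI:4431198", "MGI:97350"})),
        "MGI:3836994": E(
            dv.B9_TRANSGENE_ENDOGENOUS_MATCH, fs({"MGI:3836986", "MGI:97769"})
        ),
        "MGI:5571091": E(dv.B4_MULTIGENIC_MARKER, fs({"MGI:5569506"})),
        "MGI:4429149": E(dv.EXCLUDED, exclusion_reason=dv.NON_MOUSE_EXPRESSED),
        "MGI:4430413": E(dv.B10_DOCKING_SITE, fs({"MGI:96569"})),
        "MGI:3689403": E(dv.B3_SINGLE_AFTER_FILTER, fs({"MGI:108075"})),
        "MGI:5514345": E(dv.EXCLUDED, exclusion_reason=dv.MULTI_MARKER_NO_EXPRESSED),
        "MGI:9300001": E(dv.EXCLUDED, exclusion_reason=dv.ROSA_SUPPRESSED),
        "MGI:9300002": E(dv.B1_SINGLE, fs({COL1A1_ID})),
        "MGI:9300003": E(dv.B10_DOCKING_SITE, fs({"MGI:98297"})),
        "MGI:4412090": E(dv.EXCLUDED, exclusion_reason=dv.UNRESOLVED_MULTI),
        "MGI:9300004": E(dv.EXCLUDED, exclusion_reason=dv.UNRESOLVED_MULTI),
        "MGI:4356019": E(dv.EXCLUDED, exclusion_reason=dv.MULTI_MARKER_NO_EXPRESSED),
        "MGI:3039435": E(dv.B1_SINGLE, fs({"MGI:98279"})),
        "MGI:5544092": E(dv.EXCLUDED, exclusion_reason=dv.UNRESOLVED_MULTI),
        "MGI:9300005": E(dv.EXCLUDED, exclusion_reason=dv.UNRESOLVED_MULTI),
    }
    return FixtureSet(catalog, annotations, expected)


# alias used by the CLI and docs
paper_fixture_catalog = example_catalog


# --- synthetic catalogs --------------------------------------------------

ARCHETYPES = (
    "single_gene",
    "conditional_targeted",
    "docking_cargo",
    "docking_no_cargo",
    "transgene_single_cargo",
    "transgene_same_gene",
    "transgene_multi_cargo",
    "self_expressed",
    "region",
    "two_regions",
    "region_plus_gene",
    "digenic",
    "non_mouse_cargo",
    "ki_cargo_other",
    "two_transgenes_cargo",
    "all_tools",
)

DEFAULT_MIXTURE: Mapping[str, float] = {
    "single_gene": 0.20,
    "conditional_targeted": 0.14,
    "docking_cargo": 0.08,
    "docking_no_cargo": 0.05,
    "transgene_single_cargo": 0.08,
    "transgene_same_gene": 0.05,
    "transgene_multi_cargo": 0.05,
    "self_expressed": 0.05,
    "region": 0.05,
    "two_regions": 0.03,
    "region_plus_gene": 0.03,
    "digenic": 0.08,
    "non_mouse_cargo": 0.03,
    "ki_cargo_other": 0.04,
    "two_transgenes_cargo": 0.02,
    "all_tools": 0.02,
}


@dataclass(frozen=True)
class SimulationParams:
    n_genes: int = 60
    n_regions: int = 4
    region_size: int = 5
    n_genotypes: int = 200
    mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    p_conditional: float = 0.1
    max_annotations_per_genotype: int = 2
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.mixture) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mixture: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture probabilities must sum to 1 (got {total})")
        if any(p < 0 or p > 1 for p in self.mixture.values()):
            raise ValueError("mixture probabilities must lie in [0, 1]")
        if not 0 <= self.p_conditional <= 1:
            raise ValueError("p_conditional must lie in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        needs_genes = any(
            self.mixture.get(a, 0) > 0 for a in ARCHETYPES if a != "all_tools"
        )
        if needs_genes and self.n_genes < 4:
            raise ValueError("mixture requires at least 4 gene markers")
        if (
            any(self.mixture.get(a, 0) > 0 for a in ("region", "region_plus_gene"))
            and self.n_regions < 1
        ):
            raise ValueError("region archetypes require n_regions >= 1")
        if self.mixture.get("two_regions", 0) > 0 and self.n_regions < 2:
            raise ValueError("two_regions archetype requires n_regions >= 2")


class _Builder:
    """Accumulates simulated entities with deterministic fresh ids."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.markers: list[MarkerRef] = []
        self.alleles: list[Allele] = []
        self.genotypes: list[Genotype] = []
        self.annotations: list[SourceAnnotation] = []
        self._counter = 0
        self._wt_cache: dict[str, str] = {}
        self._tg_markers: list[str] = []

    def next_id(self, prefix: str) -> str:
        self._counter += 1
        return f"{prefix}:{self._counter:07d}"

    def gene(self, symbol: str) -> str:
        mid = self.next_id("SIM")
        self.markers.append(MarkerRef(mid, symbol, GENE))
        return mid

    def transgene_marker(self) -> str:
        mid = self.next_id("SIM")
        self.markers.append(MarkerRef(mid, f"Tg{mid[-5:]}", TRANSGENE))
        return mid

    def allele(self, **kw) -> str:
        aid = self.next_id("SIMA")
        kw.setdefault("symbol", f"a{aid[-5:]}")
        self.alleles.append(Allele(aid, **kw))
        return aid

    def wt_allele(self, gene_id: str) -> str:
        if gene_id not in self._wt_cache:
            self._wt_cache[gene_id] = self.allele(
                generation_method=ENDOGENOUS,
                mutated_markers=frozenset({gene_id}),
                is_wild_type=True,
            )
        return self._wt_cache[gene_id]

    def targeted(self, gene_id: str, **kw) -> str:
        kw.setdefault("attributes", frozenset({NULL_KNOCKOUT}))
        return self.allele(
            generation_method=TARGETED, mutated_markers=frozenset({gene_id}), **kw
        )

    def transgenic(self, **kw) -> str:
        return self.allele(
            generation_method=TRANSGENIC,
            mutated_markers=frozenset({self.transgene_marker()}),
            **kw,
        )

    def cre_transgene(self) -> str:
        return self.transgenic(attributes=frozenset({RECOMBINASE}))

    def reporter_transgene(self) -> str:
        return self.transgenic(attributes=frozenset({REPORTER}))


def simulate_catalog(
    params: SimulationParams,
) -> tuple[Catalog, tuple[SourceAnnotation, ...]]:
    """Generate a reproducible synthetic catalog plus annotation table."""
    params.validate()
    rng = random.Random(params.seed)
    b = _Builder(rng)

    genes = [b.gene(f"Gene{i + 1}") for i in range(params.n_genes)]
    b.markers.append(MarkerRef(ROSA26_ID, "Gt(ROSA)26Sor", GENE))
    b.markers.append(MarkerRef(COL1A1_ID, "Col1a1", GENE))
    b.markers.append(MarkerRef(HPRT_ID, "Hprt", GENE))
    regions: list[str] = []
    for r in range(params.n_regions):
        member_ids = [b.gene(f"R{r + 1}g{j + 1}") for j in range(params.region_size)]
        rid = b.next_id("SIM")
        b.markers.append(
            MarkerRef(rid, f"Del(R{r + 1})", MULTI_GENIC_REGION, frozenset(member_ids))
        )
        regions.append(rid)

    archetype_names = sorted(a for a in params.mixture if params.mixture[a] > 0)
    weights = [params.mixture[a] for a in archetype_names]

    def pick_gene() -> str:
        return rng.choice(genes)

    def pick_genes(n: int) -> list[str]:
        return rng.sample(genes, n)

    for i in range(params.n_genotypes):
        kind = rng.choices(archetype_names, weights=weights, k=1)[0]
        conditional = rng.random() < params.p_conditional
        pairs: list[AllelePair] = []

        if kind == "single_gene":
            g = pick_gene()
            a = b.targeted(g)
            pairs = [AllelePair(a, a if rng.random() < 0.5 else b.wt_allele(g))]
        elif kind == "conditional_targeted":
            g = pick_gene()
            a = b.targeted(g, attributes=frozenset())
            pairs = [AllelePair(a, a), AllelePair(b.cre_transgene(), None)]
            conditional = True
        elif kind == "docking_cargo":
            site = rng.choice([ROSA26_ID, COL1A1_ID, HPRT_ID])
            cargo = pick_gene()
            a = b.targeted(
                site,
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(ExpressedGene(cargo, MOUSE),),
            )
            pairs = [AllelePair(a, None)]
            if rng.random() < 0.5:
                pairs.append(AllelePair(b.cre_transgene(), None))
                conditional = True
        elif kind == "docking_no_cargo":
            site = rng.choice([ROSA26_ID, COL1A1_ID, HPRT_ID])
            a = b.targeted(site, attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}))
            pairs = [AllelePair(a, a)]
        elif kind == "transgene_single_cargo":
            cargo = pick_gene()
            a = b.transgenic(
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(ExpressedGene(cargo, MOUSE),),
            )
            pairs = [AllelePair(a, None)]
            if rng.random() < 0.5:
                tta = b.transgenic(attributes=frozenset({TRANSACTIVATOR}))
                pairs.append(AllelePair(tta, None))
        elif kind == "transgene_same_gene":
            g = pick_gene()
            tg = b.transgenic(
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(ExpressedGene(g, MOUSE),),
            )
            mut = b.targeted(g)
            pairs = [AllelePair(mut, mut), AllelePair(tg, None)]
        elif kind == "transgene_multi_cargo":
            cargo = pick_genes(2)
            a = b.transgenic(
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=tuple(ExpressedGene(g, MOUSE) for g in cargo),
            )
            pairs = [AllelePair(a, None)]
        elif kind == "self_expressed":
            g = pick_gene()
            a = b.targeted(
                g,
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(ExpressedGene(g, MOUSE),),
            )
            pairs = [AllelePair(a, a), AllelePair(b.reporter_transgene(), None)]
        elif kind == "region":
            r = rng.choice(regions)
            a = b.targeted(r)
            pairs = [AllelePair(a, b.wt_allele(r))]
        elif kind == "two_regions":
            r1, r2 = rng.sample(regions, 2)
            pairs = [
                AllelePair(b.targeted(r1), None),
                AllelePair(b.targeted(r2), None),
            ]
        elif kind == "region_plus_gene":
            r = rng.choice(regions)
            g = pick_gene()
            a1, a2 = b.targeted(r), b.targeted(g)
            pairs = [AllelePair(a1, None), AllelePair(a2, a2)]
        elif kind == "digenic":
            g1, g2 = pick_genes(2)
            a1, a2 = b.targeted(g1), b.targeted(g2)
            pairs = [AllelePair(a1, a1), AllelePair(a2, a2)]
        elif kind == "non_mouse_cargo":
            g = pick_gene()
            a = b.targeted(
                g,
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(
                    ExpressedGene(f"HUMAN{rng.randrange(999):03d}", NON_MOUSE),
                ),
            )
            pairs = [AllelePair(a, b.wt_allele(g))]
        elif kind == "ki_cargo_other":
            g, cargo = pick_genes(2)
            a = b.targeted(
                g,
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(ExpressedGene(cargo, MOUSE),),
            )
            pairs = [AllelePair(a, a)]
        elif kind == "two_transgenes_cargo":
            g1, g2 = pick_genes(2)
            a1 = b.transgenic(
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(ExpressedGene(g1, MOUSE),),
            )
            a2 = b.transgenic(
                attributes=frozenset({INSERTED_EXPRESSED_SEQUENCE}),
                expressed_genes=(ExpressedGene(g2, MOUSE),),
            )
            pairs = [AllelePair(a1, None), AllelePair(a2, None)]
        elif kind == "all_tools":
            g = pick_gene()
            pairs = [
                AllelePair(b.wt_allele(g), b.wt_allele(g)),
                AllelePair(b.reporter_transgene(), None),
            ]
        else:  # pragma: no cover - guarded by params.validate
            raise AssertionError(kind)

        gid = b.next_id("SIMG")
        b.genotypes.append(
            Genotype(
                gid,
                tuple(pairs),
                is_conditional=conditional,
                strain_background=f"strain{rng.randrange(5)}",
            )
        )
        n_ann = rng.randrange(1, params.max_annotations_per_genotype + 1)
        for _ in range(n_ann):
            if rng.random() < 0.8:
                term = f"MP:97{rng.randrange(10000, 99999)}"
                ontology = PHENOTYPE
            else:
                term = f"OMIM:9{rng.randrange(10000, 99999)}"
                ontology = DISEASE
            b.annotations.append(
                SourceAnnotation(gid, term, ontology, reference=f"J:SIM{i}")
            )

    catalog = Catalog.build(b.markers, b.alleles, b.genotypes)
    return catalog, tuple(b.annotations)


# --- run summaries -------------------------------------------------------

_REMOVAL_CLASSES = {
    flt.CONDITIONAL_RECOMBINASE: "recombinase",
    flt.TRANSGENIC_REPORTER: "reporter_transgene",
    flt.TRANSGENIC_TRANSACTIVATOR: "transactivator_transgene",
    flt.WILD_TYPE: "wild_type",
}


@dataclass(frozen=True)
class RemovalCount:
    genotypes: int = 0
    alleles: int = 0


@dataclass(frozen=True)
class BreakdownReport:
    total_genotypes: int
    with_derived: int
    one_marker: int
    resolved_multi: int
    novel_markers_from_multi: int
    exclusions_by_reason: Mapping[str, int]
    removals_by_allele_class: Mapping[str, RemovalCount]


def summarize_run(traces: Iterable[DecisionTrace]) -> BreakdownReport:
    """Tabulate a derive run: outcome counts and tool-allele removals."""
    traces = list(traces)
    one_marker = 0
    resolved_multi = 0
    single_markers: set[str] = set()
    multi_markers: set[str] = set()
    exclusions: dict[str, int] = {}
    removal_genotypes: dict[str, set[str]] = {c: set() for c in _REMOVAL_CLASSES.values()}
    removal_alleles: dict[str, set[str]] = {c: set() for c in _REMOVAL_CLASSES.values()}

    for trace in traces:
        res = trace.resolution
        if res.annotate_markers:
            if res.terminal_box == dv.B1_SINGLE:
                one_marker += 1
                single_markers.update(res.annotate_markers)
            else:
                resolved_multi += 1
                multi_markers.update(res.annotate_markers)
        elif res.exclusion_reason is not None:
            exclusions[res.exclusion_reason] = (
                exclusions.get(res.exclusion_reason, 0) + 1
            )
        for verdict in trace.verdicts:
            if verdict.excluded:
                cls = _REMOVAL_CLASSES[verdict.reason]
                removal_genotypes[cls].add(trace.genotype_id)
                removal_alleles[cls].add(verdict.allele_id)

    return BreakdownReport(
        total_genotypes=len(traces),
        with_derived=one_marker + resolved_multi,
        one_marker=one_marker,
        resolved_multi=resolved_multi,
        novel_markers_from_multi=len(multi_markers - single_markers),
        exclusions_by_reason=dict(sorted(exclusions.items())),
        removals_by_allele_class={
            cls: RemovalCount(len(removal_genotypes[cls]), len(removal_alleles[cls]))
            for cls in sorted(removal_genotypes)
        },
    )
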
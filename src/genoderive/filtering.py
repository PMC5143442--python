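"""Identification and removal of non-causative (tool) alleles.

Four kinds of alleles never cause the annotated phenotypes and are
excluded before a genotype is resolved:

* wild-type alleles;
* transgenic transactivator alleles that express no gene beyond the
  transactivator itself;
* transgenic reporter alleles without the inserted-expressed-sequence
  attribute;
* recombinase alleles (transgenic or knock-in) in conditional genotypes
  that express no gene beyond the recombinase.

Knock-in reporters and transactivators are always retained, because they
are frequently also knock-outs of the targeted locus. A recombinase or
transactivator allele that expresses additional cargo genes is retained —
the cargo may be causative, and downstream rules decide what to annotate.
The recombinase/transactivator product itself (cre, tTA) has no mouse
ortholog and is never recorded among an allele's expressed genes, so
"expresses nothing but the tool product" is simply an empty
``expressed_genes`` list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    Allele,
    Catalog,
    Genotype,
    INSERTED_EXPRESSED_SEQUENCE,
    RECOMBINASE,
    REPORTER,
    TRANSACTIVATOR,
    TRANSGENIC,
)

RETAIN = "retain"
EXCLUDE = "exclude"

# exclusion reasons, in precedence order
WILD_TYPE = "wild_type"
TRANSGENIC_TRANSACTIVATOR = "transgenic_transactivator"
TRANSGENIC_REPORTER = "transgenic_reporter"
CONDITIONAL_RECOMBINASE = "conditional_recombinase"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class CausalityVerdict:
    allele_id: str
    verdict: str
    reason: str

    @property
    def excluded(self) -> bool:
        return self.verdict == EXCLUDE


def classify_allele_causality(allele: Allele, is_conditional: bool) -> CausalityVerdict:
    """Decide whether an allele is a non-causative tool.

    Classification depends only on the allele itself and the genotype's
    conditional flag, never on the other alleles present. The first
    matching rule (wild-type, transgenic transactivator, transgenic
    reporter, conditional recombinase) supplies the reason code.
    """
    expresses_cargo = len(allele.expressed_genes) > 0
    if allele.is_wild_type:
        reason = WILD_TYPE
    elif (
        allele.generation_method == TRANSGENIC
        and TRANSACTIVATOR in allele.attributes
        and not expresses_cargo
    ):
        reason = TRANSGENIC_TRANSACTIVATOR
    elif (
        allele.generation_method == TRANSGENIC
        and REPORTER in allele.attributes
        and INSERTED_EXPRESSED_SEQUENCE not in allele.attributes
    ):
        reason = TRANSGENIC_REPORTER
    elif RECOMBINASE in allele.attributes and is_conditional and not expresses_cargo:
        reason = CONDITIONAL_RECOMBINASE
    else:
        return CausalityVerdict(allele.id, RETAIN, NOT_APPLICABLE)
    return CausalityVerdict(allele.id, EXCLUDE, reason)


def filter_noncausative(
    genotype: Genotype, catalog: Catalog
) -> tuple[list[Allele], list[CausalityVerdict]]:
    """Classify every distinct allele of the genotype.

    Returns the retained alleles (in order of first appearance) plus all
    verdicts, including retains, for the decision trace. An all-tool
    genotype legitimately yields an empty retained list.
    """
    retained: list[Allele] = []
    verdicts: list[CausalityVerdict] = []
    for aid in genotype.distinct_allele_ids():
        allele = catalog.allele(aid, referrer=genotype.id)
        verdict = classify_allele_causality(allele, genotype.is_conditional)
        verdicts.append(verdict)
        if not verdict.excluded:
            retained.append(allele)
    return retained, verdicts
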
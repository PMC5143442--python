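# genoderive

Derive marker-level (gene, transgene, or multi-genic region) phenotype and
disease annotations from mouse *genotype*-level annotations.

Curated mouse genotypes frequently mix the causative mutation with
transgenic tools — cre/Flp recombinases, tTA transactivators, fluorescent
reporters — and wild-type partner alleles. `genoderive` filters those
non-causative alleles out and resolves each genotype to the marker(s)
whose mutation actually causes the annotated phenotypes, emitting derived
marker-to-term annotations plus a full per-genotype decision trace.

## How it works

1. **Locus accounting** (`genoderive.locus_accounting`) — count the
   genetic loci touched by a genotype's alleles: mutated endogenous genes,
   transgene markers, genes inside multi-genic deletion regions, and
   inserted expressed genes.
2. **Tool filtering** (`genoderive.filtering`) — exclude wild-type
   alleles, cargo-less transgenic transactivators, reporter-only
   transgenes, and (in conditional genotypes) cargo-less recombinase
   alleles, whether transgenic or knock-in.
3. **Resolution** (`genoderive.derivation`) — a staged rule engine maps
   the post-filter locus set to the causative marker(s): single-locus
   genotypes, multi-genic region markers, transgenes with expressed
   cargo, docking-site knock-ins (Gt(ROSA)26Sor / Col1a1 / Hprt), and the
   self-expressed knock-in case. Unresolvable multi-locus genotypes are
   excluded rather than guessed at. Gt(ROSA)26Sor never receives derived
   annotations.
4. **Fan-out** — every genotype-level annotation is propagated to the
   resolved markers, deduplicated on (marker, term, ontology) with merged
   provenance.

The docking-site list is configuration (`DerivationConfig`), not
inference; strain background is carried in traces but never consulted.

## CLI

```sh
# write the packaged worked-example catalog + annotations + expectations
genoderive fixtures --out examples/

# validate any catalog
genoderive validate --catalog examples/catalog.json

# run the derivation
genoderive derive --catalog examples/catalog.json \
    --annotations examples/annotations.tsv --out out/

# summarize a run from its trace document
genoderive report --traces out/traces.json

# generate a seeded synthetic catalog
genoderive simulate --out sim/ --seed 7 --genotypes 500
```

`derive` writes `derived_annotations.tsv` (sorted, byte-stable) and
`traces.json` (per-genotype verdicts, locus sets before/after filtering,
terminal rule, and exclusion reason). A YAML `--config` file may override
`docking_site_ids` / `never_self_annotate_ids`.

Catalogs are JSON documents with `markers`, `alleles`, and `genotypes`
arrays; annotation tables are TSV
(`genotype_id  term_id  ontology  qualifier  reference`) with `MP:` terms
for phenotypes and `OMIM:` terms for diseases.

## Python API

```python
import genoderive as gd

fx = gd.example_catalog()
derived, traces = gd.derive_annotations(fx.annotations, fx.catalog)
report = gd.summarize_run(traces)
```

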
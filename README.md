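# ptgr — in-silico cloning for the pTGR plasmid standard

`ptgr` is a Python toolkit for designing and virtually executing restriction
cloning on pTGR-style shuttle vectors for *Corynebacterium glutamicum*
engineering. The pTGR standard arranges eight parts around a circular
plasmid — host replicon, *E. coli* replicon, selectable marker,
transcriptional regulator, promoter/operator, ribosome binding site (RBS),
ORF and terminator — each flanked by a dedicated pair of unique restriction
sites so any part can be exchanged in one digestion/ligation cycle:

```
XbaI —promoter— NheI —RBS— NdeI —ORF— EcoRI ... AvrII —terminator— SpeI   (the TU cassette)
BamHI —regulator— BglII —E. coli ori— SphI —marker— PstI —host ori— KpnI  (the backbone)
```

The ORF's ATG is embedded in the NdeI site (CAT|ATG) and multi-gene
constructs are built with isocaudomer arithmetic: XbaI/SpeI/NheI/AvrII all
leave 5′-CTAG cohesive ends, so

* **operons** grow by moving an NheI–AvrII (RBS+ORF) cassette into the
  acceptor's unique AvrII site — the joint is a *dead* NheI/AvrII scar
  (`CCTAGC`, cut by neither enzyme) and AvrII is regenerated downstream;
* **gene clusters** grow by moving a whole XbaI–SpeI transcriptional unit
  into the acceptor's unique SpeI site — a dead XbaI/SpeI scar (`ACTAGA`)
  forms at the joint and SpeI is regenerated.

Because both moves are recursive, a design with *n* genes needs exactly
*n* cloning steps (one stage of parallel ORF insertions plus *n − 1*
cassette transfers). The package provides the digestion/ligation simulator,
the slot-grammar validator, the assembly planner/executor, a one-step gene
designer (codon preference + forbidden-site removal), GenBank/FASTA/JSON
IO, a deterministic synthetic fixture generator, and a CLI.

## Worked example

```python
from ptgr import (Design, GeneSpec, TuSpec, generate_fixtures,
                  plan_assembly, execute_plan, site_census)

registry, backbone = generate_fixtures(42)   # synthetic part stand-ins

operon = Design("demo-operon",
                (TuSpec("tac", (GeneSpec("sod_rbs", "mCherry"),
                                GeneSpec("sod_rbs", "eGFP"))),),
                replicon="pGA1")
plan = plan_assembly(operon, registry)
print("cloning steps:", plan.n_stages)
product = execute_plan(plan, registry)
census = site_census(product)
print("length:", len(product))
print({k: census[k] for k in ("NheI", "AvrII", "NdeI", "EcoRI")})
```

prints

```
cloning steps: 2
length: 5659
{'NheI': 1, 'AvrII': 1, 'NdeI': 2, 'EcoRI': 2}
```

Two cloning steps build the dual-reporter operon (one parallel-insertion
stage, one cassette transfer). In the product the NheI and AvrII sites are
again unique — the joint scar is dead and the downstream AvrII was
regenerated, so a third gene could be added the same way — while NdeI and
EcoRI are duplicated, one pair per gene, exactly as the extension predicts.

The same API covers part swaps (e.g. the host replicon via PstI/KpnI to
drop copy number from ~30 to 1–2 per cell), plasmid audits
(`validate_plasmid`), qualitative construct ranking from the measured
promoter/RBS/replicon strengths, fluorescence normalisation by fluorophore
brightness (eGFP 34, mCherry 16 1/(mM·cm)), and one-step ORF design
(`design_orf`).

A CLI mirrors the library 1:1
(`ptgr fixtures | validate | digest | assemble-tu | insert-orf |
extend-operon | extend-cluster | swap | plan | run-plan | series |
optimize`); exit status is 0 iff no error-severity finding occurred.

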
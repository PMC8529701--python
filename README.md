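# phytofoundry

Dry-lab tooling for biofoundry cell-free expression of plant proteins:
phytobrick part validation, in-silico Golden Gate assembly, combinatorial
construct design, acoustic-dispenser picklist compilation, HiBiT
luminescence quantification, and assay-planning calculators.

## Who this is for

Plant synthetic biologists and biofoundry engineers who assemble
phytobrick-standard DNA parts into cell-free protein synthesis (CFPS)
expression plasmids and screen tag configurations at nanoliter scale. The
package covers everything that happens *before and after* the wet bench:
checking that parts obey the fusion-site grammar, predicting the exact
assembly product, expanding tag × CDS screens, generating the instruction
CSV an acoustic liquid handler executes, and turning plate-reader numbers
back into protein concentrations.

## The model

**Fusion-site grammar.** Every cloneable part carries two 4-nt fusion
sites, written as the top-strand 5'→3' 4-mer. The toolkit grammar is

| category | 5' site | 3' site |
|---|---|---|
| N-terminal tag | `CCAT` | `AATG` |
| CDS (no stop) | `AATG` | `TTCG` |
| C-terminal tag (with stop) | `TTCG` | `GCTT` |
| expression acceptor | `AATG` or `CCAT` | `GCTT` |

so any acceptor + (optional N-tag) + CDS + C-tag chain ligates in exactly
one order, and the `AATG` junction supplies the start codon.

**Golden Gate simulation.** A Type IIS enzyme (BsaI-class `GGTCTC(N1)` or
BpiI-class `GAAGAC(N2)`) cuts at a fixed offset outside its recognition
site, leaving 4-nt 5' overhangs. For a sense site ending at position *e*,
the top-strand cut is at *e + spacer* and the overhang is
`seq[t:t+4]`. Digestion yields fragments with boundary overhangs; ligation
joins fragments wherever one fragment's right overhang equals the next
one's left overhang, and a closed chain is a circular product. Because
recognition sites face away from retained fragments, a correct assembly
eliminates every site — the reaction converges and the product cannot be
re-cut.

**Reaction layout.** Miniaturized CFPS reactions are compiled as a
two-step picklist: 1735 nl master mix plus a 265-nl cherry-pick carrying
26.6 ng plasmid topped up with water — a 2000-nl reaction at 13.3 ng/µl
template. Volumes are quantized to the 2.5-nl droplet and each 65-µl
master-mix source well supports `floor((65000 − 30000)/1735) = 20`
transfers before spilling to the next well.

**Quantification.** An 11-residue HiBiT peptide tag complements an added
18-kDa partner into an active luciferase, so luminescence is linear in
tagged-protein concentration: `RLU = slope·[nM] + intercept`, fitted over
a 0.01–2 nM control-protein standard curve, with diluted CFPS readings
back-calculated and converted by `µg/ml = µM × kDa`.

## Worked example

```python
from phytofoundry import fixtures, designer, foundry, quant

config = fixtures.FixtureConfig(seed=42)
registry, spec = fixtures.design_fixture(config)      # 11 CDS x 8 configurations
orders = designer.expand_design(spec, registry)
construct = designer.assemble_order(orders[0], registry)
protein = designer.extract_fusion_orf(construct)
picklist = foundry.compile_cfps_picklist(
    [(o.construct_id, 150.0, foundry.well_name(i % 16, i // 16))
     for i, o in enumerate(orders)], replicates=3)
```

prints, step by step:

```
expanded 88 construct orders
first order: pEPQD0KN0024 + None + pSYNUGT01 + pEPYC0CM0257
assembled 2897 bp circular product, junctions GCTT-AATG-TTCG
fusion protein: 129 aa, 14.0 kDa
tags: [('NET', 0, 5), ('HiBiT', 118, 129)]
picklist: 792 transfers into 264 wells, final template 13.3 ng/ul
```

The 88 orders are the full cross product of 8 grammar-compatible
tag/acceptor configurations with 11 coding sequences. The first construct
uses the MEKKI expression-tag acceptor tagless (hence 3 junctions, no
`CCAT`), translates to a fusion starting `MEKKI` and ending in the
11-residue HiBiT tag, and the three-replicate picklist fills 264 wells at
2000 nl each with the template at 13.3 ng/µl.

Quantifying a simulated plate read back through the standard curve:

```
standard curve: slope 9.98e+05 RLU/nM, r^2 0.9995
sample: 41.6 uM (1134 ug/ml)
```

i.e. a 41.8 µM ground-truth sample diluted 10^5-fold is recovered within
the 2% read noise, and converts to mass concentration via its 27.27 kDa
chain weight.

There is also a CLI for the common operations:

```
phytofoundry registry validate <registry.csv>
phytofoundry assemble --acceptor pEPQD0KN0245 --parts pEPQD0CM0543,pEPQD0CM0296,pEPYC0CM0257
phytofoundry assay mz --formula C10H18O --glucoside --adduct M+H
phytofoundry fixtures build --seed 42 --out fixtures/
```

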
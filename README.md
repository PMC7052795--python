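# loopasm

In-silico recursive Type IIS (Golden Gate) DNA assembly: a simulator and
planner for the alternating BsaI/SapI "odd/even" assembly scheme.  It models
one-pot digestion-ligation reactions as end-state chemistry, enforces the
overhang grammar and part-position syntax, plans hierarchical multi-TU
constructs up to a receiver-free level-4 linear assembly, predicts
verification readouts (restriction digest profiles, in-silico PCR with the
standard UNS primer pair), and emits bench recipes.

## What is modeled

- **seqio** — annotated linear/circular DNA records with wrap-aware feature
  spans, GenBank/FASTA round-tripping, canonical rotation for plasmid
  identity, translation.
- **typeiis** — enzyme-agnostic Type IIS site scanning, sticky-fragment
  digestion (exact length conservation on circles), exhaustive ligation
  product enumeration with a combinatorial-explosion guard, one-pot assembly
  with intended / parental / misassembly classification, overhang fidelity
  checks.
- **schema** — the grammar layer: overhang alphabets (SapI codes
  alpha=ATG, beta=GCA, gamma=TAC, epsilon=CAG, omega=GGT; BsaI codes A-F as
  replaceable config), receiver construction for four kits x two parities x
  four positions, part nomenclature (`CE_sfGFP` style), SapI-mediated L0
  entry, and domestication (recognition-site removal, synonymous inside
  CDSs, transition edits elsewhere, iterated to a fixpoint).
- **planner** — design trees, parity/marker-alternation validation,
  bottom-up simulation of every node, composition censuses (TU and part
  counts), and 10 ul reaction recipes (15 fmol parts / 7.5 fmol receiver,
  parity-specific master mixes, regular/short cycling, 1x/2x enzyme).
- **verify** — digest profiles and tolerance-based band matching,
  in-silico PCR, efficiency/productivity colony-count calculators, and
  concatemer ladders for receiver-free reactions.
- **fixtures** — a deterministic synthetic data generator (seeded) for
  kits, the L0 part catalog, and the published test-assembly trees
  (`L1-4_sfGFP` ... `L4`), so everything runs offline.

## CLI

```sh
loopasm fixtures --seed 42 --out-dir fixtures/        # write synthetic kit/parts/designs
loopasm scan --enzyme bsai fixtures/receivers.gb
loopasm assemble --receiver R.gb --parts p1.gb --parts p2.gb \
    --enzyme bsai --out product.gb --report report.json
loopasm plan --design fixtures/design_L3-4_sfGFP.json --seed 42
loopasm simulate --design fixtures/design_L2-4_sfGFP.json --seed 42 --out-dir products/
loopasm recipe --design fixtures/design_L1-4_sfGFP.json --node L1-4_sfGFP \
    --conc conc.csv --seed 42
loopasm digest --enzymes bsai,sapi product.gb
loopasm pcr product.gb                                # default UNS primer pair
loopasm metrics --sfgfp 91 --white 9 --blue 5
```

## Notes

- Python API mirrors the CLI: see `loopasm.fixtures.generate_library`,
  `loopasm.planner.plan_design` / `simulate_plan` / `count_composition`,
  and `loopasm.typeiis.one_pot_assemble`.
- Kinetics, methylation sensitivity, and gel mobility are deliberately out
  of scope; products are classified by end-state recognition-site logic.
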
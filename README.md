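# tfrctx

Genome-context prediction of regulatory targets for TetR-family
transcriptional regulators (TFRs).

## The problem

TFRs are one of the largest families of bacterial one-component
transcription factors: a conserved N-terminal helix-turn-helix
(Pfam PF00440, TetR_N) and a variable C-terminal ligand-binding domain.
Tens of thousands are known from genome sequencing; almost none have a
known target gene. The founding member, TetR, represses the divergently
transcribed efflux-pump gene *tetA*, the two promoters sharing an
intergenic region that carries two 15 bp palindromic operators bound by
the TetR dimer.

That arrangement generalises into a usable prediction rule. Surveying
streptomycete genomes, most TFR genes sit head-to-head with one neighbor,
and the ones whose translational starts are within **200 bp** of that
neighbor's are, essentially always, its direct (usually repressing)
regulator. `tfrctx` implements this genome-context method end to end:

- **context classification** — each TFR gene is placed in one of three
  groups by orientation to its immediate neighbors: *divergent*
  (head-to-head, at any distance), *operonic* (same strand within a 35 bp
  ORF-to-ORF gap, hence probably co-transcribed), or *other*;
- **separation measurement** — for divergent pairs, the count of bases
  strictly between the first bases of the two start codons (transcription
  starts being unknown for almost all of these genes);
- **target prediction** — the ≤200 bp rule (inclusive by default; a flag
  selects strict `<`);
- **product typing** — predicted targets sorted into enzymes by EC class
  1–6, membrane transporters by family (MFS/ABC/RND/other), other membrane
  proteins, other proteins, and unknowns, from product text and supplied
  conserved-domain hit tables via a priority-ordered rule table;
- **operator discovery** — inverted-repeat scanning of intergenic DNA
  (arms, loop, mismatch budget), degenerate-consensus construction and
  IUPAC consensus matching, and placement of sites within the intergenic
  region relative to the two genes;
- **synthetic genomes** — a generator that plants TFR contexts,
  separations, product labels and palindromic operators with full ground
  truth, so the whole pipeline is testable without downloads.

## Worked example

`examples/01_distance_rule_panel.py` applies the distance rule to the
packaged panel of nine experimentally characterized regulator/neighbor
pairs:

```
regulator  target    separation  predicted  observed
ActR       SCO5083       110 bp  True       repressed
SCO4099    SCO4098       139 bp  True       repressed
SGR3979    SGR3978       144 bp  True       repressed
SCO7222    SCO7223       146 bp  True       repressed
SCO3367    SCO3366       158 bp  True       repressed
SGR5269    SGR5270       212 bp  False      none
SGR6912    SGR6911       280 bp  False      none
AtrA       SCO4119       425 bp  False      activated
SGR3402    SGR3403       601 bp  False      none

5 of 9 divergent pairs fall within 200 bp.
```

The five pairs within 200 bp are exactly the five where the regulator was
shown to repress the divergent neighbor; none of the four beyond 200 bp
shows repression. `examples/03_operator_discovery.py` scans the
footprinted operators — the three SCO7222 sites are perfect arm-7
palindromes around a 1 nt loop whose rebuilt consensus is
`TGGAACGNCGTTCCA` — and the other examples run the synthetic pipeline and
the survey report.

The same functionality is exposed as a CLI:

```sh
tfrctx simulate --seed 4 -o sim/
tfrctx classify --genbank sim/fixture.gbk --tfrs sim/tfrs.txt -o out/
tfrctx operators --fasta out/igr.fasta --consensus TGGAACGNCGTTCCA -o ops/
tfrctx summarize --classification out/classification.tsv -o report/
```

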
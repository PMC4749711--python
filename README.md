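# spacertyper

Typing and comparative analysis of the bacterial **16S–23S rRNA
intergenic spacer (ITS)** — the hypervariable region that separates
closely related strains when the 16S rRNA gene cannot. The package was
built around the spacer biology of sphingomonads (α-Proteobacteria
common in oligotrophic drinking water), where spacers of 415–849 bp and
42.2–57.9 mol% G+C fall into five arrangement types by their tRNA gene
content, and the ITS-2 sub-spacer between the two tRNA genes is the
discriminating marker.

It is a library first (`import spacertyper`), with narrative scripts in
`examples/` and a thin `spacertyper` CLI for shell use.

## What it does

- **In-silico PCR** with degenerate IUPAC primers (both published assay
  sets ship with the package) and excision of the spacer strictly
  between the primer footprints.
- **tRNA gene detection** with a transparent rule-based cloverleaf
  scanner (acceptor/D/anticodon/T arms, pair scores GC 3 / AT 2 / GT 1,
  `TTC` T-loop signature) including operational **pseudo-tRNA**
  flagging.
- **ITS typing**: `ITS_none`, `ITS_Ala`, `ITS_AlaIle`, `ITS_IleAla`,
  `ITS_IlePseudo` (plus `ITS_other`); ITS-1/2/3 partition and ITS-2
  size-group binning (16–19 / 60–61 / 122–138 nt).
- **Alignment & conservation**: affine-gap progressive MSA, pairwise
  percent-identity summaries, conserved-block discovery (e.g. the
  `CCAACCAT` / `TGGT` ITS-2 boundary motifs), indel-event counting and
  group-level length-stretch location.
- **Phylogeny**: complete deletion → JC69 distances
  (`d = −¾ ln(1 − 4p/3)`) → neighbor joining → ML branch lengths by
  Felsenstein pruning → seeded bootstrap with majority-rule consensus
  and percent supports.
- **ITS-2 folding**: Nussinov-style hairpin prediction with stacking
  bonus; long-stem vs short-hairpin (putative RNase III target)
  classification.
- **Synthetic panels**: a seeded generator of whole operon panels
  (default: 14 reference clades + 23 isolates) with complete ground
  truth, used throughout the tests.

## Worked example

```python
from spacertyper import PanelConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(simulate=PanelConfig(seed=42), seed=42, bootstrap_reps=100)
report = run_pipeline(cfg)
print(report["metadata"]["n_annotated"])            # 37
print(report["type_summary"]["most_common_type"])   # ITS_AlaIle
print(report["conservation"]["ITS-2"])
print(report["tree"]["n_leaves"], report["tree"]["n_informative_columns"])
```

prints

```
37
ITS_AlaIle
{'mean_pid': 22.66, 'sd_pid': 6.96, 'min_pid': 11.01, 'max_pid': 61.29, 'n': 36}
37 56
```

meaning: all 37 simulated operons were excised and typed, the dominant
arrangement is tRNA-Ala followed by tRNA-Ile (as in real sphingomonad
panels), the ITS-2 regions average ~23 % pairwise identity (the
hallmark hypervariability of this sub-spacer), and the bootstrap
consensus tree covers all 37 sequences using the 56 alignment columns
that survive complete deletion. The same stages are available piecewise
— see `examples/01_simulate_panel.py` through `examples/05_fold_its2.py`,
each of which prints and explains its own numbers.

From the shell:

```bash
spacertyper simulate --seed 42 --out-prefix panel
spacertyper run --seed 42 --reps 100 --out report.json
spacertyper report report.json
```

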
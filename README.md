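# vusworm

Functional interpretation of ciliopathy-associated missense variants of
uncertain significance (VUS) from quantitative *C. elegans* assays.

Most missense variants in clinical databases cannot be classified as benign
or pathogenic from sequence evidence alone. For cilia genes such as
*TMEM67/MKS3*, patient variants can be knocked into the orthologous worm
gene (*mks-3*) and their effect on sensory-cilium structure and function
measured directly. `vusworm` implements the quantitative analysis behind
that strategy, for geneticists and worm labs running such assay panels:

* **Assay metrics** — per-worm dye-filling scores (0–4 filled phasmid
  neurons), roaming counts normalized per replicate to wild-type (N2), and
  the per-plate chemotaxis index *(b − c)/n*.
* **Statistics** — Shapiro–Wilk routing, Kruskal–Wallis with mid-ranks and
  tie correction, Dunn's post hoc with configurable multiplicity adjustment,
  the Schaich–Hammerle chi-squared critical-difference post hoc (for heavily
  tied ordinal dye-fill data), and one-way ANOVA with Tukey's HSD.
* **Integrated score** — each strain's three assay averages are normalized
  to the `mks-3(+); nphp-4(Δ)` positive control, capped at 1.0, and summed
  into a score on [0, 3]; strains scoring **< 2.5** are interpreted as
  carrying a pathogenic variant.
* **Orthogonal quantifications** — TZ::GFP reporter intensity with 40×40 px
  boxed background subtraction (42×42 px ring), percent localization calls,
  ROR2 phospho-induction percentages from western densitometry, and
  cumulative/shell GDT model-quality scores.
* **Synthetic data** — because no raw per-worm records are deposited, a
  calibrated 15-strain generator panel (wild-type, control, null, two known
  benign, two known pathogenic, eight VUS) reproduces the statistical
  structure of each assay so the whole pipeline is testable end to end.

## Worked example

Run the full simulate → summarize → test → score pipeline on the built-in
panel:

```bash
vusworm report --seed 1 --outdir results/demo
```

which prints the ranked score table (abridged):

```
strain                      dyefill  roaming  chemotaxis  score   classification
mks-3(+);nphp-4(delta)      1.000    1.000    1.000       3.000   benign
Benign1                     1.000    1.000    0.957       2.957   benign
VUS3                        1.000    1.000    0.783       2.783   benign
VUS8                        0.343    0.473    0.775       1.591   pathogenic
VUS1                        0.353    1.000    0.160       1.513   pathogenic
mks-3(delta);nphp-4(delta)  0.378    0.471    0.524       1.373   pathogenic
Pathogenic2                 0.318    0.436    0.128       0.882   pathogenic
```

Each row shows the three control-normalized assay components (1.0 = at or
above the control average), their sum, and the < 2.5 classification. The
control scores exactly 3.0 against itself; the *mks-3* deletion null falls
well below the cutoff; VUS2/3/7 classify benign and VUS1/4/5/6/8 pathogenic.

Library use mirrors the CLI:

```python
from vusworm import GDTInput, gdt_score
gdt_score(GDTInput((0.5, 1.5, 3.0, 9.0), length=4))  # 118.75
```

Other subcommands: `simulate` (write raw assay TSVs), `score`, `stats`,
`quantify-tz`, `ror2`, `gdt`. All validation failures exit with code 2,
I/O failures with code 3.

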
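# nrlkit

Nucleosome repeat length (NRL) estimation and strand-aware nucleosome-array
analysis around oriented DNA motifs, for chromatin biologists working with
MNase-seq or chemical nucleosome maps.

Architectural proteins such as CTCF phase long nucleosome arrays around
their binding sites: a nucleosome-depleted region (NDR) sits asymmetrically
~41 bp 5' of the motif centre, the first downstream nucleosome at +105 bp,
and the spacing of the arrays tightens as binding strength grows.  `nrlkit`
measures these signatures from BED-level nucleosome maps:

- **Phasograms & NRL** — histogram of pairwise dyad distances within
  anchored windows; the NRL is the OLS slope of smoothed-peak position vs
  peak order, `NRL = d(position)/d(order)`, accepted when the regression
  F-test gives p < 0.05.  Peak picking is automated (prominence-filtered
  local maxima, greedy minimum separation).
- **Interference diagnostic** — shows why windows spanning the anchor mix
  same-side and cross-NDR distances, producing extra peaks and a spuriously
  small naive NRL; flanking windows such as [100, 2000] give the honest
  estimate.
- **Motif affinity** — JASPAR PFM scanning at a relative log-odds threshold
  (both strands), TRAP total binding affinity
  `sum_i R0 e^{-E_i} / (1 + R0 e^{-E_i})` over a ±30 bp extended context,
  evidence/TSS filtering, and stratification into binding-strength
  quintiles Q1–Q5.
- **Aggregate profiles** — strand-oriented occupancy / GC / interval-density
  profiles with edge-aware means, NDR localisation, and a per-side
  asymmetry report.
- **Interval annotation** — TAD common/lost/gained classification by
  fractional coverage (>90% / <80%), per-quintile feature enrichment, and
  oriented flank read counting.
- **Synthetic data** — a generator for phased arrays with configurable
  per-side spacing, jitter, NDR geometry, depth and background, making
  every downstream stage testable without downloads.

See `docs/methods.md` for the model and every default, and `examples/` for
one short runnable script per capability.

## Worked example

```python
import nrlkit as nk

anchors = nk.generate_anchor_sites(500, 2_600_000, seed=1)
model = nk.ArrayModel()            # 186 bp spacing, NDR at -41 bp
dyads = nk.generate_nucleosome_map(anchors, model,
                                   genome_size=2_600_000, seed=2)
est = nk.nrl_for_anchors(dyads, anchors, side="downstream")
print(f"{est.nrl_bp:.2f} +- {est.slope_sd:.2f} bp, p = {est.p_value:.3g}")
```

prints

```
185.47 +- 0.19 bp, p = 1.39e-21
```

i.e. the 186 bp generating spacing is recovered within a base pair from the
slope of ten phasogram peaks, and the linear fit is highly significant.
Running `python examples/04_interference_artifact.py` shows the companion
failure mode:

```
true spacing                  : 186 bp
flanking [100, 2000] estimate : 185.9 bp
spanning [-500, 500] estimate : 129.8 bp
extra interference peaks      : [292, 478, 664, 850]
artefact-prone                : True
```

— the window that includes the anchor itself under-estimates the repeat
length by ~56 bp, which is exactly why the anchor must be excluded from NRL
windows.

## Command line

A thin CLI wraps the library for batch use:

```bash
nrlkit simulate --seed 1 --out sim/            # synthetic dataset
nrlkit nrl sim/dyads.bed sim/anchors.bed --side downstream
nrlkit scan genome.fa motif.jaspar --out hits.bed --threshold 0.8
nrlkit interference sim/dyads.bed sim/anchors.bed
nrlkit demo --seed 1 --out demo/               # end-to-end report
```

Subcommands: `simulate`, `scan`, `trap`, `stratify`, `filter`, `phasogram`,
`nrl`, `interference`, `profile`, `enrich`, `tads`, `flanks`, `demo`.

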
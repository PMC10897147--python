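# turnoverms

Protein-turnover analysis for pulse-step stable-isotope labeling proteomics.

## The problem

In metabolic labeling experiments, an animal is switched to an isotopically
heavy diet (¹⁵N-enriched chow, or ¹³C₆-lysine) for a fixed window. Proteins
synthesized during the window incorporate heavy atoms; proteins made before it
stay light. For each protein the **fractional abundance**

```
FA = I_old / (I_old + I_new)
```

— the integrated signal of the pre-existing ("old") species over the total —
measures how much of that protein pool survived the labeling window, i.e. its
relative turnover. Stepping the labeling window across ages (9–12, 12–15,
15–18, 18–21, 21–24 months in the mouse-brain design this package models)
turns FA into a trajectory over the aging continuum, from which trend
clusters, compartment enrichments, sex differences and proteasome-complex
contrasts can be read.

`turnoverms` implements that analysis as a tested pipeline for researchers
working with such cohorts (or wanting to validate analysis choices against
simulated ones):

- **isotope** — exact isotopologue envelopes for peptides under natural,
  ¹⁵N-enriched (per-atom probability *p*) and ¹³C₆-lysine label schemes, by
  convolution of per-element isotope distributions; TMT/carbamidomethyl/diGly
  modifications built in.
- **ms1** — extracted-ion-chromatogram (XIC) reconstruction of old/new species
  areas, NNLS deconvolution of mixed envelopes, peptide FA, and the standard
  identification filters (length ≥ 5, q ≤ 0.01, optional diGly +114.042927
  subset).
- **tmt** — split-pool TMT quantification: channel-total loading
  normalization, bridge-channel alignment across plexes, per-protein
  per-channel FA from separated old/new PSM pools.
- **stats** — area-weighted peptide→protein rollup, NSAF abundance, group
  comparisons (one-way ANOVA + Tukey, Kruskal–Wallis + Dunn/BH or
  Tukey-on-ranks, Welch/Student t, two-way ANOVA), reference-group median
  adjustment, 19S vs 20S proteasome complex contrasts, volcano-style
  differential abundance with BH-FDR.
- **cluster** — row z-scoring, k-means trend clustering with
  silhouette-selected k under a minimum cluster size (sklearn-style
  `TrendClusterer` estimator), and sample-space PCA.
- **enrich** — one-sided Fisher overrepresentation against GMT term sets with
  BH-FDR, combined (−log₁₀FDR × log₂fold) term ranking, and 2×2 set-overlap
  tests.
- **simulate** — a synthetic-cohort generator with first-order kinetics and a
  long-lived fraction, `FA = λ + (1−λ)·exp(−k(a)·T)`, planted trend
  archetypes tied to compartment annotations, a sex-shifted profile,
  proteasome subunit groups, and a 7-day ¹³C₆-lysine pulse with partial
  degradation inhibition — so every stage can be validated against exact
  ground truth.
- **io / cli** — documented TSV/CSV/GMT/FASTA formats and a
  `turnoverms` command chaining the stages (`simulate`, `quant-ms1`,
  `quant-tmt`, `rollup`, `cluster`, `enrich`, `diff`, `report`).

## Worked example

Simulate a small one-sex cohort, quantify it back from simulated MS1 spectra,
and cluster the aging trends:

```python
import numpy as np
from turnoverms import simulate as sim, workflows as wf

design = sim.CohortDesign(sexes=("M",), replicates=3, seed=7)
panel = sim.make_panel(n_proteins=60, seed=7)
truth = sim.simulate_truth(design, panel)

est, tru = wf.ms1_round_trip(truth, noise_cv=0.10, seed=7,
                             samples=list(truth.samples.index[:6]))
diff = (est.values - tru.values).to_numpy()
print(f"proteins quantified: {est.values.shape[0]}")
print(f"FA RMSE vs truth:    {np.sqrt(np.nanmean(diff**2)):.4f}")

res = wf.aging_trend_analysis(truth.truth_matrix(), seed=7)
print(f"selected k:          {res['clusterer'].n_clusters_}")

terms = sim.annotation_fixture(panel, seed=7)
ranked = wf.cluster_enrichment(res["labels"], set(truth.replicate_fa.index), terms)
top = ranked[0].iloc[0]
print(f"cluster 0 top term:  {top['name']} (fold {top['fold_enrichment']:.1f}, FDR {top['fdr']:.2e})")
```

Output:

```
proteins quantified: 60
FA RMSE vs truth:    0.0034
selected k:          5
cluster 0 top term:  nucleosome (fold 5.0, FDR 1.79e-11)
```

The RMSE of 0.0034 says the XIC quantification recovers each protein's
per-replicate FA to well under one percentage point at 10 % peak-intensity
noise; the clusterer finds exactly the five planted trend archetypes, and the
planted compartment term tops its cluster's enrichment at a vanishing FDR.

The same chain is available from the shell:

```bash
turnoverms simulate --seed 7 --out run/sim --n-proteins 60 --sexes M --replicates 3 --with-ms1
turnoverms cluster  --fa-matrix run/sim/truth_fa.csv --seed 7 --out run/cluster
turnoverms enrich   --clusters run/cluster/clusters.csv --gmt run/sim/annotations.gmt \
                    --background run/sim/truth_fa.csv --out run/enrich
turnoverms report   --run-dir run --out run/report.json
```

## File formats

- **PSM TSV**: `sequence` (bracketed mass deltas allowed, e.g.
  `K[229.1629]`), optional `protein`, `pool` (`old`/`new`), `charge`,
  `sample`, `q_value`, `modifications`.
- **Spectra TSV**: one centroid peak per row — `scan, rt, mz, intensity`
  (mzML is read via pyteomics when installed).
- **Species TSV**: per (peptide, pool) theoretical lines, `mz` and
  `abundance` as `;`-joined floats, plus elution apex `rt`.
- **Reporter TSV** + plex-layout JSON: `psm_id, protein, channel_126…`, with
  `channel_map` and the bridge channel in the layout.
- **FaMatrix CSV**: `#age/#sex/#fraction/#treatment/#replicate` header block,
  then proteins × samples.
- **GMT**: `term<TAB>description<TAB>member…`.

## Scope notes

Database searching, peak picking from profile data, retention-time alignment,
isotopic-impurity correction and fragment-ion modeling are out of scope: the
pipeline consumes identified PSM tables and centroided MS1 spectra.
See `docs/methods.md` for the model, parameter defaults and limitations.
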
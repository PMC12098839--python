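# plexquant

Quantitation and trend analysis for TMTpro 18-plex proteomics with
detector-saturation quality control.

On high-sensitivity MS2 instruments, reporter ions that reach ~10⁶
detector units saturate the detector: the two 0.006 Da-spaced ¹³C/¹⁵N
isotopolog peaks of a reporter pair *coalesce* into a single distorted
peak whose apparent resolving power drops below the ~45,000 needed to
separate the pair — and whose intensity can no longer be apportioned
between the two channels. Dim scans fail the same resolution gate for
the opposite reason. `plexquant` is a toolkit for proteomics cores and
analysts working with TMTpro 18-plex data who need to (1) extract
per-channel reporter observations from MS2 scans under a peak-match
tolerance, (2) remove PSMs corrupted by saturation or low signal,
(3) roll retained PSMs up to a normalized protein × channel matrix, and
(4) model age and sex abundance trends across a cohort.

## The filter and the model

A peptide-spectrum match (PSM) is removed when

- any matched reporter ion has resolving power **R < 45,000**, or
- the summed signal-to-noise across the 18 channels is
  **ΣS/N < 1440** (an average of 80 per channel).

Retained PSMs are summed to proteins per channel on the S/N scale, each
channel is rescaled to a common total (equal loading), and log₂ values
are modeled per protein by ordinary least squares:

    log2(protein) = intercept + age + sex              [+ age×sex]

with age either continuous (months) or categorical. Each term is tested
with a partial F-test against the model without it, Benjamini–Hochberg
adjusted across proteins. Continuous vs non-continuous age trajectories
are compared by BIC (lower wins); significant trajectories are
categorized into stepwise trends ("Up-Up", "Up-Down", …) by testing
adjacent-age contrasts; a joint model with an age×tissue interaction
separates proteins aging consistently across tissues from
tissue-specific ones; gene-set over-representation uses the upper-tail
hypergeometric test. Simulators for reporter scans (with an explicit
coalescence model) and for multi-tissue cohorts (with planted effects
and exported ground truth) make every stage testable without raw data.
See `docs/methods.md` for the full model description and assumptions.

## Worked example

```python
import numpy as np
from plexquant import (CohortSpec, analyze_matrix, detect_coalescence,
                       simulate_cohort, simulate_reporter_scan)
from plexquant.reference import channel_labels, isotopolog_pairs
from plexquant.simulate import protein_matrix_from_peptides

# --- a reporter scan with six saturated isotopolog pairs -------------
labels = list(channel_labels())
intens = np.full(18, 5e4)
for n_m, c_m in isotopolog_pairs()[:6]:
    intens[labels.index(n_m.label)] = 3e6   # saturated
    intens[labels.index(c_m.label)] = 1e6
scan, truth = simulate_reporter_scan(intens, seed=1)
print(f"peaks in reporter region: {len(scan.peaks)}")
ev = detect_coalescence(scan)[0]
print(f"merged {ev.low_label}/{ev.high_label} at m/z {ev.merged_mz:.4f} "
      f"(+{ev.offset_to_low:.4f} / -{ev.offset_to_high:.4f} Da)")

# --- an aging cohort: 3 ages x 2 sexes x 3 replicates ----------------
pep, design, _ = simulate_cohort(CohortSpec(n_proteins=400, seed=8))
mat = np.log2(protein_matrix_from_peptides(pep))
res = analyze_matrix(mat, design)
sig = res["fdr_age"] < 0.1
print(f"proteins with age differences (FDR<0.1): {int(sig.sum())}/400")
print(res.loc[sig, "age_model_class"].value_counts().to_dict())
```

prints

```
peaks in reporter region: 12
merged 127N/127C at m/z 127.1263 (+0.0016 / -0.0047 Da)
proteins with age differences (FDR<0.1): 58/400
{'continuous': 35, 'non-continuous': 23}
```

Twelve peaks instead of 18: the six saturated pairs each collapsed to
one peak, sitting between the pair's theoretical positions (offsets sum
to the 0.0063 Da pair spacing) with sub-45 K resolving power, so every
affected PSM is caught by the resolution filter. In the cohort, 58 of
400 proteins show an age difference at FDR < 0.1 — the simulator plants
effects in ~20% of proteins — and the BIC split classifies most of the
detected trajectories as continuous, with planted step patterns making
up the non-continuous class.

The same pipeline is scriptable from the shell:

```sh
plexquant extract --scans scans.tsv --psms psms.tsv --tolerance 0.001 --out quant.tsv
plexquant filter --psms quant.tsv --out retained.tsv --audit audit.tsv
plexquant quantify --psms retained.tsv --out matrix.tsv
plexquant trends --matrix matrix.tsv --design design.tsv --log2 --out trends.tsv
plexquant enrich --results trends.tsv --gmt sets.gmt --out enrich.tsv
```

## Layout

| module | contents |
| --- | --- |
| `plexquant.reference` | TMTpro 18-plex channel table, exact m/z, isotopolog pairs |
| `plexquant.extraction` | peak→channel matching, PSM records, mzML/TSV I/O |
| `plexquant.qc` | resolution + S/N filter, bimodality diagnostic, coalescence detection |
| `plexquant.quantify` | protein roll-up, channel normalization, log₂ transform |
| `plexquant.simulate` | reporter-scan and cohort simulators with ground truth |
| `plexquant.trends` | OLS/F-tests, BH-FDR, BIC classification, stepwise categories, cross-tissue tests, hypergeometric enrichment |
| `plexquant.cli` | `plexquant` command-line entry points |
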
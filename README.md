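# msdeconv

Deconvolution and annotation of LC-ESI-MS metabolomics peak tables, with
first-class support for U-¹³C-labeling experiments.

Starting from an XCMS-style peak table (one chromatogram), the pipeline

1. detects isotopologue chains — natural patterns with increasing m/z and
   decreasing intensity, and *mirrored* chains descending from fully
   ¹³C-labeled monoisotopic peaks;
2. assembles **pseudo spectra**: groups of peaks whose m/z distances match
   a configurable list of adducts and neutral losses, anchored by seed
   adducts (e.g. `[M+H]+`, `[M+Na]+`, `[M+K]+`);
3. associates ¹³C monoisotopic peaks with their ¹²C counterparts at a
   distance of `n × 1.003355 / z` Da, with `n` restricted to carbon counts
   plausible under mass decomposition;
4. annotates homoadducts (`[2M+H]+`) including mixed-label species
   (`[2M+5+H]+`);
5. explains *large uncommon neutral losses* by searching constrained
   sum-formula triplets `s_primary = s_fragment + s_loss`, each member
   decomposed with an exact carbon count inferred from the labeling
   distances — unique triplets set the loss formula, multiple survivors
   are flagged ambiguous;
6. optionally prunes members whose EIC correlation to the primary peak
   falls below a threshold.

Around the pipeline: spectrum-aware mass decomposition with a
plausibility-filter stack (element bounds, element-probability and
element-ratio heuristics, Senior and Lewis/RDBE rules, an O ≥ 3.3 × P rule,
required-subformula and fixed-carbon constraints), mass-isotopomer-ratio
quantitation with Student's t / Benjamini–Hochberg statistics,
dot-product reference lists reusable across chromatograms, matching against
local MassBank-format record files, CSV/TSV/XLSX exports, a minimal mzML
reader for EIC extraction, and a synthetic-data generator with full ground
truth for testing.

## CLI

```bash
# synthetic fixture with ground truth
msdeconv simulate --preset glutamate --seed 42 --noise low --out fixtures/

# deconvolve a peak table (optionally with raw data for EIC pruning)
msdeconv deconvolve --peaks fixtures/peaks.csv --out out/
msdeconv deconvolve --peaks peaks.csv --mzml run.mzML --config cfg.json --out out/

# sum formulae for a neutral mass (all filters on by default)
msdeconv decompose --mass 147.052 --fixed-c 5

# fold-changes + t-test + BH over a long-format abundance table
msdeconv quantify --input abundances.csv --group-a mutant --group-b wt --out fc.csv

# annotate another chromatogram from a stored reference list
msdeconv apply-refs --list ref.json --peaks other.csv --score 0.8 --out applied.json

# annotated peak list / molecule list exports
msdeconv export --peaks peaks.csv --spectra out/spectra.json --kind molecules --out mols.csv
```

The config JSON accepts any `SDConfig` field (`eps_mz`, `eps_rt`,
`labeled`, `correlation_threshold`, `max_isotopes`, `decomp_tolerance`,
`mode`) plus `ion_list_file` pointing to a JSON/TSV adduct list
(columns: label, delta_mass, charge, multiplicity, is_seed, mode).

## Library example

```python
from msdeconv import SDConfig, deconvolve
from msdeconv.io import read_peak_table

peaks = read_peak_table("peaks.csv")
result = deconvolve(peaks, SDConfig(eps_mz=0.005, eps_rt=5.0, labeled=True))
for spec in result.spectra:
    print(spec.id, spec.M, [a.ion_label for a in spec.annotations])
```

## Layout

```
src/msdeconv/
  chem.py      element masses, Formula arithmetic, ion species, m/z math
  decomp.py    bounded formula enumeration + filter stack
  pipeline.py  the deconvolution steps and curation operations
  quant.py     isotopomer ratios, normalization, t-test, BH
  refmatch.py  reference lists, pseudo fragment spectra, record matching
  io.py        peak tables, exports, result JSON, EIC extraction
  mzml.py      minimal mzML read/write (MS1)
  cli.py       click-based command line
  simulate.py  synthetic chromatograms with ground truth
tests/         pytest suite incl. acceptance criteria
scripts/       acceptance report generator
```
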
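# comsv

Structural-variant (SV) calling from nano-channel optical genome mapping
data of cancer samples. Cancer samples mix cell types and sub-clones, so the
fraction of molecules supporting an SV can be far below the 50%/100%
expected for germline heterozygous/homozygous variants; the pipelines here
make no prior assumption about that fraction.

The package contains:

* **`comsv.formats`** — readers/writers for the standard optical-mapping
  text formats (BNX molecules, CMAP consensus/reference maps, XMAP
  alignments), in-silico digestion of DNA sequence into label maps, and a
  unified SV-call TSV / VCF 4.2 (symbolic ALTs, BND pairs) exporter.
* **`comsv.simulate`** — a cancer-aware simulator: SV events applied along a
  clone evolution graph (normal → trunk → two sub-clones), diploid clone
  genomes, configurable cell mixtures (including high/low tumor-content
  presets), and noisy molecule sampling (per-molecule stretch, Gaussian
  sizing error growing with sqrt(distance), label dropout, false labels)
  with ground-truth SVs and true alignments emitted alongside.
* **`comsv.align`** — a dynamic-programming fit aligner for label maps in
  reference windows, used for targeted re-alignment (e.g. detecting the
  second copy of a tandem duplication from the unaligned part of a
  molecule).
* **`comsv.indel`** — the indel pipeline: per-molecule distance
  normalization, cross-molecule arbitration of abnormal label pairs
  (candidate / corrected / alignment-discarded), candidate-region
  construction with anchor labels, 1-D penalized-likelihood clustering of
  pooled anchor-to-anchor distances with no prior on the supporting
  fraction, typing/zygosity rules, and redundancy-removing post-processing
  with a logistic confidence score.
* **`comsv.complexsv`** — the complex-SV pipeline: junction classification
  from split alignments (inversion / duplication / intra- and
  inter-chromosomal translocation / large-indel hand-off), targeted
  re-alignment rescue, contig-alignment evidence, break-point consolidation
  across molecules, complete-vs-partial status, and cross-pipeline
  annotation/de-duplication (e.g. an insertion matching a tandem-duplication
  unit is reported once, as the duplication).
* **`comsv.evaluate`** — benchmark scoring against simulator truth:
  one-to-one greedy matching with configurable tolerances, precision /
  recall / F1 (with honest `None` for empty denominators), optional
  zygosity-aware matching, and per-clone-of-origin stratification.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit and property tests per module (with independent
brute-force oracles for the DP aligner, the distance clustering, interval
merging and call matching) and `tests/test_acceptance.py`, which runs the
end-to-end acceptance properties on a small toy genome (noise-free control
with correct alignments, supporting-fraction sweep 0.9→0.1 at 100×
coverage, mixture-preset truth consistency, stage stratification, size and
zygosity recovery). The whole run takes a couple of minutes on one CPU.

## CLI

```sh
# simulate a low-tumor-content two-sub-clone benchmark dataset
comsv simulate --scenario scenario.yaml --noise noise.yaml --seed 1 --out sim/

# call indels from aligned molecules
comsv call-indel --xmap sim/true_alignments.xmap --bnx sim/molecules.bnx \
    --ref sim/reference.cmap --out calls.tsv --vcf calls.vcf

# call complex SVs (optionally with contig alignments and gene annotation)
comsv call-complex --xmap sim/true_alignments.xmap --bnx sim/molecules.bnx \
    --ref sim/reference.cmap --indel-calls calls.tsv --out complex.tsv

# score against simulator truth
comsv evaluate --calls calls.tsv --truth sim/truth.tsv --out metrics.json
```

Scenario/noise/criteria YAML files mirror the parameter dataclasses
(`comsv.simulate.NoiseModel`, `comsv.indel.IndelParams`,
`comsv.complexsv.ComplexParams`, `comsv.evaluate.MatchCriteria`); every
threshold used by the pipelines lives in those dataclasses with its default.

## Library example

```python
import numpy as np
from comsv.simulate import (toy_reference, random_sv_events, NoiseModel,
                            make_support_series)
from comsv.indel import call_indels
from comsv.evaluate import match_calls, precision_recall_f1

rng = np.random.default_rng(0)
refs = toy_reference(rng)
events = random_sv_events(rng, refs, {"deletion": 10, "insertion": 10},
                          "tumor", occupied=[], zygosity="hom")
(ds,) = make_support_series(refs, events, [0.15], NoiseModel(coverage=100))
calls, stats = call_indels(ds.true_alignments, ds.molecules_by_id(), refs)
res = match_calls(calls, ds.truth)
print(precision_recall_f1(res.tp, res.fp, res.fn))
```
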
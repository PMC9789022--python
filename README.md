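# clonescribe

Clonal lineage tracing with random DNA barcodes and Cas9/stgRNA expression
recording: a tested, reusable analysis pipeline plus the synthetic-data
generator needed to exercise it.

## Who this is for

Labs that tag tumor cell populations with lentiviral DNA barcodes (a random
30-base insert, one per cell) to follow clone proportions through growth,
drug treatment and metastasis, and that additionally record cumulative gene
expression with a self-targeting guide RNA (stgRNA): Cas9 cuts the stgRNA's
own encoding locus at a rate proportional to the tagged gene's expression,
so indels accumulate in the 20-nt protospacer as a molecular tape.
`clonescribe` turns raw amplicon reads into clone censuses, diversity and
composition statistics, per-read expression scores, and clone-level
expression/abundance associations.

## The core methods

**Barcode collapsing.** Sequencing error scatters a true barcode across
nearby variants. Barcodes are collapsed greedily in descending read count:
a barcode within Hamming distance ≤ 2 of an established representative is
absorbed into the closest one; otherwise it becomes a representative.
Representatives therefore form an independent set at distance 2, reads are
conserved, and no transitive chaining occurs.

**Diversity.** For clone proportions $p_i$ the Shannon entropy
$H = -\sum_i p_i \ln p_i$ gives the *corrected barcode number* $e^H$ (the
Hill number of order 1) — the number of equally abundant clones with the
same entropy. Sample compositions are compared with the Jensen–Shannon
divergence $\mathrm{JSD}(p,q) = H(m) - \tfrac12\bigl(H(p)+H(q)\bigr)$,
$m = (p+q)/2$, in nats (0 identical, $\ln 2$ disjoint), either over all
barcodes or over the union of per-sample top-10 barcodes. Group contrasts
use Welch's *t*-test with Bonferroni correction.

**Mutation scores.** Each observed stgRNA variant is globally aligned to
the template under an affine cost model — mismatch 1.0, gap open 2.5, gap
extension 0.5 per additional base — by dynamic programming; among
minimum-cost alignments, operations are preferred in the order mismatch >
insertion > deletion, left to right. The total decomposes into mismatch,
insertion and deletion components; insertion + deletion is the expression
indicator (mismatches are dominated by synthesis/sequencing noise).
Plasmid stg variants scoring ≥ 4.0 from the template form a *blacklist* of
wrong templates; a read strictly closer to a blacklist member than to the
template is discarded.

**Association.** Clones are summarized by total reads and read-weighted
mean indel score; their association is the weighted Spearman correlation
(weighted Pearson of cumulative-weight mid-ranks), weighted by reads.

## Worked example

Simulate a drug-treatment experiment (one barcoded pool grown into a
control and a uniformly thinned treated tumor), emit FASTQ, re-extract and
collapse barcodes, and compute diversity:

```sh
clonescribe simulate --scenario treatment --seed 1 --depth 20000 --out demo/
```

prints

```json
{
  "samples": {
    "control": {
      "barcodes": 1891,
      "corrected_barcode_number": 1459.8793654932686,
      "shannon_entropy": 7.286109084914162
    },
    "treated": {
      "barcodes": 1891,
      "corrected_barcode_number": 1476.8853384320728,
      "shannon_entropy": 7.297690648124592
    }
  },
  "scenario": "treatment",
  "seed": 1
}
```

Both tumors retain ~1900 of the 2000 simulated clones at 20k reads, and the
corrected barcode number of the treated tumor (1477) is indistinguishable
from the control (1460): uniform, clone-independent killing thins every
clone alike and does not reduce effective diversity — the expected behavior
when no pre-existing resistant subclone exists. `demo/` also contains the
per-sample FASTQ with truth tables, the merged count table, and the
pairwise Jensen–Shannon divergence matrix (here 0.121 nats between control
and treated, reflecting only growth noise).

The same stages are available as `clonescribe extract / merge / diversity /
record-score / correlate`, and as library functions
(`clonescribe.align_score`, `merge_barcodes`, `corrected_barcode_number`,
`weighted_spearman`, ...).

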
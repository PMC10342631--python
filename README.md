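# sirc

Detection and characterization of **short interrupted repeat cassettes
(SIRCs)** — arrays of 2–8 short direct repeats (DRs, typically 10–29 bp)
separated by mutually *dissimilar* spacer sequences — in plant nuclear
genomes. SIRC-like elements resemble prokaryotic CRISPR arrays
morphologically but sit in a eukaryotic repeat landscape dominated by
transposons, satellites and low-complexity DNA, so naive repeat detection
drowns in false positives. This package provides the full discovery
workflow for researchers studying repetitive DNA and mobile genetic
elements (MGEs): a maximal-repeat cassette detector, a nine-rule
complexity/structure/copy-number filter cascade, and the downstream
statistics (palindromes, hidden copies, DR copy-number census, annotation
overlap and positional enrichment, cis-regulatory-element scanning) —
plus a synthetic-genome generator that provides exact ground truth for
every stage.

## The method

**Detection.** Maximal exact repeated pairs (two non-overlapping
occurrences of a substring that cannot be extended on either side) are
enumerated in overlapping genome windows; occurrences of each repeat unit
are chained into candidate cassettes when unit count lies in [2, 8] and
each spacer gap is within [0.5, 3] × DR length. Degenerate flanking units
are admitted by Hamming re-matching against the per-column majority
consensus (≤ 20% mismatch).

**Filtration.** A candidate with consensus *c* and spacers *s₁…sₖ*
(merged in genomic order into *S*) is accepted iff

```
DUST(c) < 0.33          Trifonov(c) > 0.1
DUST(c)·|c| < 11        Trifonov(c)/|c| > 0.0028
GC(c) ∉ {0, 100}%       Trifonov(S) > 0.15
Trifonov(S)/k > 0.07    min_i copies(s_i) < 100
and the full cassette contains no tandem repeat
```

where DUST is the triplet-redundancy statistic
`Σ_t c_t(c_t−1)/2 / (k−1)` over the `k = L−2` overlapping triplets, and
Trifonov (linguistic) complexity is `Π_m V_m / min(4^m, L−m+1)` over word
sizes m = 1…min(7, L−1).

**Characterization.** Accepted cassettes get palindrome calls (arm +
loop ≤ 4 bp + reverse-complement arm; classes none / 3 / 4–9 / 10+ bp),
genome-wide DR and spacer copy numbers, *hidden copies* (full-cassette
occurrences within ≤ 5 substitutions found by pigeonhole-seeded Hamming
search), a DR × annotation-category occurrence census, positional
enrichment `score = log10(observed/expected)` against a shuffle null with
empirical p-values and Benjamini–Hochberg q-values, and IUPAC motif (CRE)
scanning with binomial-tail significance.

## Worked example

```python
import dataclasses
from sirc import *
from sirc.pipeline import PipelineConfig

config = PipelineConfig(seed=7)
config.sim = dataclasses.replace(
    config.sim, genome_length=300_000, n_cassettes=8,
    n_tandem_decoys=3, n_lowcomplexity_decoys=3,
    n_gc_decoys=2, n_highcopy_decoys=2, n_mge_like=2,
)
genome, truth = simulate_genome(dataclasses.replace(config.sim, seed=config.seed))
candidates = scan_genome(genome, config.scan)
accepted, reports = filter_cassettes(candidates, genome, config.filter)

planted = {t.unit_starts for t in truth if t.kind == "cassette"}
recovered = [a for a in accepted if tuple(u.start for u in a.units) in planted]
stats = summarize_cohort(recovered, genome)
```

Output:

```
genome: 300000 bp; 8 cassettes, 10 decoys implanted
candidates: 30
accepted: 18
planted cassettes recovered: 8 / 8
DR length mode: 14 | mean GC %: 36.3 | genome fraction %: 0.594
SIRC_chr1_37054_37302 units: 7 DR: AACGCACCTTTAAC palindrome arm: 0
hidden copies (k=5): 0
```

All 8 implanted cassettes are recovered with exact unit coordinates and
none of the 10 engineered decoys survives the cascade (each fails exactly
its designated rule — check `reports`). The extra accepted records are
chance two-unit repeat pairs in the random background: they genuinely
satisfy the cassette definition, which is precisely why the filter
cascade exists for real genomes. The cohort summary gives the DR-length
mode, GC distribution, and the fraction of the genome covered by
cassettes.

The same workflow is available from the shell:

```
sirc simulate --config cfg.yml --seed 7 --out-prefix sim
sirc detect   --genome sim.fasta --config cfg.yml --out cand.gff3
sirc filter   --genome sim.fasta --candidates cand.gff3 --out acc.gff3 --report report.tsv
sirc characterize --genome sim.fasta --accepted acc.gff3 --annotations ann.gff3 --out-prefix results
```

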
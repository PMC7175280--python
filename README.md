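# codonharmony

A codon-harmonization workbench for designing and diagnosing recombinant
coding sequences.

When a gene is expressed in a heterologous host, replacing every codon with
the host's most abundant synonym ("full optimization") can make elongation
so fast that the nascent chain misfolds. *Codon harmonization* instead
chooses host codons whose **relative codon usage** (RCU — a codon's usage as
a percentage of its most-used synonym; 100% marks the family maximum)
mirrors the native gene's codon-by-codon landscape, preserving the rare-codon
pauses thought to pace co-translational folding. This package is aimed at
protein-expression and structural-biology labs designing constructs for
difficult targets such as membrane proteins, where even a two-fold yield
change decides whether isotope-labelled NMR samples are affordable.

## What it implements

**Design engines** (all conserve the encoded protein exactly; chimeric genes
are harmonized region-by-region against each segment's donor-species table
via a `RegionMap`):

| rule | selection |
|------|-----------|
| FO   | host synonym with RCU = 100 at every position |
| DO   | host synonym closest in RCU to the native codon, excluding any more than 5 percentage points below it |
| NT   | host synonym with the closest RCU **not exceeding** the native codon's (minimal-RCU fallback, flagged in the ledger) |
| FT   | seeded cumulative random draw over an LSR (likelihood-for-selection-to-replace) distribution that decays with \|ΔRCU\| |

Every run returns a per-codon substitution ledger (native codon/RCU, chosen
codon/host RCU, feasible set, rule note) plus provenance. A greedy GC-content
pass (`apply_gc_bias`) and a restriction-site scanner (NcoI/BamHI by default,
report-only) round out the design side.

**Diagnostics**:

* `%MinMax` — sliding-window (18 codons) codon-optimality profile in
  [−100, +100]: for each window, the mean usage of the actual codons
  (X_act) is contrasted with the window's attainable maximum, minimum and
  average synonymous usage (X_max, X_min, X_avg):
  +100·(X_act−X_avg)/(X_max−X_avg) above average,
  −100·(X_avg−X_act)/(X_avg−X_min) below. A seeded random reverse-translation
  null model provides the comparison trace.
* `CAI` — geometric mean of relative-adaptiveness weights w = RCU/100
  (Met/Trp/stop excluded).
* `Nc` — effective number of codons from plug-in family homozygosity
  F_k = Σp², Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, exactly 20 at maximal
  bias and 61 at uniform synonymous usage.
* `ARCU` — arithmetic mean of per-codon RCU; plus GC content and a
  rare-codon map (native RCU < 40%).

**5′-mRNA initiation window**: assembles vector UTR (−N…−1) + the first +8
coding nucleotides (the ribosomal footprint), locates the ribosome-binding
site (5′-AGGAGA-3′), folds the window by base-pair maximization (Nussinov
dynamic program with G·U wobble) or imports an RNAfold dot-bracket
prediction, and reports whether the RBS is structure-free or occluded (any
RBS nucleotide paired).

Three bundled codon-usage tables (E. coli-like host, mouse-like and
Burkholderia-like donors) are **synthetic fixtures** for tests and demos —
use your organism's real table (Kazusa-style text or 2-column TSV) for
actual designs.

## Worked example

```bash
# a 60-codon synthetic gene with ~30% rare codons under the mouse-like table
codonharmony generate --n-codons 60 --fraction-rare 0.3 --table mouse \
    --seed 5 --out gene.fasta
# -> generated 60 codons (realized rare fraction 0.271) to gene.fasta

# harmonize it for the E. coli-like host with the DO rule
codonharmony harmonize --rule do --host-table ecoli --native-table mouse \
    --ledger ledger.tsv gene.fasta harmonized.fasta

# diagnose the result
codonharmony profile --table ecoli --seed 2 --out report.json harmonized.fasta
```

The ledger shows the rule at work — native RCU 100 keeps an optimal host
codon, while a native codon at 30% RCU gets a host codon just above it:

```
position  aa  native_codon  native_rcu  chosen_codon  host_rcu
1         M   ATG           100.0000    ATG           100.0000
2         A   GCT            80.4255    GCA           100.0000
4         G   GGA            29.7794    GGT            35.5401
```

and the report's metrics block reads

```
cai 0.6648   nc 28.4721   arcu 78.9549   gc_percent 49.7268   n_rare 16
```

i.e. the harmonized gene keeps moderate adaptation (CAI 0.66, ARCU 79),
strong codon bias (Nc 28), and 16 of 60 positions still rare in the host —
deliberately, matching the native landscape. The same functions are
available from Python (`import codonharmony as ch`).

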
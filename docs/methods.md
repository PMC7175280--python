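# Methods

## Relative codon usage

All engines and diagnostics are driven by per-organism codon usage tables.
From raw counts or frequencies (the scale is irrelevant; all statistics are
scale-invariant) we derive, within each synonymous family, the
family-internal frequency `per_aa_freq` (sums to 1) and the **relative
codon usage** `rcu = 100 · f / max(f over synonyms)`. The family maximum is
100% by construction; tied maxima all receive 100 (RCU is a ratio, ties are
legitimate). Single-codon families (Met, Trp) are always 100. Stop codons,
when present, form their own family and are excluded from every
sequence-level statistic; a terminal stop in an input CDS is preserved
verbatim and never harmonized. Zero-frequency codons are allowed (RCU 0),
but the engines only emit one when a family offers no nonzero alternative,
with a logged warning.

Parsers accept Kazusa-style `CODON freq (count)` text (RNA or DNA alphabet;
internal representation is DNA) and a 2-column `codon<TAB>number` TSV.
Validation rejects unknown codon keys, negative values, all-zero families
(naming the family) and — by default — tables missing any of the 61 sense
codons; partial tables can be opted into for toy calculations.

## Harmonization rules

Let `n` be the native codon's RCU in its donor-species table and consider
the host synonyms with RCUs `h_i`.

* **FO**: choose `h_i = 100` (lexicographically smallest codon on ties).
* **DO** (tolerance `t`, default 5 percentage points): feasible set
  `{i : h_i ≥ n − t}` — never empty, since the family maximum is 100 —
  choose the feasible codon minimizing `|h_i − n|`. Equidistant ties prefer
  the higher `h_i`, then the lexicographically smallest codon (favoring
  expressibility, deterministically). The tolerance is read as percentage
  *points*, the only reading consistent with the rule's worked behaviour
  (a native 33% codon may take a host 34% codon at Δ=1, while a host codon
  6 points below a native 45% codon is excluded even though it is nearest).
* **NT**: feasible set `{i : h_i ≤ n}`, choose the maximal `h_i` (closest
  from below). If empty (every host synonym exceeds the native RCU — the
  donor's least-used synonym can still be the host's family maximum), the
  minimal-RCU host synonym is emitted and the ledger row is flagged
  `nt-fallback`; this is the closest achievable value from below.
* **FT**: every host synonym is a candidate. Each receives an LSR score
  `s_i = max(100 − |h_i − n|, ε)` (ε = 1e-6), normalized to `lsr_i = s_i/Σs`.
  Candidates are walked in descending LSR order accumulating `lsr`; a
  uniform draw `u ∈ [0,1)` selects the first candidate whose cumulative LSR
  exceeds `u`. The walk terminates because the LSRs sum to 1. The linear
  score is a documented stand-in — the selection mechanics (ranking by
  |ΔRCU| plus cumulative draw) are fixed, but the scoring function is a
  pluggable argument for users with a preferred decay.

Randomness: one `numpy` `default_rng(ft_seed)` per invocation, one draw per
codon position in sequence order (including single-candidate positions), so
ledgers are auditable and runs are bit-reproducible per seed. Coordinates
are 1-based inclusive throughout (codon positions and nucleotide offsets).

Chimeric genes use a `RegionMap` — ordered, non-overlapping 1-based codon
segments, each naming its donor table; validation rejects gaps, overlaps and
unresolvable table ids. This is how a eukaryotic/prokaryotic fusion is
harmonized against mouse-like usage in its cytoplasmic regions and
GC-rich-prokaryote usage in its transmembrane region.

### GC-content pass

`apply_gc_bias` is a greedy left-to-right pass over an existing result: at
each position, synonyms that remain feasible under the original rule *and*
lie strictly within `slack_points` of the chosen codon's host RCU may
replace it, taking whichever minimizes |GC(sequence) − target|; ties keep
the current codon. The strict inequality makes `slack_points = 0` an exact
no-op (with a weak inequality, equal-RCU synonym pairs would still swap at
zero slack, which contradicts the knob's "off" position); any positive
slack admits equal-RCU synonyms. Because the current codon always competes,
the gap to the target is monotonically non-increasing. Translation and rule
guarantees (DO floor, NT ceiling) are preserved by construction.

### Restriction-site scan

`scan_forbidden_motifs` reports every exact, possibly overlapping match of
each motif (defaults: NcoI `CCATGG`, BamHI `GGATCC` — the cloning sites) on
the given strand, 1-based offsets. Repair is deliberately manual: silently
swapping codons to erase a site would bypass the rule that produced them.

## Diagnostics

**%MinMax** (window `w = 18` codons): per window, with `f(c)` the table's
usage frequency of codon `c`,

    X_act = mean f(actual codon)        X_max = mean max synonymous f
    X_min = mean min synonymous f       X_avg = mean of family-average f

    %MinMax = +100·(X_act − X_avg)/(X_max − X_avg)   if X_act > X_avg
              −100·(X_avg − X_act)/(X_avg − X_min)   if X_act < X_avg
              0                                       otherwise

Windows are reported at their first codon; only full windows are emitted
(the edge convention is otherwise arbitrary). Degenerate windows where all
synonym frequencies coincide give 0. The null model reverse-translates the
protein `n_replicates` times (default 100, explicit seed required — there
is no canonical replicate count), sampling each codon with probability
`per_aa_freq`, and averages the per-window profile; Monte-Carlo error decays
as 1/√n.

**CAI**: geometric mean of `w = rcu/100` under a reference table, excluding
Met/Trp (always w = 1, no information) and stops. With no curated
highly-expressed reference set supplied, the host usage table itself is the
reference — a documented approximation; pass your own w-map when you have a
reference-gene set. Zero-weight codons raise by default;
`zero_weight="pseudo"` substitutes `0.5/family size`.

**Nc** (effective number of codons): plug-in family homozygosity
`F = Σ p_i²` over observed synonymous proportions, averaged per degeneracy
class (9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold families), then

    Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to [20, 61].

The plug-in estimator (rather than Wright's small-sample bias correction,
which can stray outside the bounds) makes the extremes exact: one codon per
amino acid ⇒ every F = 1 ⇒ Nc = 20; uniform synonymous usage ⇒ F_k = 1/k ⇒
Nc = 61. An amino acid absent from the sequence is simply absent from its
class average (equivalent to imputing the class mean); an entirely
unobserved three-fold class (only Ile) is imputed as the mean of the two-
and four-fold averages; an entirely unobserved two-, four- or six-fold
class raises — the statistic is not meaningful on such short peptides.

**ARCU**: arithmetic mean of per-codon RCU (terminal stop excluded), either
against one table or region-wise via a `RegionMap` (both region-specific
native scoring and host-only scoring are supported; which is appropriate
depends on whether one is asking about the donor landscape or the host's
view of it).

**Rare codons**: native RCU strictly below the threshold (default 40%),
scored against each position's donor table.

## 5′-mRNA initiation window

The ribosomal footprint extends ~13 nt into the coding region in reported
footprinting work, which for the vector context modelled here corresponds
to pairing potential through the +8 coding nucleotide; the analysed window
is therefore UTR(−N…−1) + CDS(+1…+8). The window length is configurable
(the −53 default in the bundled examples depends on the vector; it is an
input, not a constant, and the vendor UTR sequence is user-supplied — a
synthetic 53-nt fixture containing the RBS is used in tests). The RBS
(default `AGGAGA`) is located by exact search in the upstream part,
rightmost match on duplicates (the biologically active site is the one at
canonical spacing from the start codon; all matches are recorded).

**Folding.** Thermodynamic MFE folding is intentionally not reimplemented:
the module imports RNAfold dot-bracket output directly (sequence line +
structure line with optional trailing energy, which is stored as an
annotation only). The built-in alternative, `fold_bpmax`, is a
Nussinov-style dynamic program maximizing Watson–Crick + G·U pair count
with a minimum hairpin loop of 3 unpaired bases and a deterministic
traceback (unpaired 5′ base preferred when free of cost, else leftmost
partner). It is a qualitative screen — pair counts, not energies — and is
validated against exhaustive structure enumeration for short sequences.

**Occlusion.** A window is *occluded* when ≥1 RBS nucleotide is paired in
the attached structure (`rbs_paired_fraction` = paired RBS nt / 6). The
free/occluded dichotomy carries no fraction cutoff; any pairing counts,
which makes the verdict monotone under added pairs.

## Synthetic data generator

`generate_synthetic_gene` emulates the input this workbench exists for: a
two-species chimeric CDS with a controlled rare-codon landscape. Defaults —
rare fraction 0.25, threshold 40%, two-region chimera support — mirror a
partially deoptimized construct in which roughly a quarter of positions
carry rare codons. Positions after the fixed ATG start are rare with
probability `fraction_rare`; amino acids are drawn uniformly from families
that can realise the requested class, then codons uniformly within the
class pool, so the realized fraction is binomial about the target (the
truth ledger records every position's codon, donor RCU and table). It does
**not** emulate amino-acid composition bias, codon autocorrelation,
dicodon/codon-pair effects or mRNA-structure constraints of real genes —
passing tests demonstrate the algorithms' contracts, not biological
performance on natural sequences.

The three bundled tables are synthetic: plausible family skews (GC3-biased
for the Burkholderia-like donor), every multi-codon family containing at
least one rare synonym, and a leucine family constructed so the DO rule's
two canonical worked substitutions (33→34 chosen; a 6-point-below nearest
neighbour excluded at native 45) are exactly reproducible. They are
fixtures, not measurements.

## Problem sizes and numerics

Test and demonstration scales are chosen for desk-scale runs: 1,000
30-codon genes for the translation-preservation sweep, 10,000 draws for the
FT frequency check (3 binomial SE), exhaustive fold verification over all
sequences ≤ 8 nt plus 500 random 9–12-mers, 100-replicate null models.
Floating-point comparisons in guarantees use 1e-9 slack; LSR normalization
and per-family frequency sums are exact to 1e-9. Percent values are clamped
to their nominal ranges ([−100, 100], [20, 61]) only after computation, as
a guard against round-off at the boundaries.

## Known limitations

* No thermodynamic energies, suboptimal ensembles or pairing probabilities;
  import RNAfold output for those.
* CAI without a curated reference set measures adaptation to bulk usage,
  not to highly-expressed genes.
* The LSR scoring form is a stand-in (mechanics fixed, score pluggable).
* No codon-pair bias, Shine–Dalgarno-like internal motif avoidance, repeat
  filters or mRNA-stability optimization; the motif scanner is report-only.
* Elongation-efficiency and tRNA-adaptation indices are out of scope.
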
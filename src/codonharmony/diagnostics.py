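"""Sequence descriptors: %MinMax profile, CAI, Nc, ARCU, GC, rare codons.

The %MinMax statistic contrasts, over a sliding window (default 18 codons),
the mean usage frequency of the codons actually present (X_actual) with the
window's attainable extremes — the mean of each position's family-maximal
(X_max), family-minimal (X_min) and family-average (X_avg) synonymous
frequencies:

    %MinMax = +100 · (X_actual − X_avg) / (X_max − X_avg)   if X_actual > X_avg
              −100 · (X_avg − X_actual) / (X_avg − X_min)   if X_actual < X_avg
              0                                              otherwise

+100 means the window holds only each family's most abundant codon, −100
only the rarest, 0 the average of all possible codon choices. The companion
null model reverse-translates the protein at random, sampling codons with
their per-amino-acid frequencies, and averages the profile over replicates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import genetic_code as gcode
from .harmonize import RegionMap
from .tables import CodonUsageTable

__all__ = [
    "MinMaxProfile",
    "RareCodonAnnotation",
    "MetricReport",
    "percent_minmax",
    "null_model_minmax",
    "cai",
    "effective_number_of_codons",
    "arcu",
    "gc_content",
    "annotate_rare",
    "metric_report",
]


@dataclass
class MinMaxProfile:
    window_size: int
    values: list[tuple[int, float]]              # (1-based window start, %)
    null_values: list[tuple[int, float]] | None = None
    table_id: str = ""

    @property
    def percents(self) -> list[float]:
        return [p for _, p in self.values]


@dataclass
class RareCodonAnnotation:
    threshold_points: float
    positions: list[dict]        # {"position", "codon", "native_rcu", "table_id"}

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MetricReport:
    cai: float
    nc: float
    arcu: float
    gc_percent: float
    n_rare: int
    provenance: dict = field(default_factory=dict)


def _coding_codons(seq: str) -> list[str]:
    """Codons of the CDS with a terminal stop (if any) dropped; internal
    stops rejected."""
    codons = gcode.split_codons(seq)
    if codons and gcode.is_stop(codons[-1]):
        codons = codons[:-1]
    for i, c in enumerate(codons, start=1):
        if gcode.is_stop(c):
            raise ValueError(f"internal stop codon {c} at codon position {i}")
    return codons


def percent_minmax(
    seq: str, table: CodonUsageTable, window_size: int = 18
) -> MinMaxProfile:
    """Windowed %MinMax trace; windows reported at their first codon, full
    windows only."""
    codons = _coding_codons(seq)
    if len(codons) < window_size:
        raise ValueError(
            f"sequence has {len(codons)} codons; need at least one "
            f"{window_size}-codon window"
        )
    f_actual = np.array([table.freq(c) for c in codons])
    fam_stats = {}
    for c in set(codons):
        syn = [table.freq(s) for s in gcode.synonyms(c)]
        fam_stats[c] = (max(syn), min(syn), sum(syn) / len(syn))
    f_max = np.array([fam_stats[c][0] for c in codons])
    f_min = np.array([fam_stats[c][1] for c in codons])
    f_avg = np.array([fam_stats[c][2] for c in codons])

    values: list[tuple[int, float]] = []
    w = window_size
    for start in range(len(codons) - w + 1):
        sl = slice(start, start + w)
        x_act, x_max = f_actual[sl].mean(), f_max[sl].mean()
        x_min, x_avg = f_min[sl].mean(), f_avg[sl].mean()
        if x_act > x_avg and x_max > x_avg:
            pct = 100.0 * (x_act - x_avg) / (x_max - x_avg)
        elif x_act < x_avg and x_avg > x_min:
            pct = -100.0 * (x_avg - x_act) / (x_avg - x_min)
        else:
            pct = 0.0
        values.append((start + 1, float(np.clip(pct, -100.0, 100.0))))
    return MinMaxProfile(window_size=w, values=values, table_id=table.species_label)


def null_model_minmax(
    seq: str,
    table: CodonUsageTable,
    window_size: int = 18,
    n_replicates: int = 100,
    seed: int | None = None,
) -> list[tuple[int, float]]:
    """Mean %MinMax trace of random reverse translations of the protein.

    Each replicate resamples every codon from its synonymous family with
    probability equal to the family-internal usage frequency; seeded and
    reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seed is None:
        raise ValueError("null model requires an explicit seed")
    codons = _coding_codons(seq)
    rng = np.random.default_rng(seed)
    families: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in {gcode.translate_codon(c) for c in codons}:
        syn = list(gcode.AA_TO_CODONS[aa])
        p = np.array([table.per_aa_freq[c] for c in syn])
        families[aa] = (syn, p / p.sum())
    aas = [gcode.translate_codon(c) for c in codons]

    acc: np.ndarray | None = None
    starts: list[int] = []
    for _ in range(n_replicates):
        sampled = [
            families[aa][0][rng.choice(len(families[aa][0]), p=families[aa][1])]
            for aa in aas
        ]
        prof = percent_minmax("".join(sampled), table, window_size)
        vals = np.array(prof.percents)
        starts = [s for s, _ in prof.values]
        acc = vals if acc is None else acc + vals
    mean = acc / n_replicates
    return [(s, float(v)) for s, v in zip(starts, mean)]


def cai(
    seq: str,
    reference: CodonUsageTable | Mapping[str, float],
    zero_weight: str = "error",
) -> float:
    """Codon adaptation index: geometric mean of relative-adaptiveness
    weights w = RCU/100 against a highly-expressed reference.

    Met, Trp (single-codon families) and stops are excluded from the
    product. A zero-weight codon raises by default; ``zero_weight="pseudo"``
    substitutes 0.5 / family size instead.
    """
    if isinstance(reference, CodonUsageTable):
        weights = {c: r / 100.0 for c, r in reference.rcu.items()}
    else:
        weights = {gcode.normalize_codon(c): float(w) for c, w in reference.items()}
    codons = _coding_codons(seq)
    logs: list[float] = []
    for i, c in enumerate(codons, start=1):
        aa = gcode.translate_codon(c)
        if aa in ("M", "W", gcode.STOP):
            continue
        w = weights.get(c)
        if w is None:
            raise ValueError(f"no reference weight for codon {c} (position {i})")
        if w <= 0:
            if zero_weight == "pseudo":
                w = 0.5 / len(gcode.AA_TO_CODONS[aa])
            else:
                raise ValueError(
                    f"zero reference weight for codon {c} at position {i}; "
                    "pass zero_weight='pseudo' to substitute a pseudo-weight"
                )
        logs.append(np.log(w))
    if not logs:
        raise ValueError("no codons contribute to CAI (all Met/Trp/stop)")
    return float(np.exp(np.mean(logs)))


def effective_number_of_codons(seq: str) -> float:
    """Plug-in Wright-style effective number of codons.

    Family homozygosity is the plug-in F = Σ p_i² over observed synonymous
    proportions; class averages over observed families give
    Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to [20, 61]. With the
    plug-in estimator the bounds are exact: single-codon usage gives 20,
    perfectly uniform synonymous usage 61. An entirely unobserved Ile
    (3-fold) class is imputed as the mean of the 2- and 4-fold class
    averages; other empty classes raise.
    """
    codons = _coding_codons(seq)
    if not codons:
        raise ValueError("no codons")
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1

    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, k in gcode.DEGENERACY.items():
        if k == 1:
            continue
        fam = [counts.get(c, 0) for c in gcode.AA_TO_CODONS[aa]]
        n = sum(fam)
        if n == 0:
            continue                    # imputed via the class mean
        p = np.array(fam, dtype=float) / n
        class_F[k].append(float((p ** 2).sum()))

    fbar: dict[int, float] = {}
    for k, fs in class_F.items():
        if fs:
            fbar[k] = float(np.mean(fs))
    if 3 not in fbar:
        if 2 in fbar and 4 in fbar:
            fbar[3] = (fbar[2] + fbar[4]) / 2.0
        else:
            raise ValueError("cannot impute 3-fold class: 2- or 4-fold unobserved")
    missing = [k for k in (2, 4, 6) if k not in fbar]
    if missing:
        raise ValueError(f"no observed families of degeneracy {missing}")

    nc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return float(np.clip(nc, 20.0, 61.0))


def arcu(
    seq: str,
    table: CodonUsageTable | None = None,
    region_map: RegionMap | None = None,
    tables: Mapping[str, CodonUsageTable] | None = None,
) -> float:
    """Average relative codon usage: arithmetic mean of per-codon RCU (%),
    terminal stop excluded. Scoring is against *table*, or region-wise
    against *tables* when a :class:`RegionMap` is given."""
    codons = _coding_codons(seq)
    if region_map is not None:
        if tables is None:
            raise ValueError("region-wise ARCU needs the tables mapping")
        region_map.validate(len(codons), tables)
        vals = [
            tables[region_map.table_id_at(i)].rcu[c]
            for i, c in enumerate(codons, start=1)
        ]
    else:
        if table is None:
            raise ValueError("arcu needs a table or a region map")
        vals = [table.rcu[c] for c in codons]
    return float(np.mean(vals))


def gc_content(seq: str) -> float:
    """GC percentage of a plain-ACGT DNA string; ambiguity codes rejected."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous/non-DNA characters: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def annotate_rare(
    seq: str,
    region_map: RegionMap,
    tables: Mapping[str, CodonUsageTable],
    threshold: float = 40.0,
) -> RareCodonAnnotation:
    """Flag codons whose native RCU is strictly below *threshold* percent."""
    codons = _coding_codons(seq)
    region_map.validate(len(codons), tables)
    hits = []
    for i, c in enumerate(codons, start=1):
        tid = region_map.table_id_at(i)
        rcu = tables[tid].rcu[c]
        if rcu < threshold:
            hits.append(
                {"position": i, "codon": c, "native_rcu": rcu, "table_id": tid}
            )
    return RareCodonAnnotation(threshold_points=threshold, positions=hits)


def metric_report(
    seq: str,
    host_table: CodonUsageTable,
    cai_reference: CodonUsageTable | Mapping[str, float] | None = None,
    region_map: RegionMap | None = None,
    tables: Mapping[str, CodonUsageTable] | None = None,
    rare_threshold: float = 40.0,
) -> MetricReport:
    """One-stop summary: CAI, Nc, ARCU, GC%, rare-codon count.

    CAI defaults to the host table itself as reference when no
    highly-expressed reference set is supplied. Rare codons are scored
    against the host table unless a region map with donor tables is given.
    """
    codons = _coding_codons(seq)
    if region_map is None:
        region_map = RegionMap.single("host", len(codons))
        tables = {"host": host_table}
    rare = annotate_rare("".join(codons), region_map, tables, rare_threshold)
    return MetricReport(
        cai=cai(seq, cai_reference if cai_reference is not None else host_table),
        nc=effective_number_of_codons(seq),
        arcu=arcu(seq, table=host_table),
        gc_percent=gc_content(seq),
        n_rare=len(rare),
        provenance={
            "host_table": host_table.species_label,
            "nc_estimator": "plug-in",
            "cai_reference": "host-table" if cai_reference is None else "supplied",
            "rare_threshold": rare_threshold,
        },
    )
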
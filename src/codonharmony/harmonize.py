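"""Sequence-design engines for heterologous expression.

Four rules, all preserving the encoded protein exactly:

* **FO** (full optimization) — every codon becomes the host's most abundant
  synonym (RCU 100). The traditional vendor default.
* **DO** (deoptimization to match the donor) — for each native codon, host
  synonyms whose RCU falls more than a tolerance (default 5 percentage
  points) below the native codon's RCU are excluded; among the rest the one
  closest in RCU to the native value is chosen. E.g. with the bundled
  tables a native Leu CTT at 33% RCU maps to host TTG at 34%, while a native
  CTC at 45% maps to TTA (52%) because the nearer CTT (39%) sits more than
  5 points below 45.
* **NT** (no tolerance) — only host synonyms whose RCU does not exceed the
  native codon's are eligible; the closest from below wins. When no synonym
  sits at or below the native RCU the minimal-RCU synonym is used and the
  ledger notes the fallback.
* **FT** (full tolerance) — every host synonym is a candidate, weighted by a
  likelihood-for-selection-to-replace (LSR) score that decays with the
  absolute RCU difference from the native codon; a seeded cumulative random
  draw walks the candidates in descending LSR order and picks the first one
  whose cumulative LSR exceeds the draw.

Chimeric genes are handled through a :class:`RegionMap` assigning each codon
interval its donor-species usage table, so a eukaryotic/prokaryotic fusion is
harmonized region by region against the appropriate native table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from . import genetic_code as gcode
from .tables import CodonUsageTable

__all__ = [
    "Segment",
    "RegionMap",
    "HarmonizationConfig",
    "LedgerRow",
    "HarmonizationResult",
    "LsrCandidate",
    "LsrDistribution",
    "FrameError",
    "harmonize_fo",
    "harmonize_do",
    "harmonize_nt",
    "harmonize_ft",
    "compute_lsr",
    "apply_gc_bias",
    "scan_forbidden_motifs",
    "DEFAULT_FORBIDDEN_MOTIFS",
]

logger = logging.getLogger(__name__)

#: NcoI and BamHI recognition sites — the cloning sites the designed gene
#: must not recreate internally.
DEFAULT_FORBIDDEN_MOTIFS: tuple[str, ...] = ("CCATGG", "GGATCC")

LSR_EPSILON = 1e-6


class FrameError(ValueError):
    """Out-of-frame input or an internal stop codon."""


@dataclass(frozen=True)
class Segment:
    """1-based inclusive codon interval attributed to one donor table."""

    start: int
    end: int
    table_id: str


@dataclass
class RegionMap:
    """Ordered, non-overlapping segments covering codons 1..L."""

    segments: list[Segment]

    @classmethod
    def single(cls, table_id: str, n_codons: int) -> "RegionMap":
        return cls([Segment(1, n_codons, table_id)])

    def validate(self, n_codons: int, tables: Mapping[str, CodonUsageTable]) -> None:
        if not self.segments:
            raise ValueError("empty region map")
        segs = sorted(self.segments, key=lambda s: s.start)
        expected = 1
        for seg in segs:
            if seg.start != expected:
                raise ValueError(
                    f"region map gap/overlap at codon {expected} "
                    f"(segment starts at {seg.start})"
                )
            if seg.end < seg.start:
                raise ValueError(f"segment {seg} has end < start")
            if seg.table_id not in tables:
                raise ValueError(f"unresolvable table id {seg.table_id!r}")
            expected = seg.end + 1
        if expected != n_codons + 1:
            raise ValueError(
                f"region map covers codons 1..{expected - 1}, "
                f"sequence has {n_codons}"
            )
        self.segments = segs

    def table_id_at(self, position: int) -> str:
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg.table_id
        raise IndexError(f"codon position {position} outside region map")


@dataclass
class HarmonizationConfig:
    """Knobs shared by the engines; defaults follow the study conditions."""

    rule: str = "DO"
    do_tolerance_points: float = 5.0
    ft_seed: int | None = None
    gc_target: float | None = None
    gc_slack_points: float = 0.0
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    rare_threshold_points: float = 40.0

    def __post_init__(self) -> None:
        if self.do_tolerance_points < 0:
            raise ValueError("do_tolerance_points must be >= 0")
        if self.gc_target is not None and not 0 < self.gc_target < 100:
            raise ValueError("gc_target must be in (0, 100)")


@dataclass
class LedgerRow:
    """Audit record for one codon substitution."""

    position: int                       # 1-based codon index
    amino_acid: str
    native_codon: str
    native_rcu: float
    chosen_codon: str
    host_rcu: float
    feasible_set: tuple[tuple[str, float], ...]
    rule_note: str = ""


@dataclass
class HarmonizationResult:
    output_sequence: str
    ledger: list[LedgerRow]
    provenance: dict = field(default_factory=dict)

    def host_rcus(self) -> list[float]:
        return [row.host_rcu for row in self.ledger]


@dataclass(frozen=True)
class LsrCandidate:
    codon: str
    host_rcu: float
    abs_delta: float
    lsr: float


@dataclass
class LsrDistribution:
    """Normalized selection likelihoods, sorted by LSR descending."""

    candidates: list[LsrCandidate]

    def cumulative_select(self, u: float) -> LsrCandidate:
        """Walk candidates in descending LSR, return the first whose
        cumulative LSR exceeds *u* (the paper's iterative draw)."""
        acc = 0.0
        for cand in self.candidates:
            acc += cand.lsr
            if acc > u:
                return cand
        return self.candidates[-1]       # guards float round-off at u ~ 1


def compute_lsr(
    native_rcu: float,
    host_candidates: Sequence[tuple[str, float]],
    score: Callable[[float], float] | None = None,
) -> LsrDistribution:
    """Likelihood-for-selection-to-replace over candidate host codons.

    The default score is linear in similarity, ``max(100 − |Δ|, ε)`` with
    Δ the host-vs-native RCU difference in points, normalized to sum to 1.
    The scoring function is pluggable (it must be non-increasing in |Δ|).
    """
    if not host_candidates:
        raise ValueError("compute_lsr needs at least one candidate")
    score = score or (lambda d: max(100.0 - d, LSR_EPSILON))
    deltas = [abs(rcu - native_rcu) for _, rcu in host_candidates]
    raw = [score(d) for d in deltas]
    total = sum(raw)
    cands = [
        LsrCandidate(codon=c, host_rcu=rcu, abs_delta=d, lsr=s / total)
        for (c, rcu), d, s in zip(host_candidates, deltas, raw)
    ]
    cands.sort(key=lambda x: (-x.lsr, x.codon))
    return LsrDistribution(cands)


# ---------------------------------------------------------------------------
# engine internals

def _split_and_check(seq: str) -> tuple[list[str], str | None]:
    """Split into codons, detach a terminal stop, reject internal stops."""
    codons = gcode.split_codons(seq)
    if not codons:
        raise FrameError("empty sequence")
    terminal_stop = None
    if gcode.is_stop(codons[-1]):
        terminal_stop = codons[-1]
        codons = codons[:-1]
    for i, c in enumerate(codons, start=1):
        if gcode.is_stop(c):
            raise FrameError(f"internal stop codon {c} at codon position {i}")
    return codons, terminal_stop


def _candidate_pool(
    host_table: CodonUsageTable, codon: str
) -> tuple[list[tuple[str, float]], str]:
    """Host synonyms as (codon, rcu). Zero-frequency synonyms are withheld
    unless the whole family is zero-frequency-free of alternatives."""
    all_cands = host_table.family_rcus(codon)
    nonzero = [(c, r) for c, r in all_cands if r > 0]
    if nonzero:
        return nonzero, ""
    logger.warning(
        "family %s has only zero-frequency host codons; emitting anyway",
        gcode.translate_codon(codon),
    )
    return all_cands, "zero-frequency-only family"


ChooseFn = Callable[
    [float, list[tuple[str, float]]], tuple[str, float, tuple[tuple[str, float], ...], str]
]


def _run_engine(
    seq: str,
    rule: str,
    native_rcu_at: Callable[[int, str], float],
    host_table: CodonUsageTable,
    choose: ChooseFn,
    provenance: dict,
) -> HarmonizationResult:
    codons, terminal_stop = _split_and_check(seq)
    out: list[str] = []
    ledger: list[LedgerRow] = []
    for pos, codon in enumerate(codons, start=1):
        aa = gcode.translate_codon(codon)
        native_rcu = native_rcu_at(pos, codon)
        pool, pool_note = _candidate_pool(host_table, codon)
        chosen, host_rcu, feasible, note = choose(native_rcu, pool)
        if pool_note:
            note = f"{note}; {pool_note}" if note else pool_note
        out.append(chosen)
        ledger.append(
            LedgerRow(pos, aa, codon, native_rcu, chosen, host_rcu, feasible, note)
        )
    if terminal_stop is not None:
        out.append(terminal_stop)      # stop is preserved verbatim
    result = HarmonizationResult(
        output_sequence="".join(out), ledger=ledger, provenance=provenance
    )
    assert _protein(result.output_sequence) == _protein(seq)
    return result


def _protein(seq: str) -> str:
    return "".join(gcode.translate_codon(c) for c in gcode.split_codons(seq))


def _native_lookup(
    region_map: RegionMap, tables: Mapping[str, CodonUsageTable]
) -> Callable[[int, str], float]:
    def lookup(pos: int, codon: str) -> float:
        table = tables[region_map.table_id_at(pos)]
        return table.rcu[codon]

    return lookup


# ---------------------------------------------------------------------------
# the four rules

def harmonize_fo(seq: str, host_table: CodonUsageTable) -> HarmonizationResult:
    """Full optimization: host RCU-100 synonym at every position.

    Ledger ``native_rcu`` is the input codon rescored against the host table
    (FO consults no donor table). Family RCU ties break toward the
    lexicographically smallest codon.
    """

    def choose(native_rcu, pool):
        best = [(c, r) for c, r in pool if r >= max(r2 for _, r2 in pool)]
        best.sort(key=lambda cr: cr[0])
        c, r = best[0]
        return c, r, tuple(best), ""

    def native_rcu_at(pos, codon):
        return host_table.rcu[codon]

    prov = {"rule": "FO", "host_table": host_table.species_label}
    return _run_engine(seq, "FO", native_rcu_at, host_table, choose, prov)


def harmonize_do(
    seq: str,
    region_map: RegionMap,
    native_tables: Mapping[str, CodonUsageTable],
    host_table: CodonUsageTable,
    config: HarmonizationConfig | None = None,
) -> HarmonizationResult:
    """DO rule: closest host RCU, never more than the tolerance below native.

    The feasible set is provably non-empty (the host family maximum, RCU 100,
    always clears ``native_rcu − tolerance``). Equidistant ties prefer the
    higher host RCU, then the lexicographically smallest codon.
    """
    config = config or HarmonizationConfig(rule="DO")
    tol = config.do_tolerance_points
    codons, _ = _split_and_check(seq)
    region_map.validate(len(codons), native_tables)

    def choose(native_rcu, pool):
        feasible = tuple((c, r) for c, r in pool if r >= native_rcu - tol)
        chosen = min(feasible, key=lambda cr: (abs(cr[1] - native_rcu), -cr[1], cr[0]))
        return chosen[0], chosen[1], feasible, ""

    prov = {
        "rule": "DO",
        "host_table": host_table.species_label,
        "native_tables": {k: t.species_label for k, t in native_tables.items()},
        "do_tolerance_points": tol,
    }
    return _run_engine(
        seq, "DO", _native_lookup(region_map, native_tables), host_table, choose, prov
    )


def harmonize_nt(
    seq: str,
    region_map: RegionMap,
    native_tables: Mapping[str, CodonUsageTable],
    host_table: CodonUsageTable,
    config: HarmonizationConfig | None = None,
) -> HarmonizationResult:
    """No-tolerance rule: closest host RCU not exceeding the native RCU.

    If every host synonym exceeds the native RCU the minimal-RCU synonym is
    emitted and the ledger row carries the note ``nt-fallback``.
    """
    codons, _ = _split_and_check(seq)
    region_map.validate(len(codons), native_tables)

    def choose(native_rcu, pool):
        feasible = tuple((c, r) for c, r in pool if r <= native_rcu)
        if feasible:
            chosen = max(feasible, key=lambda cr: (cr[1], [-ord(x) for x in cr[0]]))
            return chosen[0], chosen[1], feasible, ""
        chosen = min(pool, key=lambda cr: (cr[1], cr[0]))
        return chosen[0], chosen[1], tuple(pool), "nt-fallback"

    prov = {
        "rule": "NT",
        "host_table": host_table.species_label,
        "native_tables": {k: t.species_label for k, t in native_tables.items()},
    }
    return _run_engine(
        seq, "NT", _native_lookup(region_map, native_tables), host_table, choose, prov
    )


def harmonize_ft(
    seq: str,
    region_map: RegionMap,
    native_tables: Mapping[str, CodonUsageTable],
    host_table: CodonUsageTable,
    config: HarmonizationConfig,
) -> HarmonizationResult:
    """Full-tolerance rule: seeded cumulative draw over the LSR distribution.

    One uniform draw is consumed per codon position in sequence order (also
    at single-candidate positions) so the random stream lines up with the
    ledger. Bit-reproducible for a fixed ``config.ft_seed``.
    """
    if config.ft_seed is None:
        raise ValueError("harmonize_ft requires config.ft_seed")
    codons, _ = _split_and_check(seq)
    region_map.validate(len(codons), native_tables)
    rng = np.random.default_rng(config.ft_seed)

    def choose(native_rcu, pool):
        dist = compute_lsr(native_rcu, pool)
        u = float(rng.random())
        cand = dist.cumulative_select(u)
        feasible = tuple((c.codon, c.host_rcu) for c in dist.candidates)
        return cand.codon, cand.host_rcu, feasible, f"u={u:.6f}"

    prov = {
        "rule": "FT",
        "host_table": host_table.species_label,
        "native_tables": {k: t.species_label for k, t in native_tables.items()},
        "ft_seed": config.ft_seed,
    }
    return _run_engine(
        seq, "FT", _native_lookup(region_map, native_tables), host_table, choose, prov
    )


# ---------------------------------------------------------------------------
# post-passes

def _gc_count(s: str) -> int:
    return s.count("G") + s.count("C")


def apply_gc_bias(
    result: HarmonizationResult,
    host_table: CodonUsageTable,
    gc_target: float,
    slack_points: float,
    config: HarmonizationConfig | None = None,
) -> HarmonizationResult:
    """Greedy GC-content adjustment within an RCU slack band.

    One left-to-right pass. At each position the synonyms that (a) remain
    feasible under the original rule and (b) lie strictly within
    ``slack_points`` of the chosen codon's host RCU may replace it, picking
    whichever brings whole-sequence GC closest to ``gc_target``. Strict
    inequality makes ``slack_points=0`` an exact no-op; ties keep the
    current codon. The overall |GC − target| gap never increases.
    """
    config = config or HarmonizationConfig(rule=result.provenance.get("rule", "DO"))
    rule = result.provenance.get("rule", config.rule)
    tol = config.do_tolerance_points
    codons = [row.chosen_codon for row in result.ledger]
    terminal = result.output_sequence[3 * len(codons):]
    gc_now = _gc_count("".join(codons) + terminal)
    total_len = 3 * len(codons) + len(terminal)
    new_ledger = [replace(row) for row in result.ledger]

    def feasible_under_rule(row: LedgerRow, rcu: float) -> bool:
        if rule == "FO":
            return rcu >= 100.0
        if rule == "DO":
            return rcu >= row.native_rcu - tol
        if rule == "NT":
            if "nt-fallback" in row.rule_note:
                return False
            return rcu <= row.native_rcu
        return True                      # FT: full tolerance

    for i, row in enumerate(new_ledger):
        if slack_points <= 0:
            break
        pool = dict(host_table.family_rcus(row.chosen_codon))
        current_rcu = row.host_rcu
        options = [(row.chosen_codon, current_rcu)]
        for c, r in sorted(pool.items()):
            if c == row.chosen_codon or r <= 0:
                continue
            if abs(r - current_rcu) < slack_points and feasible_under_rule(row, r):
                options.append((c, r))
        if len(options) == 1:
            continue

        def gap(option: tuple[str, float]) -> float:
            gc_new = gc_now - _gc_count(codons[i]) + _gc_count(option[0])
            return abs(100.0 * gc_new / total_len - gc_target)

        current_gap = gap((row.chosen_codon, current_rcu))
        best = min(options, key=lambda o: (gap(o), o[0] != row.chosen_codon, o[0]))
        if best[0] != row.chosen_codon and gap(best) < current_gap:
            gc_now += _gc_count(best[0]) - _gc_count(codons[i])
            codons[i] = best[0]
            row.chosen_codon, row.host_rcu = best
            row.rule_note = (row.rule_note + "; " if row.rule_note else "") + "gc-bias"

    out_seq = "".join(codons) + terminal
    prov = dict(result.provenance)
    prov.update({"gc_target": gc_target, "gc_slack_points": slack_points})
    return HarmonizationResult(out_seq, new_ledger, prov)


def scan_forbidden_motifs(
    seq: str, motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS
) -> list[dict]:
    """Report every exact match of each motif (1-based nt offsets, given
    strand only, overlapping matches included). Report-only: no repair."""
    s = seq.strip().upper()
    hits: list[dict] = []
    for motif in motifs:
        m = motif.strip().upper()
        start = s.find(m)
        while start != -1:
            hits.append({"motif": m, "offset": start + 1})
            start = s.find(m, start + 1)
    hits.sort(key=lambda h: (h["offset"], h["motif"]))
    return hits
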
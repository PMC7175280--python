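"""Synthetic coding-gene generator with a per-position usage truth ledger.

Emulates the codon landscape of a two-species chimeric gene: each region
draws codons from its donor-species usage table, with a controlled fraction
of positions deliberately taken from the rare (<40% RCU) pool. The
generator returns both the DNA and a truth ledger, so tests of the rare-
codon annotator, the harmonization engines and the profilers never need
external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import genetic_code as gcode
from .harmonize import RegionMap, Segment
from .tables import CodonUsageTable

__all__ = ["SyntheticGeneSpec", "generate_synthetic_gene"]


@dataclass
class SyntheticGeneSpec:
    """Recipe for one synthetic gene.

    ``n_codons`` counts amino-acid codons including the ATG start; a
    terminal TAA stop is appended on top. ``region_boundaries`` maps the
    gene onto donor tables as (start, end, table_id) codon intervals; when
    omitted the whole gene uses the single supplied table.
    """

    n_codons: int
    fraction_rare: float = 0.25
    region_boundaries: list[tuple[int, int, str]] | None = None
    seed: int = 0
    rare_threshold: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_rare <= 1.0:
            raise ValueError("fraction_rare must be in [0, 1]")
        if self.n_codons < 2:
            raise ValueError("need at least start codon + one position")


@dataclass
class SyntheticGene:
    sequence: str                        # ATG ... TAA, in frame
    truth: list[dict] = field(default_factory=list)
    region_map: RegionMap | None = None

    @property
    def realized_rare_fraction(self) -> float:
        rows = [r for r in self.truth if r["eligible"]]
        if not rows:
            return 0.0
        return sum(r["is_rare"] for r in rows) / len(rows)


def _pools(
    table: CodonUsageTable, threshold: float
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per-amino-acid rare (<threshold) and non-rare codon pools."""
    rare: dict[str, list[str]] = {}
    common: dict[str, list[str]] = {}
    for aa, codons in gcode.AA_TO_CODONS.items():
        if aa == gcode.STOP:
            continue
        for c in codons:
            (rare if table.rcu[c] < threshold else common).setdefault(
                aa, []
            ).append(c)
    return rare, common


def generate_synthetic_gene(
    spec: SyntheticGeneSpec, tables: Mapping[str, CodonUsageTable]
) -> SyntheticGene:
    """Generate an in-frame gene with a known per-position RCU truth ledger.

    Starts with ATG, ends with TAA, contains no internal stop (only sense
    codons are sampled). Positions after the start are rare with
    probability ``fraction_rare``; amino acids are drawn only from families
    that can satisfy the requested class, so the realized rare fraction is
    binomial around the target (within ~2/√n of it for n positions).
    """
    if spec.region_boundaries:
        segments = [Segment(s, e, t) for s, e, t in spec.region_boundaries]
        region_map = RegionMap(segments)
    else:
        if len(tables) != 1:
            raise ValueError(
                "without region_boundaries exactly one table must be supplied"
            )
        region_map = RegionMap.single(next(iter(tables)), spec.n_codons)
    region_map.validate(spec.n_codons, tables)

    rng = np.random.default_rng(spec.seed)
    pools = {tid: _pools(tables[tid], spec.rare_threshold) for tid in tables}
    for tid, (rare, _) in pools.items():
        if spec.fraction_rare > 0 and not rare:
            raise ValueError(
                f"table {tid!r} has no codons below "
                f"{spec.rare_threshold}% RCU; fraction_rare unreachable"
            )

    codons: list[str] = []
    truth: list[dict] = []
    for pos in range(1, spec.n_codons + 1):
        tid = region_map.table_id_at(pos)
        table = tables[tid]
        rare_pool, common_pool = pools[tid]
        if pos == 1:
            codon, want_rare, eligible = "ATG", False, False
        else:
            want_rare = bool(rng.random() < spec.fraction_rare)
            pool = rare_pool if want_rare else common_pool
            aa = sorted(pool)[rng.integers(len(pool))]
            fam = pool[aa]
            codon = fam[rng.integers(len(fam))]
            eligible = True
        truth.append(
            {
                "position": pos,
                "codon": codon,
                "amino_acid": gcode.translate_codon(codon),
                "native_rcu": table.rcu[codon],
                "table_id": tid,
                "is_rare": table.rcu[codon] < spec.rare_threshold,
                "eligible": eligible,
            }
        )
        codons.append(codon)
    codons.append("TAA")

    return SyntheticGene(
        sequence="".join(codons), truth=truth, region_map=region_map
    )
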
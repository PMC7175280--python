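"""File I/O: FASTA, ledger/profile TSVs, combined JSON/TSV reports.

FASTA goes through Biopython. Sequences are normalized to uppercase DNA on
read (RNA U is converted to T with a log note); IUPAC ambiguity codes are
rejected with the offending position so frame errors surface at the door,
not deep inside an engine.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diagnostics import MetricReport, MinMaxProfile, RareCodonAnnotation
from .harmonize import HarmonizationResult

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_ledger_tsv",
    "write_minmax_tsv",
    "combined_report",
    "write_report_json",
    "write_report_tsv",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

LEDGER_COLUMNS = (
    "position",
    "aa",
    "native_codon",
    "native_rcu",
    "chosen_codon",
    "host_rcu",
    "rule_note",
)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read DNA records as (id, sequence); uppercase, U→T, strict alphabet."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if "U" in seq:
            logger.info("record %s: RNA alphabet converted U->T", rec.id)
            seq = seq.replace("U", "T")
        for i, base in enumerate(seq, start=1):
            if base not in "ACGT":
                raise ValueError(
                    f"record {rec.id}: non-ACGT character {base!r} at "
                    f"position {i}"
                )
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def write_ledger_tsv(result: HarmonizationResult, path: str | Path) -> None:
    """Per-codon substitution ledger as TSV (spec'd column order)."""
    lines = ["\t".join(LEDGER_COLUMNS)]
    for row in result.ledger:
        lines.append(
            "\t".join(
                [
                    str(row.position),
                    row.amino_acid,
                    row.native_codon,
                    f"{row.native_rcu:.4f}",
                    row.chosen_codon,
                    f"{row.host_rcu:.4f}",
                    row.rule_note,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_minmax_tsv(profile: MinMaxProfile, path: str | Path) -> None:
    """%MinMax trace as 3-column TSV: window_start, percent, null_percent."""
    null = dict(profile.null_values or [])
    lines = ["window_start\tpercent\tnull_percent"]
    for start, pct in profile.values:
        null_s = f"{null[start]:.4f}" if start in null else ""
        lines.append(f"{start}\t{pct:.4f}\t{null_s}")
    Path(path).write_text("\n".join(lines) + "\n")


def _flatten(report: dict) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []

    def walk(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k in obj:
                walk(f"{prefix}.{k}" if prefix else str(k), obj[k])
        elif isinstance(obj, (list, tuple)):
            for i, v in enumerate(obj):
                walk(f"{prefix}[{i}]", v)
        else:
            rows.append((prefix, json.dumps(obj)))

    walk("", report)
    return rows


def combined_report(
    metrics: MetricReport | None = None,
    minmax: MinMaxProfile | None = None,
    rare: RareCodonAnnotation | None = None,
    occlusion: dict | None = None,
    motifs: Sequence[dict] | None = None,
    provenance: dict | None = None,
) -> dict:
    """Merge analysis results into one machine-readable report.

    Sections that were not computed are omitted; field order is
    deterministic; the schema is versioned.
    """
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if provenance:
        report["provenance"] = dict(sorted(provenance.items()))
    if metrics is not None:
        report["metrics"] = {
            "cai": metrics.cai,
            "nc": metrics.nc,
            "arcu": metrics.arcu,
            "gc_percent": metrics.gc_percent,
            "n_rare": metrics.n_rare,
            "provenance": dict(sorted(metrics.provenance.items())),
        }
    if minmax is not None:
        report["minmax"] = {
            "window_size": minmax.window_size,
            "table_id": minmax.table_id,
            "values": [[s, p] for s, p in minmax.values],
        }
        if minmax.null_values is not None:
            report["minmax"]["null_values"] = [
                [s, p] for s, p in minmax.null_values
            ]
    if rare is not None:
        report["rare_codons"] = {
            "threshold_points": rare.threshold_points,
            "positions": list(rare.positions),
        }
    if occlusion is not None:
        report["rbs_occlusion"] = dict(occlusion)
    if motifs is not None:
        report["forbidden_motifs"] = list(motifs)
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")


def write_report_tsv(report: dict, path: str | Path) -> None:
    """Flat key\tvalue view of the same report (values JSON-encoded, so the
    two emissions carry identical content)."""
    lines = ["key\tvalue"] + [f"{k}\t{v}" for k, v in _flatten(report)]
    Path(path).write_text("\n".join(lines) + "\n")
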
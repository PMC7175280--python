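"""Translation-initiation window assembly and RBS occlusion analysis.

The ribosomal footprint extends a few nucleotides into the coding region
(+8 here), so the window analysed is the vector 5′ context (e.g. −53…−1)
concatenated with the first 8 coding nucleotides. Secondary structure over
that window either comes from an external thermodynamic folder (RNAfold
dot-bracket output is parsed directly) or from the built-in base-pair
maximization fold — a Nussinov-style dynamic program that maximizes
Watson–Crick (+ optional G·U wobble) pair count. Base-pair maximization is
a qualitative stand-in: it ranks hairpin-forming windows sensibly but does
not reproduce free energies.

A ribosome-binding site (default 5′-AGGAGA-3′) is located in the upstream
part; the window is called *occluded* when any RBS nucleotide is paired in
the structure, *free* otherwise.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

__all__ = [
    "FivePrimeWindow",
    "RBS_MOTIF",
    "build_window",
    "fold_bpmax",
    "import_structure",
    "rbs_occlusion",
    "pair_table",
]

logger = logging.getLogger(__name__)

#: Shine–Dalgarno-type ribosome binding site encoded by the expression vector.
RBS_MOTIF = "AGGAGA"

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass
class FivePrimeWindow:
    """Assembled −N…+8 window with optional secondary structure."""

    upstream: str                       # vector context, positions −N…−1
    coding_prefix: str                  # first coding nucleotides, +1…+8
    rbs_span: tuple[int, int]           # 1-based inclusive, within window
    rbs_matches: tuple[int, ...] = ()   # all motif start offsets found
    structure: str | None = None        # dot-bracket, len == len(window)
    energy: float | None = None         # annotation only (from import)

    @property
    def window(self) -> str:
        return self.upstream + self.coding_prefix

    @property
    def pairing_count(self) -> int:
        if self.structure is None:
            return 0
        return self.structure.count("(")

    @property
    def rbs_paired_fraction(self) -> float:
        if self.structure is None:
            raise ValueError("no structure attached")
        lo, hi = self.rbs_span
        paired = sum(1 for i in range(lo - 1, hi) if self.structure[i] != ".")
        return paired / (hi - lo + 1)


def _clean(seq: str, what: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return s


def build_window(
    vector_utr: str,
    cds: str,
    coding_extent: int = 8,
    rbs_motif: str = RBS_MOTIF,
) -> FivePrimeWindow:
    """Assemble the initiation window: UTR + first *coding_extent* nt of CDS.

    The RBS motif is located by exact search within the upstream part; with
    several matches the rightmost (closest to the start codon) is used and
    all are recorded. Missing motif or too-short CDS raise.
    """
    utr = _clean(vector_utr, "vector UTR")
    cds = _clean(cds, "CDS")
    if len(cds) < coding_extent:
        raise ValueError(
            f"CDS has {len(cds)} nt; need at least {coding_extent} "
            "(ribosomal footprint extent)"
        )
    if not cds.startswith("ATG"):
        logger.warning("CDS does not start with ATG (got %s)", cds[:3])
    motif = _clean(rbs_motif, "RBS motif")
    matches = []
    start = utr.find(motif)
    while start != -1:
        matches.append(start + 1)       # 1-based
        start = utr.find(motif, start + 1)
    if not matches:
        raise ValueError(f"RBS motif {motif} not found in the vector UTR")
    if len(matches) > 1:
        logger.info("RBS motif at offsets %s; using rightmost", matches)
    rbs_start = matches[-1]
    return FivePrimeWindow(
        upstream=utr,
        coding_prefix=cds[:coding_extent],
        rbs_span=(rbs_start, rbs_start + len(motif) - 1),
        rbs_matches=tuple(matches),
    )


def _can_pair(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


def fold_bpmax(seq: str, min_loop: int = 3, allow_gu: bool = True) -> str:
    """Maximum-base-pair dot-bracket structure of *seq* (treated as RNA).

    Nussinov-style dynamic program; hairpin loops must enclose at least
    *min_loop* unpaired bases. Traceback is deterministic: an unpaired 5′
    base is preferred when it loses nothing, otherwise the leftmost pairing
    partner achieving the optimum is taken.
    """
    rna = seq.strip().upper().replace("T", "U")
    n = len(rna)
    if n == 0:
        raise ValueError("empty sequence")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters: {sorted(bad)}")

    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(rna[i], rna[k], allow_gu):
                    inner = N[i + 1][k - 1] if k - 1 > i else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            N[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i][j] == 0:
            continue
        if N[i][j] == N[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(rna[i], rna[k], allow_gu):
                inner = N[i + 1][k - 1] if k - 1 > i else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == N[i][j]:
                    structure[i], structure[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return "".join(structure)


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position, −1 if unpaired; validates
    balance."""
    partners = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            partners[i], partners[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return partners


_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def import_structure(fpw: FivePrimeWindow, dot_bracket_text: str) -> FivePrimeWindow:
    """Attach an externally predicted structure (RNAfold output dialect).

    Accepts multi-line text: optional ``>`` header, optional sequence line,
    then a structure line with an optional trailing ``(energy)``. The
    energy is stored as an annotation only. Length mismatch or unbalanced
    brackets raise.
    """
    structure = None
    energy = None
    for line in dot_bracket_text.splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        if set(line) <= set("ACGUTacgut"):
            continue                     # sequence line
        m = _ENERGY_RE.search(line)
        if m and not set(line[: m.start()].strip()) <= set(".()"):
            continue
        if m:
            energy = float(m.group(1))
            line = line[: m.start()].strip()
        if set(line) <= set(".()") and line:
            structure = line
            break
    if structure is None:
        raise ValueError("no dot-bracket structure line found")
    if len(structure) != len(fpw.window):
        raise ValueError(
            f"structure length {len(structure)} != window length "
            f"{len(fpw.window)}"
        )
    pair_table(structure)                # balance check
    return replace(fpw, structure=structure, energy=energy)


def rbs_occlusion(fpw: FivePrimeWindow) -> dict:
    """Occlusion verdict: ``occluded`` iff ≥1 RBS nucleotide is paired.

    Returns ``{"verdict": "free"|"occluded", "rbs_paired_fraction": f}``.
    """
    if fpw.structure is None:
        raise ValueError("window has no structure; fold or import one first")
    frac = fpw.rbs_paired_fraction
    return {
        "verdict": "occluded" if frac > 0 else "free",
        "rbs_paired_fraction": frac,
    }
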
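"""ORF detection, truncation calls and terpene-synthase motif scanning.

Cloned terpene-synthase transcripts from different grapevine cultivars often
carry SNPs introducing premature stop codons, the prevalent cause of loss of
function in the family.  This module finds the longest ATG-initiated,
stop-terminated open reading frame in the three forward frames, flags
isolates whose predicted protein is short relative to a reference, and scans
proteins for the canonical class-I plant TPS motifs: the N-terminal RRx8W
and the C-terminal metal-binding DDxxD and NSE/DTE motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "OrfCall",
    "MotifHit",
    "find_longest_orf",
    "classify_cds",
    "scan_tps_motifs",
    "MOTIF_PATTERNS",
]

_NT = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWYX")
_STOPS = {"TAA", "TAG", "TGA"}

# Motif consensus patterns over the protein alphabet.  NSE/DTE is an explicit
# simplification of the literature consensus ([ND]Dxx[ST]xxxE core); all
# three are overridable by callers.
MOTIF_PATTERNS: dict[str, str] = {
    "RRx8W": r"RR.{8}W",
    "DDxxD": r"DD..D",
    "NSE/DTE": r"[ND]D[LIV].[ST]...E",
}


@dataclass(frozen=True)
class OrfCall:
    """Longest open reading frame: 0-based half-open, stop codon included."""

    start: int
    end: int
    frame: int
    protein: str


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int        # 0-based position on the protein
    matched: str


def _validate_nt(seq: str) -> str:
    up = seq.upper()
    bad = set(up) - _NT
    if bad:
        raise ValueError(f"invalid nucleotide character(s): {sorted(bad)}")
    return up


def find_longest_orf(seq: str) -> OrfCall | None:
    """Longest ATG-initiated, stop-terminated ORF across the 3 forward frames.

    The returned span includes the stop codon; the protein excludes it.
    Ties (equal length) are broken by the smallest start position.  Returns
    None when no complete ORF exists.
    """
    s = _validate_nt(seq)
    n = len(s)
    best: OrfCall | None = None
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = s[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                end = pos + 3
                length = end - start
                if best is None or length > best.end - best.start or (
                    length == best.end - best.start and start < best.start
                ):
                    protein = str(Seq(s[start : pos]).translate())
                    best = OrfCall(start, end, frame, protein)
                start = None
    return best


def classify_cds(
    isolate_protein: str, reference_protein: str, min_fraction: float = 0.9
) -> tuple[str, float]:
    """Call an isolate full_length or premature_stop by relative protein length.

    An isolate shorter than ``min_fraction`` of the reference protein is
    treated as truncated (loss of function by premature stop); the length
    fraction is returned alongside the call.  The boundary itself counts as
    full length (>= rule).
    """
    if not isolate_protein or not reference_protein:
        raise ValueError("proteins must be non-empty")
    fraction = len(isolate_protein) / len(reference_protein)
    call = "full_length" if fraction >= min_fraction else "premature_stop"
    return call, fraction


def scan_tps_motifs(
    protein: str, patterns: dict[str, str] | None = None
) -> list[MotifHit]:
    """All (possibly overlapping) TPS motif matches in a protein.

    Positions are 0-based.  Hits are sorted by (position, motif name).
    """
    up = protein.upper()
    bad = set(up) - _AA
    if bad:
        raise ValueError(f"invalid amino-acid character(s): {sorted(bad)}")
    pats = MOTIF_PATTERNS if patterns is None else patterns
    hits: list[MotifHit] = []
    for name, pat in pats.items():
        # lookahead so overlapping occurrences are all reported
        for m in re.finditer(rf"(?=({pat}))", up):
            hits.append(MotifHit(name, m.start(), m.group(1)))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits
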
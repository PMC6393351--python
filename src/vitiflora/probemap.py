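"""Remap short microarray probes to gene models by exhaustive k-mismatch matching.

Grapevine terpene synthase (VviTPS) genes are so closely related that
short-oligo probes designed against one gene model frequently cross-hybridize
with paralogues.  This module re-maps every probe against a set of curated
cDNA gene models using a full-length, ungapped Hamming-distance rule (a probe
"binds" a gene if it, or its reverse complement, aligns end-to-end somewhere
on the cDNA with at most ``max_mm`` mismatches) and classifies probes as
unique (one gene), ambiguous (>=2 genes, reported as a "1:n" ratio) or
unmapped.  Only unique probes can be attributed to a single gene and carried
into gene-level expression summaries.

Coordinates are 0-based half-open throughout; ``N`` and IUPAC ambiguity
letters never match anything and therefore count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProbeHit",
    "ProbeGeneMap",
    "ProbeClassification",
    "hamming_matches",
    "build_probe_gene_map",
    "classify_probes",
    "probes_per_gene",
    "reverse_complement",
]

_IUPAC = set("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FORWARD = "forward"
REVCOMP = "reverse-complement"


def _validate(seq: str, what: str) -> str:
    up = seq.upper()
    bad = set(up) - _IUPAC
    if bad:
        raise ValueError(
            f"non-nucleotide character(s) {sorted(bad)} in {what} sequence"
        )
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC nucleotide alphabet."""
    return _validate(seq, "input").translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class ProbeHit:
    """A single full-length placement of a probe on a gene model.

    ``offset`` is the 0-based start of the alignment on the gene's given
    strand; ``orientation`` records whether the probe itself or its reverse
    complement matched.
    """

    probe_id: str
    gene_id: str
    offset: int
    orientation: str
    mismatches: int


@dataclass
class ProbeGeneMap:
    """Cross-hybridization structure: one minimal-mismatch hit per (probe, gene).

    ``probe_ids`` / ``gene_ids`` are the full universes, including probes and
    genes without any hit.
    """

    hits: list[ProbeHit]
    probe_ids: list[str]
    gene_ids: list[str]
    max_mm: int = 2

    def genes_of(self, probe_id: str) -> list[str]:
        return sorted({h.gene_id for h in self.hits if h.probe_id == probe_id})

    def mapped_probes(self) -> set[str]:
        return {h.probe_id for h in self.hits}


@dataclass
class ProbeClassification:
    """Partition of the probe universe into unique / ambiguous / unmapped."""

    unique: set[str]
    ambiguous: dict[str, int]          # probe -> number of genes hit (>= 2)
    unmapped: set[str]
    ambiguity_ratios: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "total_mapped": len(self.unique) + len(self.ambiguous),
            "unique": len(self.unique),
            "ambiguous": len(self.ambiguous),
            "unmapped": len(self.unmapped),
        }


def _encode(seq: str) -> np.ndarray:
    # bytes compare: anything outside A/C/G/T is mapped to 0 and never matches
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    keep = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[~keep] = 0
    # an ambiguity code in BOTH probe and gene must still mismatch: map probe
    # side to 0 and gene side to 0 as well, then treat 0==0 as mismatch via
    # a sentinel shift on one side (done in _scan)
    return arr, keep


def _scan(probe_arr, probe_valid, gene_arr, gene_valid, max_mm: int):
    """All offsets where probe aligns to gene with <= max_mm mismatches."""
    m, n = len(probe_arr), len(gene_arr)
    if m > n:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(gene_arr, m)
    valid_windows = np.lib.stride_tricks.sliding_window_view(gene_valid, m)
    match = (windows == probe_arr) & valid_windows & probe_valid
    mismatches = m - match.sum(axis=1)
    offs = np.nonzero(mismatches <= max_mm)[0]
    return offs, mismatches[offs]


def hamming_matches(
    probe: str, gene: str, max_mm: int = 2
) -> list[tuple[int, str, int]]:
    """Every full-length ungapped placement of ``probe`` on ``gene``.

    Both the probe and its reverse complement are scanned.  Returns
    ``(offset, orientation, mismatches)`` triples sorted by
    (mismatches, offset, forward-before-reverse).

    Parameters
    ----------
    probe, gene : str
        Nucleotide sequences (case-insensitive, IUPAC letters allowed;
        non-ACGT letters always count as mismatches).
    max_mm : int
        Maximum Hamming distance for a placement to be reported.
    """
    if not probe:
        raise ValueError("probe sequence is empty")
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    probe_u = _validate(probe, "probe")
    gene_u = _validate(gene, "gene")
    gene_arr, gene_valid = _encode(gene_u)

    out: list[tuple[int, str, int]] = []
    for orientation, pseq in (
        (FORWARD, probe_u),
        (REVCOMP, reverse_complement(probe_u)),
    ):
        parr, pvalid = _encode(pseq)
        offs, mms = _scan(parr, pvalid, gene_arr, gene_valid, max_mm)
        out.extend((int(o), orientation, int(mm)) for o, mm in zip(offs, mms))
    out.sort(key=lambda t: (t[2], t[0], t[1] != FORWARD))
    return out


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))}")


def build_probe_gene_map(
    probes: Mapping[str, str] | Iterable[tuple[str, str]],
    genes: Mapping[str, str] | Iterable[tuple[str, str]],
    max_mm: int = 2,
    both_strands: bool = True,
) -> ProbeGeneMap:
    """Scan every probe against every gene; keep one minimal-mismatch hit per pair.

    Ties within one (probe, gene) pair are broken by smallest offset, then
    forward orientation before reverse complement, so output is deterministic
    and independent of input order.
    """
    probe_items = list(probes.items()) if isinstance(probes, Mapping) else list(probes)
    gene_items = list(genes.items()) if isinstance(genes, Mapping) else list(genes)
    if not probe_items or not gene_items:
        raise ValueError("probes and genes must be non-empty")
    _check_unique_ids([p for p, _ in probe_items], "probe")
    _check_unique_ids([g for g, _ in gene_items], "gene")

    hits: list[ProbeHit] = []
    # pre-encode genes once
    encoded = []
    for gid, gseq in gene_items:
        arr, valid = _encode(_validate(gseq, f"gene {gid}"))
        encoded.append((gid, arr, valid))

    for pid, pseq in probe_items:
        pu = _validate(pseq, f"probe {pid}")
        orients = [(FORWARD, pu)]
        if both_strands:
            orients.append((REVCOMP, reverse_complement(pu)))
        enc_orients = [(o, *_encode(s)) for o, s in orients]
        for gid, garr, gvalid in encoded:
            best: tuple[int, int, int] | None = None  # (mm, offset, rev?)
            best_orient = FORWARD
            for orientation, parr, pvalid in enc_orients:
                offs, mms = _scan(parr, pvalid, garr, gvalid, max_mm)
                for o, mm in zip(offs, mms):
                    key = (int(mm), int(o), orientation != FORWARD)
                    if best is None or key < best:
                        best = key
                        best_orient = orientation
            if best is not None:
                hits.append(
                    ProbeHit(pid, gid, best[1], best_orient, best[0])
                )
    hits.sort(key=lambda h: (h.probe_id, h.gene_id))
    return ProbeGeneMap(
        hits=hits,
        probe_ids=sorted(p for p, _ in probe_items),
        gene_ids=sorted(g for g, _ in gene_items),
        max_mm=max_mm,
    )


def classify_probes(pg_map: ProbeGeneMap) -> ProbeClassification:
    """Partition probes into unique (1 gene), ambiguous (>=2) and unmapped."""
    gene_counts: dict[str, int] = {}
    for h in pg_map.hits:
        gene_counts[h.probe_id] = gene_counts.get(h.probe_id, 0) + 1
    unique = {p for p, c in gene_counts.items() if c == 1}
    ambiguous = {p: c for p, c in gene_counts.items() if c >= 2}
    unmapped = set(pg_map.probe_ids) - set(gene_counts)
    ratios = {p: f"1:{c}" for p, c in ambiguous.items()}
    return ProbeClassification(
        unique=unique, ambiguous=ambiguous, unmapped=unmapped,
        ambiguity_ratios=ratios,
    )


def probes_per_gene(
    pg_map: ProbeGeneMap,
    classification: ProbeClassification,
    unique_only: bool = True,
) -> dict[str, int]:
    """Number of (unique, by default) probes binding each gene.

    Genes without any qualifying probe get count 0, so the result always
    covers the full gene universe.
    """
    counts = {g: 0 for g in pg_map.gene_ids}
    for h in pg_map.hits:
        if unique_only and h.probe_id not in classification.unique:
            continue
        counts[h.gene_id] += 1
    return counts
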
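"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the study's real inputs so the whole pipeline is
testable without downloads:

* :func:`gen_probe_design` — gene-model cDNAs plus short probes planted
  into one (unique) or several (ambiguous/cross-hybridizing) genes at
  controlled mismatch counts, with rejection sampling guaranteeing no
  accidental near-matches, so the planted unique/ambiguous sets are an
  exact oracle for the probe remapper.
* :func:`gen_expression` — probe x sample RMA-like log2 matrices with an
  optional planted (sample x gene) high-expression block.
* :func:`gen_volatile_study` — a cultivar x stage x replicate volatile
  study (concentration truth with multiplicative lognormal replicate noise)
  together with raw GC-MS peak tables back-computed through calibration
  curves, so quantification round-trips to the truth.

Every generator is deterministic under a fixed seed.  The default volatile
study mirrors the real experiment: Muscat of Alexandria (MA), Sauvignon
Blanc (SB) and Shiraz (SH) flowers at stages EL-18 and EL-26, four
biological replicates, 12 sesquiterpenes with one dominant compound per
cultivar ((E)-beta-farnesene, (E,E)-alpha-farnesene and (+)-valencene,
respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .probemap import hamming_matches
from .volatiles import CalibrationCurve, ConcentrationTable

__all__ = [
    "ProbeDesignTruth",
    "VolatileStudyDesign",
    "gen_probe_design",
    "gen_expression",
    "gen_volatile_study",
    "default_volatile_design",
    "DEFAULT_COMPOUND_MEANS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedProbe:
    probe_id: str
    sequence: str
    targets: dict[str, int]      # gene_id -> planted mismatch count
    offsets: dict[str, int]      # gene_id -> planted offset


@dataclass
class ProbeDesignTruth:
    """Genes + probes with the planted cross-hybridization structure."""

    genes: list[tuple[str, str]]
    probes: list[PlantedProbe]
    expected_unique: set[str]
    expected_ambiguous: dict[str, int]   # probe -> ambiguity degree (>=2)

    def gene_dict(self) -> dict[str, str]:
        return dict(self.genes)

    def probe_dict(self) -> dict[str, str]:
        return {p.probe_id: p.sequence for p in self.probes}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute exactly n_mut distinct positions (Hamming distance n_mut)."""
    if n_mut == 0:
        return seq
    arr = bytearray(seq.encode())
    for pos in rng.choice(len(arr), size=n_mut, replace=False):
        old = arr[pos]
        choices = [b for b in _BASES if b != old]
        arr[pos] = int(rng.choice(choices))
    return arr.decode()


def _place_offsets(
    rng: np.random.Generator, gene_length: int, probe_length: int, n: int
) -> list[int]:
    """n non-overlapping probe offsets inside a gene (stars-and-bars)."""
    free = gene_length - n * probe_length
    if free < 0:
        raise ValueError(
            f"cannot place {n} non-overlapping {probe_length}-mers "
            f"in a {gene_length} nt gene"
        )
    gaps = rng.multinomial(free, [1.0 / (n + 1)] * (n + 1))
    offs, pos = [], 0
    for i in range(n):
        pos += int(gaps[i])
        offs.append(pos)
        pos += probe_length
    return offs


def gen_probe_design(
    n_genes: int,
    probes_per_gene: int,
    n_ambiguous: int,
    mismatch_range: tuple[int, int] = (0, 2),
    probe_length: int = 60,
    gene_length: int = 600,
    seed: int = 0,
    ambiguous_only_genes: int = 0,
    degrees: Sequence[int] | None = None,
    degree_range: tuple[int, int] = (2, 3),
    max_mm_guard: int = 2,
) -> ProbeDesignTruth:
    """Plant probes into random gene backgrounds with known ambiguity.

    Exactly ``n_ambiguous`` probes are planted into >=2 genes (their
    ambiguity degrees taken from ``degrees`` or drawn from
    ``degree_range``); all others into exactly one gene.  When
    ``ambiguous_only_genes`` = k > 0, the first k genes receive no unique
    probes at all (every probe whose home gene they are is ambiguous), so
    exactly ``n_genes - k`` genes retain a unique probe.  Backgrounds are
    rejection-sampled until no probe has an unplanted placement within
    ``max_mm_guard`` mismatches, making the planted truth exact.
    """
    if probe_length > gene_length:
        raise ValueError("probe_length exceeds gene length: impossible design")
    total_probes = n_genes * probes_per_gene
    if n_ambiguous > total_probes:
        raise ValueError("n_ambiguous exceeds the number of probes")
    if not (0 <= mismatch_range[0] <= mismatch_range[1]):
        raise ValueError(f"bad mismatch_range {mismatch_range}")
    if ambiguous_only_genes > n_genes:
        raise ValueError("ambiguous_only_genes exceeds n_genes")
    if n_ambiguous < ambiguous_only_genes * probes_per_gene:
        raise ValueError(
            "n_ambiguous too small to cover ambiguous_only_genes x "
            "probes_per_gene home slots"
        )
    if degrees is not None and len(degrees) != n_ambiguous:
        raise ValueError("degrees must have length n_ambiguous")

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i + 1:03d}" for i in range(n_genes)]

    # choose which (gene, slot) homes hold ambiguous probes
    slots = [(g, s) for g in range(n_genes) for s in range(probes_per_gene)]
    amb_slots = [(g, s) for g, s in slots if g < ambiguous_only_genes]
    remaining_needed = n_ambiguous - len(amb_slots)
    # spread extra ambiguous homes over non-reserved genes, keeping at least
    # one unique slot per gene whenever possible
    pool = [
        (g, s)
        for g in range(ambiguous_only_genes, n_genes)
        for s in range(1, probes_per_gene)
    ]
    if remaining_needed > len(pool):
        pool = [(g, s) for g, s in slots if g >= ambiguous_only_genes]
    if remaining_needed > 0:
        picks = rng.choice(len(pool), size=remaining_needed, replace=False)
        amb_slots += [pool[i] for i in sorted(picks)]
    amb_set = set(amb_slots)

    for attempt in range(50):
        probes: list[PlantedProbe] = []
        planted: dict[int, list[tuple[int, str]]] = {
            g: [] for g in range(n_genes)
        }  # gene -> [(offset, planted copy)]
        deg_iter = iter(degrees) if degrees is not None else None
        k = 0
        for g in range(n_genes):
            for s in range(probes_per_gene):
                pid = f"probe{g * probes_per_gene + s + 1:04d}"
                pseq = _random_seq(rng, probe_length)
                if (g, s) in amb_set:
                    if deg_iter is not None:
                        d = int(next(deg_iter))
                    else:
                        d = int(rng.integers(degree_range[0],
                                             min(degree_range[1], n_genes) + 1))
                    if d > n_genes:
                        raise ValueError(f"ambiguity degree {d} > n_genes")
                    others = [x for x in range(n_genes) if x != g]
                    extra = list(rng.choice(others, size=d - 1, replace=False))
                    targets = [g] + [int(x) for x in extra]
                else:
                    targets = [g]
                tgt_mm: dict[str, int] = {}
                tgt_off: dict[str, int] = {}
                for t in targets:
                    mm = int(rng.integers(mismatch_range[0],
                                          mismatch_range[1] + 1))
                    copy = _mutate(rng, pseq, mm)
                    planted[t].append((0, copy))  # offset placed later
                    tgt_mm[gene_ids[t]] = mm
                    tgt_off[gene_ids[t]] = len(planted[t]) - 1
                probes.append(PlantedProbe(pid, pseq, tgt_mm, tgt_off))
                k += 1

        # lay the planted copies into fresh random backgrounds
        genes: list[tuple[str, str]] = []
        for g in range(n_genes):
            copies = planted[g]
            glen = max(gene_length,
                       len(copies) * (probe_length + 20) + probe_length)
            offs = (
                _place_offsets(rng, glen, probe_length, len(copies))
                if copies else []
            )
            background = bytearray(_random_seq(rng, glen).encode())
            for (pos, (_, copy)) in zip(offs, copies):
                background[pos: pos + probe_length] = copy.encode()
            genes.append((gene_ids[g], background.decode()))
            for i, pos in enumerate(offs):
                copies[i] = (pos, copies[i][1])
        # resolve recorded offsets (index -> position)
        for p in probes:
            p.offsets = {
                gid: planted[gene_ids.index(gid)][idx][0]
                for gid, idx in p.offsets.items()
            }

        if _design_is_clean(probes, genes, max_mm_guard):
            expected_ambiguous = {
                p.probe_id: len(p.targets) for p in probes if len(p.targets) >= 2
            }
            expected_unique = {
                p.probe_id for p in probes if len(p.targets) == 1
            }
            return ProbeDesignTruth(
                genes=genes,
                probes=probes,
                expected_unique=expected_unique,
                expected_ambiguous=expected_ambiguous,
            )
    raise RuntimeError("rejection sampling failed to produce a clean design")


def _design_is_clean(
    probes: list[PlantedProbe], genes: list[tuple[str, str]], max_mm: int
) -> bool:
    """Planted hits are present and minimal; no stray near-matches exist.

    For every (probe, gene): if planted, the best placement must have
    exactly the planted mismatch count (no accidental closer match); if not
    planted, no placement within ``max_mm`` may exist.
    """
    for p in probes:
        scan_mm = max([max_mm, *p.targets.values()])
        for gid, gseq in genes:
            hits = hamming_matches(p.sequence, gseq, scan_mm)
            if gid in p.targets:
                planted_mm = p.targets[gid]
                if not hits or hits[0][2] != planted_mm:
                    return False
                # a second, unplanted placement within max_mm is also a foul
                if any(
                    h[2] <= max_mm and h[0] != p.offsets.get(gid)
                    for h in hits
                ):
                    return False
            elif any(h[2] <= max_mm for h in hits):
                return False
    return True


def gen_expression(
    design: ProbeDesignTruth,
    samples: Sequence[str],
    hotspot: tuple[Sequence[str], Sequence[str], float] | None = None,
    baseline_mean: float = 8.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Probe x sample log2 expression with an optional planted block.

    Each probe's value is its home gene's baseline plus Gaussian noise;
    hotspot cells (sample subset x gene subset, effect size in log2 units)
    are shifted additively.  A probe planted into several genes inherits the
    shift if any of its target genes is in the hotspot.  Returns the matrix
    and the planted truth (empty hotspot when effect size is 0).
    """
    if not samples:
        raise ValueError("sample list is empty")
    rng = np.random.default_rng(seed)
    gene_ids = [g for g, _ in design.genes]
    if hotspot is not None:
        hs_samples, hs_genes, effect = (
            list(hotspot[0]), list(hotspot[1]), float(hotspot[2])
        )
        if not set(hs_samples) <= set(samples):
            raise ValueError("hotspot samples not a subset of samples")
        if not set(hs_genes) <= set(gene_ids):
            raise ValueError("hotspot genes not a subset of genes")
    else:
        hs_samples, hs_genes, effect = [], [], 0.0

    probe_ids = [p.probe_id for p in design.probes]
    values = baseline_mean + rng.normal(
        0.0, noise_sd, size=(len(probe_ids), len(samples))
    )
    hs_gene_set = set(hs_genes)
    hs_col = [j for j, s in enumerate(samples) if s in set(hs_samples)]
    if effect != 0.0 and hs_col:
        for i, p in enumerate(design.probes):
            if set(p.targets) & hs_gene_set:
                values[i, hs_col] += effect
    expr = pd.DataFrame(values, index=probe_ids, columns=list(samples))
    truth: dict[str, object] = {
        "hotspot": (
            {"samples": sorted(hs_samples), "genes": sorted(hs_genes),
             "effect": effect}
            if effect != 0.0 and hs_samples and hs_genes
            else None
        ),
        "baseline_mean": baseline_mean,
        "noise_sd": noise_sd,
    }
    return expr, truth


# ---------------------------------------------------------------------------
# Volatile study
# ---------------------------------------------------------------------------

@dataclass
class VolatileStudyDesign:
    """Cultivar x stage x replicate study with per-cell compound means.

    ``compound_means`` maps (cultivar, stage) -> {compound: µg/g FW};
    replicate noise is multiplicative lognormal with log-scale sigma
    ``noise_sigma``.
    """

    cultivars: list[str]
    stages: list[str]
    replicates: int
    compound_means: Mapping[tuple[str, str], Mapping[str, float]]
    noise_sigma: float = 0.25
    tissue_mass: float = 0.010        # g FW per extraction vial
    is_area: float = 1.0e5            # internal-standard peak area
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for cell, means in self.compound_means.items():
            for comp, m in means.items():
                if m < 0:
                    raise ValueError(
                        f"negative mean for {comp} in cell {cell}"
                    )

    @property
    def compounds(self) -> list[str]:
        comps: list[str] = []
        for means in self.compound_means.values():
            for c in means:
                if c not in comps:
                    comps.append(c)
        return comps


# Default study conditions: per-(cultivar, stage) mean concentrations in
# µg/g FW, chosen once so the noise-free study reproduces the qualitative
# chemotype story — a unique dominant sesquiterpene per cultivar, a ~74%
# MA farnesene drop from EL-18 to EL-26, an ~85% SH (E,E)-alpha-farnesene
# rise, >10-point farnesene flux increases in SB/SH, and humulyl-cascade
# shares spanning ~14.7-18.6% across the six cultivar x stage groups.
DEFAULT_COMPOUND_MEANS: dict[tuple[str, str], dict[str, float]] = {
    ("MA", "EL-18"): {
        "(E)-beta-farnesene": 8.7, "(E,E)-alpha-farnesene": 0.8,
        "(Z,E)-alpha-farnesene": 0.0, "beta-caryophyllene": 1.6,
        "(E)-beta-caryophyllene": 0.1, "alpha-humulene": 0.3,
        "(+)-valencene": 0.6, "7-epi-alpha-selinene": 0.6,
        "alpha-selinene": 0.2, "beta-selinene": 0.1,
        "germacrene D": 0.1, "(+)-aromadendrene": 0.0,
    },
    ("MA", "EL-26"): {
        "(E)-beta-farnesene": 5.0, "(E,E)-alpha-farnesene": 1.0,
        "(Z,E)-alpha-farnesene": 0.1, "beta-caryophyllene": 1.2,
        "(E)-beta-caryophyllene": 0.05, "alpha-humulene": 0.25,
        "(+)-valencene": 0.6, "7-epi-alpha-selinene": 0.6,
        "alpha-selinene": 0.2, "beta-selinene": 0.1,
        "germacrene D": 0.1, "(+)-aromadendrene": 0.0,
    },
    ("SB", "EL-18"): {
        "(E)-beta-farnesene": 2.5, "(E,E)-alpha-farnesene": 12.0,
        "(Z,E)-alpha-farnesene": 0.0, "beta-caryophyllene": 4.4,
        "(E)-beta-caryophyllene": 0.3, "alpha-humulene": 1.15,
        "(+)-valencene": 4.0, "7-epi-alpha-selinene": 4.0,
        "alpha-selinene": 1.5, "beta-selinene": 0.5,
        "germacrene D": 0.8, "(+)-aromadendrene": 0.3,
    },
    ("SB", "EL-26"): {
        "(E)-beta-farnesene": 2.5, "(E,E)-alpha-farnesene": 12.0,
        "(Z,E)-alpha-farnesene": 1.5, "beta-caryophyllene": 2.8,
        "(E)-beta-caryophyllene": 0.19, "alpha-humulene": 0.7,
        "(+)-valencene": 2.0, "7-epi-alpha-selinene": 2.0,
        "alpha-selinene": 0.8, "beta-selinene": 0.2,
        "germacrene D": 0.4, "(+)-aromadendrene": 0.0,
    },
    ("SH", "EL-18"): {
        "(E)-beta-farnesene": 2.0, "(E,E)-alpha-farnesene": 3.0,
        "(Z,E)-alpha-farnesene": 0.0, "beta-caryophyllene": 4.0,
        "(E)-beta-caryophyllene": 0.2, "alpha-humulene": 0.9,
        "(+)-valencene": 10.0, "7-epi-alpha-selinene": 9.5,
        "alpha-selinene": 2.0, "beta-selinene": 0.5,
        "germacrene D": 1.0, "(+)-aromadendrene": 0.5,
    },
    ("SH", "EL-26"): {
        "(E)-beta-farnesene": 2.0, "(E,E)-alpha-farnesene": 5.55,
        "(Z,E)-alpha-farnesene": 1.2, "beta-caryophyllene": 3.8,
        "(E)-beta-caryophyllene": 0.2, "alpha-humulene": 0.8,
        "(+)-valencene": 7.0, "7-epi-alpha-selinene": 6.5,
        "alpha-selinene": 1.5, "beta-selinene": 0.2,
        "germacrene D": 0.6, "(+)-aromadendrene": 0.0,
    },
}


def default_volatile_design(
    noise_sigma: float = 0.25, seed: int = 0
) -> VolatileStudyDesign:
    """The packaged 3-cultivar x 2-stage x 4-replicate x 12-compound study."""
    return VolatileStudyDesign(
        cultivars=["MA", "SB", "SH"],
        stages=["EL-18", "EL-26"],
        replicates=4,
        compound_means=DEFAULT_COMPOUND_MEANS,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _default_curves(
    compounds: Sequence[str], rng: np.random.Generator
) -> dict[str, CalibrationCurve]:
    curves = {}
    for comp in compounds:
        slope = float(rng.uniform(0.5, 2.0))
        intercept = float(rng.uniform(0.0, 0.05))
        curves[comp] = CalibrationCurve(
            compound=comp, slope=slope, intercept=intercept,
            r_squared=1.0, conc_range=(0.0, 1.0),
        )
    return curves


def gen_volatile_study(
    design: VolatileStudyDesign,
    curves: Mapping[str, CalibrationCurve] | None = None,
) -> tuple[ConcentrationTable, pd.DataFrame, dict[str, CalibrationCurve]]:
    """Concentration truth plus matching raw GC-MS peak tables.

    Replicate concentration = cell mean x LogNormal(0, sigma).  Peak areas
    are back-computed through each compound's calibration curve and the
    internal-standard area, so :func:`vitiflora.volatiles.quantify` applied
    to the peak table recovers the truth (exactly when sigma = 0).

    Returns (truth concentrations, long peak table, curves used).
    """
    rng = np.random.default_rng(design.seed)
    compounds = design.compounds
    if curves is None:
        curves = _default_curves(compounds, rng)
    missing = set(compounds) - set(curves)
    if missing:
        raise ValueError(f"no calibration curve for {sorted(missing)}")

    conc_rows, peak_rows = [], []
    for cultivar in design.cultivars:
        for stage in design.stages:
            means = design.compound_means.get((cultivar, stage), {})
            for rep in range(1, design.replicates + 1):
                sid = f"{cultivar}_{stage}_r{rep}"
                row = {"sample_id": sid, "cultivar": cultivar,
                       "stage": stage, "replicate": rep}
                for comp in compounds:
                    mean = float(means.get(comp, 0.0))
                    noise = (
                        float(rng.lognormal(0.0, design.noise_sigma))
                        if design.noise_sigma > 0 else 1.0
                    )
                    conc = mean * noise
                    row[comp] = conc
                    curve = curves[comp]
                    amount = conc * design.tissue_mass   # µg in the vial
                    ratio = curve.slope * amount + curve.intercept
                    peak_rows.append(
                        {
                            "sample_id": sid, "cultivar": cultivar,
                            "stage": stage, "replicate": rep,
                            "compound": comp,
                            "peak_area": ratio * design.is_area,
                            "is_area": design.is_area,
                            "tissue_mass": design.tissue_mass,
                        }
                    )
                conc_rows.append(row)
    wide = pd.DataFrame(conc_rows).set_index("sample_id")
    truth = ConcentrationTable(
        wide=wide, modes={c: "standard" for c in compounds}
    )
    return truth, pd.DataFrame(peak_rows), dict(curves)
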
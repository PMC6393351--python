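import numpy as np
import pandas as pd
import pytest

from vitiflora.synthgen import (
    default_volatile_design,
    gen_probe_design,
    gen_volatile_study,
)


@pytest.fixture(scope="session")
def small_design():
    """5 genes x 2 probes, all unique, short probes for fast scans."""
    return gen_probe_design(
        n_genes=5, probes_per_gene=2, n_ambiguous=0,
        probe_length=24, gene_length=150, seed=1,
    )


@pytest.fixture(scope="session")
def ambiguous_design():
    """8 genes x 2 probes with 3 ambiguous probes of degree 2, 3 and 6."""
    return gen_probe_design(
        n_genes=8, probes_per_gene=2, n_ambiguous=3, degrees=[2, 3, 6],
        probe_length=24, gene_length=150, seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_study():
    """Default 3x2x4x12 volatile study at sigma = 0 (truth == means)."""
    design = default_volatile_design(noise_sigma=0.0, seed=5)
    truth, peaks, curves = gen_volatile_study(design)
    return design, truth, peaks, curves


def brute_force_hamming(probe: str, gene: str, max_mm: int):
    """Independent double-loop scan, both orientations (test oracle)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    probe, gene = probe.upper(), gene.upper()
    rc = "".join(comp.get(b, "N") for b in reversed(probe))
    hits = []
    for orientation, pseq in (("forward", probe), ("reverse-complement", rc)):
        for off in range(len(gene) - len(pseq) + 1):
            mm = 0
            for a, b in zip(pseq, gene[off:off + len(pseq)]):
                if a != b or a not in "ACGT" or b not in "ACGT":
                    mm += 1
            if mm <= max_mm:
                hits.append((off, orientation, mm))
    hits.sort(key=lambda t: (t[2], t[0], t[1] != "forward"))
    return hits


def random_instance(rng: np.random.Generator, plant: bool):
    """One (probe, gene) pair, optionally with a mutated planted copy."""
    plen = int(rng.integers(8, 30))
    glen = int(rng.integers(plen, 300))
    gene = "".join(rng.choice(list("ACGT"), glen))
    if plant and glen >= plen:
        probe = gene[: plen] if rng.random() < 0.5 else gene[-plen:]
        probe = list(probe)
        for pos in rng.choice(plen, size=min(2, plen), replace=False):
            if rng.random() < 0.7:
                probe[pos] = rng.choice(list("ACGT"))
        probe = "".join(probe)
    else:
        probe = "".join(rng.choice(list("ACGT"), plen))
    return probe, gene
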
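"""Generate the synthetic study inputs with planted ground truth.

Writes gene-model FASTA + probe TSV (with planted unique/ambiguous probes),
a probe-level expression matrix with a planted hotspot block, and the
3-cultivar x 2-stage x 4-replicate volatile study (raw peak tables +
calibration standards + concentration truth) under results/synthetic/.
"""

from pathlib import Path

from vitiflora.cli import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main(seed: int = 11) -> None:
    manifest = run_pipeline({}, ["simulate"], OUT, seed=seed)
    files = manifest["stages"]["simulate"]
    print(f"wrote {len(files)} synthetic inputs to {OUT}:")
    for name in sorted(files):
        print(f"  {name}")


if __name__ == "__main__":
    main()
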
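#!/usr/bin/env python
"""Build the synthetic study: a planted proteome, promoter set and qPCR
table emulating the screen's inputs.

Writes the full fixture (proteome FASTA, TMHMM-format predictions,
promoter genome FASTA + TSS table, Ct table, ground-truth manifests)
under results/fixture/.
"""

from pathlib import Path

from e3screen.synthetic import FixtureSpec, emit_fixture

OUT = Path("results/fixture")


def main() -> None:
    spec = FixtureSpec()
    paths = emit_fixture(spec, OUT)
    print(f"fixture: {len(spec.proteins)} planted genes "
          f"({sum(1 for r in spec.proteins if r[1] == 'C3H2C3')} C3H2C3 / "
          f"{sum(1 for r in spec.proteins if r[1] == 'C3HC4')} C3HC4), "
          f"{spec.n_decoys} motif-free decoys, "
          f"{len(spec.promoter_plants)} genes with planted upstream elements")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
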
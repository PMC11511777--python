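#!/usr/bin/env python
"""Stage 2 — simulate amplicon reads with known editing ground truth.

Places an unconstrained editor pair on the stage-1 window and draws
reads from the heteroplasmy-mixture model at its default study
conditions (edited-molecule fraction 0.5, conditional TC-site rate 0.5,
background conversion 0.002, substitution error 0.001, 20,000 reads).

FASTQ goes to scratch/ (bulk data); the truth sidecar tables go to
results/ so stage 3 can score its estimates against them.
"""

import argparse
from pathlib import Path

from mtcbe.genome_model import EditorPair, TaleSite
from mtcbe.simulator import SimulationParams, build_truth, random_amplicon, simulate_reads


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    ap.add_argument("--n-reads", type=int, default=20_000)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    amp = random_amplicon(220, seed=args.seed, id="synthetic_window")
    pair = EditorPair(TaleSite(60, 76, "top", "alpha"), TaleSite(90, 106, "bottom", "alpha"))
    params = SimulationParams(n_reads=args.n_reads, seed=args.seed)
    truth = build_truth(amp, pair, params)
    sim = simulate_reads(truth)
    sim.write(args.scratch / "02_reads.fastq.gz")
    # small truth sidecars -> results; bulk per-molecule table -> scratch
    truth.site_table().to_csv(args.outdir / "02_truth.sites.tsv", sep="\t", index=False)
    (args.outdir / "02_truth.params.json").write_text(truth.params_json())
    sim.molecule_table().to_csv(args.scratch / "02_truth.molecules.tsv", sep="\t", index=False)
    (args.outdir / "02_pair.json").write_text(pair.to_json())

    tab = truth.site_table()
    print(f"simulated {params.n_reads} reads over a {len(amp)}-nt amplicon")
    print(f"spacer {pair.spacer} carries {len(truth.sites)} editable cytosines:")
    print(tab.to_string(index=False))


if __name__ == "__main__":
    main()
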
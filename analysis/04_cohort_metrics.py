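#!/usr/bin/env python
"""Stage 4 — compare a cohort of editors: averages, ratios, significance.

Simulates four editor conditions (a 5'-T-compliant reference pair, a
noncompliant canonical pair, and two unconstrained pairs) with three
replicates each, then computes replicate means ± SD, two-tailed
unpaired t-tests against the compliant reference, amplicon-wide
off-target averages, bystander averages, and max-normalized
on-target-to-off-target ratios.

Writes results/04_replicates.tsv, results/04_stats.tsv and
results/04_cohort.tsv; a per-cytosine editing heatmap goes to
scratch/04_heatmap.png.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mtcbe.genome_model import EditorPair, TaleSite
from mtcbe.metrics import (
    EditingReport,
    aggregate_and_test,
    avg_amplicon_offtarget,
    avg_bystander,
    normalized_ratios,
)
from mtcbe.quantifier import quantify
from mtcbe.simulator import SimulationParams, build_truth, random_amplicon, simulate_reads

#: Editor conditions: conditional rate q0 and background b per editor.
#: The noncompliant canonical pair (V1-V2) is set less active, the
#: compliant reference slightly dirtier off target — the qualitative
#: regime where unconstrained pairs win on specificity.
CONDITIONS = {
    "T1-T2": dict(q0=0.55, b=0.004),
    "V1-V2": dict(q0=0.40, b=0.002),
    "aT1-aT2": dict(q0=0.60, b=0.002),
    "aV1-aV2": dict(q0=0.58, b=0.002),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    ap.add_argument("--n-reads", type=int, default=4000)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    amp = random_amplicon(220, seed=args.seed, id="synthetic_window")
    pair = EditorPair(TaleSite(60, 76, "top", "alpha"), TaleSite(90, 106, "bottom", "alpha"))

    groups, cohort, rep_rows, heat = {}, [], [], {}
    for i, (name, kw) in enumerate(CONDITIONS.items()):
        reps = []
        for r in range(3):
            p = SimulationParams(n_reads=args.n_reads, seed=args.seed + 7919 * (3 * i + r + 1), **kw)
            sim = simulate_reads(build_truth(amp, pair, p))
            _, ntab, _, rates, on = quantify(sim.reads, amp, pair)
            reps.append(on)
            rep_rows.append({"condition": name, "replicate": r, "overall_on_target": on})
        groups[name] = reps
        target_k = max(rates, key=lambda k: rates[k] or 0)
        cohort.append(
            EditingReport(
                sample=name,
                overall_on_target=float(np.mean(reps)),
                per_cytosine=rates,
                target_index=target_k,
                avg_offtarget=avg_amplicon_offtarget(ntab, amp, pair.spacer),
                avg_bystander=avg_bystander(rates, target_k),
            )
        )
        heat[name] = rates

    pd.DataFrame(rep_rows).to_csv(args.outdir / "04_replicates.tsv", sep="\t", index=False)
    stats = aggregate_and_test(groups, reference="T1-T2")
    stats.to_csv(args.outdir / "04_stats.tsv", sep="\t", index=False)
    print(stats.to_string(index=False))

    normalized_ratios(cohort, "off")
    normalized_ratios(cohort, "bystander")
    rows = [
        {
            "sample": c.sample,
            "overall_on_target": round(c.overall_on_target, 3),
            "avg_offtarget": round(c.avg_offtarget, 4),
            "avg_bystander": round(c.avg_bystander, 4),
            **{k: round(v, 4) for k, v in c.ratios.items()},
        }
        for c in cohort
    ]
    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "04_cohort.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    best = max(cohort, key=lambda c: c.ratios["on_off_normalized"])
    print(f"best on/off performer: {best.sample} (normalized ratio 1.0)")

    # per-cytosine heatmap (bulk/binary output -> scratch)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ks = sorted(next(iter(heat.values())))
        mat = np.array([[heat[n][k] or 0 for k in ks] for n in CONDITIONS])
        fig, ax = plt.subplots(figsize=(6, 3))
        im = ax.imshow(mat, aspect="auto", cmap="Blues")
        ax.set_xticks(range(len(ks)), [f"C{k}" for k in ks])
        ax.set_yticks(range(len(CONDITIONS)), list(CONDITIONS))
        fig.colorbar(im, label="% edited")
        fig.tight_layout()
        fig.savefig(args.scratch / "04_heatmap.png", dpi=120)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
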
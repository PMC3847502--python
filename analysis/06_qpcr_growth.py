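"""Relative expression of the qPCR panel and biomass from intracellular protein.

Computes efficiency-corrected (Pfaffl) ratios against the glucose 8-h
calibrator normalized on tef1, with randomization and Welch p-values per
target gene, compares them to the planted true ratios, and converts the
protein growth curve to dry biomass with the 0.35 g/g constant.
"""

import pandas as pd

import lignotx as lx
from _common import ensure_inputs, parse_args


def main() -> None:
    args = parse_args(__doc__)
    synth = ensure_inputs(args.seed, args.outdir)
    experiment = lx.QpcrExperiment.from_tsv(synth / "qpcr.tsv")
    truth = lx.GroundTruth.from_json(synth / "truth.json")

    rows = []
    sample = "ws_24h"
    for gene, true_ratio in truth.qpcr_ratios.items():
        rel = lx.pfaffl_ratio(experiment, gene, sample, seed=args.seed)
        p_rand = lx.rest_randomization_test(experiment, gene, sample, n_iter=1999, seed=args.seed)
        # Welch on the per-replicate ddCt-derived log2 ratios vs zero change:
        a = experiment.cts(gene, experiment.calibrator) - experiment.cts("tef1", experiment.calibrator)
        b = experiment.cts(gene, sample) - experiment.cts("tef1", sample)
        _, _, p_welch = lx.welch_t_test(a, b)
        rows.append(
            {"gene": gene, "sample": sample, "ratio": rel.ratio, "se": rel.se,
             "true_ratio": true_ratio, "p_randomization": p_rand, "p_welch": p_welch}
        )
        print(f"{gene:<10} ratio {rel.ratio:6.2f} (true {true_ratio:g}) "
              f"se {rel.se:.2f}  p_rand {p_rand:.4f}  p_welch {p_welch:.4f}")
    pd.DataFrame(rows).to_csv(args.outdir / "qpcr_ratios.tsv", sep="\t", index=False)

    growth = pd.read_csv(synth / "growth.tsv", sep="\t")
    growth["dry_weight_g_per_l"] = [
        lx.biomass_from_protein(p, c)
        for p, c in zip(growth["protein_g_per_l"], growth["substrate_control_g_per_l"])
    ]
    growth.to_csv(args.outdir / "growth_biomass.tsv", sep="\t", index=False)
    print("biomass (g/L) by time:",
          {f"{t:g}h": round(d, 2) for t, d in zip(growth["time_h"], growth["dry_weight_g_per_l"])})


if __name__ == "__main__":
    main()
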
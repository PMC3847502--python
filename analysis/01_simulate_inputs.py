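"""Generate the synthetic study inputs with planted ground truth.

Writes expression.tsv (log2, three conditions x three replicates),
annotation.tsv (FunCat/KOG/CAZy/secretome labels), promoters.fasta (1-kb
windows with planted GGCW4 sites), qpcr.tsv (Ct replicates for the target
panel), growth.tsv (protein-based growth curve) and truth.json (the planted
labels every downstream script is checked against).
"""

import json

import lignotx as lx
from _common import ensure_inputs, parse_args, study_design


def main() -> None:
    args = parse_args(__doc__)
    synth = ensure_inputs(args.seed, args.outdir)
    design = study_design(args.seed)
    truth = lx.GroundTruth.from_json(synth / "truth.json")
    sizes = {g: list(truth.groups.values()).count(g) for g in lx.expression.GROUPS}
    print(f"wrote synthetic inputs for {design.n_genes} genes to {synth}")
    print(f"planted transcript-group sizes: {json.dumps(sizes)}")
    print(f"planted qPCR ratios: {truth.qpcr_ratios}")
    print(f"mean planted promoter sites/gene: "
          f"{sum(truth.motif_counts.values()) / len(truth.motif_counts):.3f}")


if __name__ == "__main__":
    main()
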
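"""Shared plumbing of the analysis scripts: the study design, paths, input loading."""

from __future__ import annotations

import argparse
from pathlib import Path

import lignotx as lx

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
SYNTH = RESULTS / "synthetic"


def study_design(seed: int) -> lx.SyntheticDesign:
    """The synthetic counterpart of the study: three carbon sources, n=3
    replicates, Table-1-scale group proportions, planted enrichments,
    genome-density promoters and the Figure-5-style qPCR panel."""
    return lx.SyntheticDesign(n_genes=2000, replicates_per_condition=3, seed=seed)


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=7, help="generator seed (default 7)")
    ap.add_argument("--outdir", type=Path, default=RESULTS, help="output directory")
    return ap.parse_args()


def ensure_inputs(seed: int, outdir: Path) -> Path:
    """Generate the synthetic inputs under <outdir>/synthetic if not present."""
    synth = outdir / "synthetic"
    marker = synth / "truth.json"
    if marker.exists():
        return synth
    synth.mkdir(parents=True, exist_ok=True)
    design = study_design(seed)
    matrix, truth = lx.generate_expression(design)
    matrix.to_tsv(synth / "expression.tsv")
    lx.generate_annotation(design, truth).to_tsv(synth / "annotation.tsv")
    promoters, truth = lx.generate_promoters(design, truth)
    promoters.to_fasta(synth / "promoters.fasta")
    experiment, truth = lx.generate_qpcr(design, truth)
    experiment.to_tsv(synth / "qpcr.tsv")
    lx.generate_growth(design).to_csv(synth / "growth.tsv", sep="\t", index=False)
    truth.to_json(synth / "truth.json")
    return synth
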
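"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design: three carbon sources (glucose,
lactose, wheat straw) with replicated log2 expression, seven planted
transcript-group labels, functional-category labels with controlled
enrichment, promoter windows carrying a chosen number of non-overlapping
XYR1 consensus sites, Ct tables with chosen true ratios and amplification
efficiencies, and protein-based growth curves. Default group proportions
mirror the study's 9,129-gene array (1619 A / 288 B / 344 C / 65 D / 804 E /
1100 constitutive / remainder not induced).

Everything is deterministic for a fixed design seed; independent generator
stages draw from independent child streams of that seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GeneAnnotation, GROUPS
from .motifs import IupacMotif, PromoterSet, XYR1_CONSENSUS, scan_sequence
from .assays import QpcrExperiment, PROTEIN_PER_DRY_MASS

#: Table-1-scale genome composition used for the default group proportions
_ARRAY_GENES = 9129
_GROUP_COUNTS = {
    "A": 1619, "B": 288, "C": 344, "D": 65, "E": 804,
    "CONSTITUTIVE": 1100, "NONE": _ARRAY_GENES - (1619 + 288 + 344 + 65 + 804 + 1100),
}

DEFAULT_PROPORTIONS = {g: c / _ARRAY_GENES for g, c in _GROUP_COUNTS.items()}

DEFAULT_FUNCAT_VOCAB = (
    "01.01", "01.03", "01.06.01", "01.06.03", "01.20", "01.25.01",
    "02.01", "02.07", "02.10", "10.01", "10.03", "11.02.03.04", "12.04",
    "14.07.02", "20.01.01", "20.01.01.01", "20.01.03", "20.03.25",
    "20.09.16", "30.01.05", "32.07",
)

DEFAULT_CAZY_FAMILIES = (
    "GH1", "GH3", "GH5", "GH6", "GH7", "GH10", "GH11", "GH12", "GH16",
    "GH18", "GH27", "GH28", "GH30", "GH45", "GH47", "GH55", "GH61",
    "GH74", "CE1", "CE5", "CBM1",
)

DEFAULT_KOG_CLASSES = "JKLABCDEFGHIOPQRSTUVWZ"

#: planted enrichments emulating the study: phospholipid metabolism and DNA
#: synthesis/repair in group A, translation in the constitutive set
DEFAULT_ENRICHED_PAIRS = (
    ("A", "01.06.03", 8.0),
    ("A", "10.01", 5.0),
    ("CONSTITUTIVE", "12.04", 8.0),
)

DEFAULT_QPCR_RATIOS = {"chi18_5": 8.0, "agl1": 4.0, "man1": 0.5, "cel7a": 1.0}


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic dataset; defaults mirror the study design."""

    n_genes: int = 1000
    conditions: tuple[str, ...] = ("glucose", "lactose", "wheat_straw")
    replicates_per_condition: int = 2
    group_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    baseline_mean: float = 6.0          # log2 units
    effect_size: float = 2.0            # log2 units; 4-fold, above the 2-fold cutoff
    within_band_jitter: float = 0.2     # log2 units, pairwise spread of constitutive means
    noise_sd: float = 0.25              # log2 units per replicate
    expression_floor: float = 1.0       # "not expressed" genes sit at floor/2
    category_vocab: tuple[str, ...] = DEFAULT_FUNCAT_VOCAB
    category_base_rate: float = 0.02
    enriched_pairs: tuple[tuple[str, str, float], ...] = DEFAULT_ENRICHED_PAIRS
    cazy_rate: float = 0.023
    secreted_rate: float = 0.08
    sscp_rate: float = 0.02
    orphan_rate: float = 0.03
    unknown_rate: float = 0.35
    kog_rate: float = 0.6
    promoter_length: int = 1000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str = XYR1_CONSENSUS
    planted_sites_per_promoter: dict[str, int] | None = None
    promoter_site_density_bp: float = 1500.0  # used when planted counts are not given
    qpcr_true_ratios: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QPCR_RATIOS))
    efficiencies: dict[str, float] = field(default_factory=dict)
    qpcr_normalizer: str = "tef1"
    qpcr_calibrator: str = "glc_8h"
    qpcr_experiments: int = 2
    qpcr_replicates: int = 3
    ct_noise_sd: float = 0.15  # cycles
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"group_proportions must sum to 1 (got {total!r}); "
                f"check the group_proportions field"
            )
        unknown = set(self.group_proportions) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown transcript groups in group_proportions: {sorted(unknown)}")
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2 for the DE stage")
        if not self.effect_size > 1.0:  # log2(fold_change_min) with the default 2-fold cutoff
            raise ValueError("effect_size must exceed log2 of the fold-change cutoff (1.0)")
        if not self.within_band_jitter < np.log2(1.4):
            raise ValueError("within_band_jitter must stay inside the +/-1.4-fold band")
        for gene, e in self.efficiencies.items():
            if not (1.0 < e <= 2.0):
                raise ValueError(f"efficiency for {gene!r} must be in (1, 2]: {e}")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([self.seed, stream])

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """Planted truth accumulated across generator stages."""

    groups: dict[str, str] = field(default_factory=dict)
    categories: dict[str, list[str]] = field(default_factory=dict)
    motif_counts: dict[str, int] = field(default_factory=dict)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)
    qpcr_ratios: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def assign_groups(design: SyntheticDesign) -> dict[str, str]:
    """Deterministic planted group labels (largest-remainder apportionment).

    The label structure depends only on the design, not on the noise seed,
    so different seeds share identical ground truth.
    """
    genes = design.gene_ids()
    props = {g: design.group_proportions.get(g, 0.0) for g in GROUPS}
    raw = {g: p * design.n_genes for g, p in props.items()}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    short = design.n_genes - sum(counts.values())
    by_frac = sorted(raw, key=lambda g: (raw[g] - np.floor(raw[g]), g), reverse=True)
    for g in by_frac[:short]:
        counts[g] += 1
    labels: dict[str, str] = {}
    i = 0
    for g in GROUPS:
        for _ in range(counts[g]):
            labels[genes[i]] = g
            i += 1
    return labels


def _true_means(design: SyntheticDesign, group: str, rng: np.random.Generator) -> np.ndarray:
    """True (glucose, lactose, wheat_straw) log2 means for one gene."""
    b, e = design.baseline_mean, design.effect_size
    if group == "A":
        return np.array([b, b, b + e])
    if group == "B":
        return np.array([b, b + e, b])
    if group == "C":
        return np.array([b, b + e, b + 2 * e])
    if group == "D":
        return np.array([b, b + 2 * e, b + e])
    if group == "E":
        return np.array([b, b + e, b + e])
    if group == "CONSTITUTIVE":
        j = design.within_band_jitter / 2.0
        return b + rng.uniform(-j, j, size=3)
    # NONE: at/below the expression floor everywhere
    return np.full(3, design.expression_floor / 2.0)


def generate_expression(design: SyntheticDesign) -> tuple[ExpressionMatrix, GroundTruth]:
    """Replicated three-condition log2 expression with planted transcript groups."""
    if list(design.conditions) != ["glucose", "lactose", "wheat_straw"]:
        raise ValueError("generate_expression models the glucose/lactose/wheat_straw design")
    labels = assign_groups(design)
    genes = design.gene_ids()
    rng = design.rng(0)
    n_rep = design.replicates_per_condition
    means = np.vstack([_true_means(design, labels[g], rng) for g in genes])
    noise = rng.normal(0.0, design.noise_sd, size=(len(genes), 3, n_rep)) if design.noise_sd > 0 else np.zeros((len(genes), 3, n_rep))
    values = means[:, :, None] + noise
    cols = pd.MultiIndex.from_tuples(
        [(c, r) for c in design.conditions for r in range(1, n_rep + 1)],
        names=["condition", "replicate"],
    )
    flat = values.reshape(len(genes), 3 * n_rep)
    matrix = ExpressionMatrix(pd.DataFrame(flat, index=pd.Index(genes, name="gene_id"), columns=cols))
    return matrix, GroundTruth(groups=labels)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(design: SyntheticDesign, truth: GroundTruth) -> GeneAnnotation:
    """Category labels with controlled per-group enrichment.

    Baseline category membership is independent of the transcript group with
    probability ``category_base_rate``; for every (group, category, m) in
    ``enriched_pairs`` the membership odds for that group's genes are
    multiplied by m. Flags (CAZy, secreted, SSCP, orphan, unknown) are drawn
    at flat configurable rates.
    """
    for grp, cat, _ in design.enriched_pairs:
        if cat not in design.category_vocab:
            raise ValueError(f"enriched_pairs references unknown category {cat!r}")
        if grp not in GROUPS:
            raise ValueError(f"enriched_pairs references unknown group {grp!r}")
    if not truth.groups:
        raise ValueError("truth must carry group labels from generate_expression")

    rng = design.rng(1)
    genes = list(truth.groups)
    group_arr = np.array([truth.groups[g] for g in genes])
    base = design.category_base_rate
    base_odds = base / (1.0 - base)
    mult = {(grp, cat): m for grp, cat, m in design.enriched_pairs}

    funcat: list[list[str]] = [[] for _ in genes]
    for cat in design.category_vocab:
        probs = np.full(len(genes), base)
        for grp in set(g for g, c in mult if c == cat):
            m = mult[(grp, cat)]
            probs = np.where(group_arr == grp, base_odds * m / (1 + base_odds * m), probs)
        hit = rng.random(len(genes)) < probs
        for i in np.nonzero(hit)[0]:
            funcat[i].append(cat)

    n = len(genes)
    cazy_flag = rng.random(n) < design.cazy_rate
    families = rng.choice(DEFAULT_CAZY_FAMILIES, size=n)
    secreted = (rng.random(n) < design.secreted_rate) | (cazy_flag & (rng.random(n) < 0.5))
    sscp = secreted & ~cazy_flag & (rng.random(n) < design.sscp_rate / design.secreted_rate)
    orphan = rng.random(n) < design.orphan_rate
    unknown = rng.random(n) < design.unknown_rate
    kog = np.where(
        rng.random(n) < design.kog_rate,
        rng.choice(list(DEFAULT_KOG_CLASSES), size=n),
        "",
    )

    table = pd.DataFrame(
        {
            "funcat_codes": funcat,
            "kog_class": kog,
            "cazy_families": [[families[i]] if cazy_flag[i] else [] for i in range(n)],
            "secreted": secreted,
            "sscp": sscp,
            "orphan": orphan,
            "unknown": unknown,
            "display_name": ["" for _ in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth.categories = {g: list(codes) for g, codes in zip(genes, funcat)}
    return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _purge_matches(seq: np.ndarray, motif: IupacMotif, rng: np.random.Generator,
                   probs: np.ndarray) -> np.ndarray:
    """Resample every window matching the motif on either strand until clean."""
    from .motifs import _candidate_positions

    k = len(motif)
    rc = motif.reverse_complement()
    for _ in range(200):
        cands = set(_candidate_positions(seq, motif)) | set(_candidate_positions(seq, rc))
        if not cands:
            return seq
        for p in cands:
            seq[p : p + k] = rng.choice(4, size=k, p=probs)
    raise RuntimeError("could not purge motif matches from background sequence")


def generate_promoters(
    design: SyntheticDesign, truth: GroundTruth | None = None
) -> tuple[PromoterSet, GroundTruth]:
    """Promoter windows carrying exactly the planted non-overlapping motif counts.

    Background sequence is drawn from ``base_composition`` with all
    motif-matching windows (either strand) rejected and resampled; the
    planted sites are then inserted at recorded non-overlapping positions
    and the result is verified with the scanner, so a scan of the output
    returns exactly the planted counts.
    """
    truth = truth or GroundTruth()
    motif = IupacMotif(design.motif)
    k = len(motif)
    L = design.promoter_length
    if L < k:
        raise ValueError("promoter_length must be at least the motif length")
    planted = design.planted_sites_per_promoter
    rng = design.rng(2)
    if planted is None:
        lam = L / design.promoter_site_density_bp
        genes = design.gene_ids()
        planted = {g: int(c) for g, c in zip(genes, rng.poisson(lam, size=len(genes)))}
    probs = np.asarray(design.base_composition, dtype=float)
    base_letters = np.array(list("ACGT"))

    seqs: dict[str, str] = {}
    for gene, count in planted.items():
        if count * k > L:
            raise ValueError(f"cannot fit {count} non-overlapping sites in {L} bp for gene {gene!r}")
        for _attempt in range(50):
            enc = rng.choice(4, size=L, p=probs).astype(np.int8)
            enc = _purge_matches(enc, motif, rng, probs)
            positions = _place_sites(rng, L, k, count)
            for p in positions:
                enc[p : p + k] = _instantiate(motif, rng)
            seq = "".join(base_letters[enc])
            got_pos, _ = scan_sequence(seq, motif, strands="both")
            if len(got_pos) == count and got_pos == positions:
                seqs[gene] = seq
                truth.motif_counts[gene] = count
                truth.motif_positions[gene] = positions
                break
        else:
            raise RuntimeError(f"failed to construct promoter for {gene!r}")
    return PromoterSet(seqs, window_length=L), truth


def _place_sites(rng: np.random.Generator, L: int, k: int, count: int) -> list[int]:
    """Random non-overlapping start positions, left-to-right sorted."""
    if count == 0:
        return []
    # draw gaps: distribute the free space among count+1 gaps
    free = L - count * k
    cuts = np.sort(rng.choice(free + 1, size=count, replace=True))
    positions = [int(cuts[i]) + i * k for i in range(count)]
    return positions


def _instantiate(motif: IupacMotif, rng: np.random.Generator) -> np.ndarray:
    from .motifs import _BASE_INDEX, IUPAC

    out = []
    for letter in motif.pattern:
        choices = [c for c in IUPAC[letter] if c != "N"]
        out.append(_BASE_INDEX[rng.choice(choices)])
    return np.array(out, dtype=np.int8)


# ---------------------------------------------------------------------------
# qPCR and growth
# ---------------------------------------------------------------------------

def generate_qpcr(design: SyntheticDesign, truth: GroundTruth | None = None) -> tuple[QpcrExperiment, GroundTruth]:
    """Ct tables generated by inverting the efficiency-corrected ratio model.

    One treatment sample (wheat straw, 24 h) is compared against the
    calibrator (glucose, 8 h); true ratios per target gene come from
    ``qpcr_true_ratios``. Normalizer Cts share one true level in both
    samples, so with zero Ct noise the Pfaffl ratio recovers the planted
    ratios exactly.
    """
    truth = truth or GroundTruth()
    if design.qpcr_normalizer in design.qpcr_true_ratios:
        raise ValueError("the normalizer gene cannot carry a planted ratio")
    if not design.qpcr_true_ratios:
        raise ValueError("qpcr_true_ratios must name at least one target gene")
    eff = {g: design.efficiencies.get(g, 2.0) for g in design.qpcr_true_ratios}
    eff[design.qpcr_normalizer] = design.efficiencies.get(design.qpcr_normalizer, 2.0)

    rng = design.rng(3)
    rows = []
    samples = [
        (design.qpcr_calibrator, "glucose", 8.0),
        ("ws_24h", "wheat_straw", 24.0),
    ]
    base_ct = {design.qpcr_normalizer: 20.0}
    for g in design.qpcr_true_ratios:
        base_ct[g] = 24.0
    for gene in list(design.qpcr_true_ratios) + [design.qpcr_normalizer]:
        for sample, condition, time_h in samples:
            if gene == design.qpcr_normalizer or sample == design.qpcr_calibrator:
                true_ct = base_ct[gene]
            else:
                ratio = design.qpcr_true_ratios[gene]
                true_ct = base_ct[gene] - np.log(ratio) / np.log(eff[gene])
            for exp_id in range(1, design.qpcr_experiments + 1):
                for rep in range(1, design.qpcr_replicates + 1):
                    ct = true_ct + (rng.normal(0.0, design.ct_noise_sd) if design.ct_noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "sample": sample, "condition": condition, "time_h": time_h,
                            "gene": gene, "experiment": exp_id, "replicate": rep,
                            "ct": ct,
                        }
                    )
    experiment = QpcrExperiment(
        pd.DataFrame(rows),
        efficiencies=eff,
        normalizer=design.qpcr_normalizer,
        calibrator=design.qpcr_calibrator,
    )
    truth.qpcr_ratios = dict(design.qpcr_true_ratios)
    return experiment, truth


def generate_growth(
    design: SyntheticDesign,
    times_h: Sequence[float] = (24.0, 48.0, 72.0, 96.0),
    max_dry_weight: float = 4.0,
    control_protein: float = 0.05,
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Protein-based growth curve: logistic dry weight re-expressed as protein.

    Emulates the indirect biomass measurement on an insoluble substrate:
    protein = 0.35 * dry_weight + substrate control, plus Gaussian assay
    noise. Columns: time_h, protein_g_per_l, substrate_control_g_per_l,
    true_dry_weight_g_per_l.
    """
    rng = design.rng(4)
    t = np.asarray(times_h, dtype=float)
    dw = max_dry_weight / (1.0 + np.exp(-(t - 48.0) / 12.0))
    protein = PROTEIN_PER_DRY_MASS * dw + control_protein
    if noise_sd > 0:
        protein = np.maximum(0.0, protein + rng.normal(0.0, noise_sd, size=t.size))
    return pd.DataFrame(
        {
            "time_h": t,
            "protein_g_per_l": protein,
            "substrate_control_g_per_l": control_protein,
            "true_dry_weight_g_per_l": dw,
        }
    )
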
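"""qPCR relative-expression statistics and protein-based biomass estimation.

Relative expression follows the efficiency-corrected ratio model

    R = E_target^(Ct_t,calibrator - Ct_t,sample) / E_ref^(Ct_r,calibrator - Ct_r,sample)

with replicate-mean Ct values, normalized on a reference gene (tef1 by
default) and expressed against a calibrator sample (glucose, 8 h). The
significance of a ratio != 1 comes from a fixed-reallocation randomization
test that jointly shuffles per-replicate (target, reference) Ct pairs
between the sample and calibrator groups. An unequal-variance (Welch) t-test
is provided as the second route.

Biomass of cultures on insoluble substrates is estimated from intracellular
protein assuming 0.35 g protein per g dry mass, corrected by uninoculated
substrate controls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

PROTEIN_PER_DRY_MASS = 0.35  # g intracellular protein per g dry cell mass


# ---------------------------------------------------------------------------
# efficiency
# ---------------------------------------------------------------------------

@dataclass
class EfficiencyFit:
    """Amplification efficiency from a dilution-series standard curve."""

    gene: str
    slope: float
    efficiency: float  # E = 10^(-1/slope); E=2 is perfect doubling
    r_squared: float


def fit_efficiency(dilutions: Sequence[float], cts: Sequence[float], gene: str = "") -> EfficiencyFit:
    """OLS of Ct on log10 relative input over >=3 dilution levels.

    A non-negative slope means the assay did not amplify and is rejected.
    """
    d = np.asarray(dilutions, dtype=float)
    c = np.asarray(cts, dtype=float)
    if d.size != c.size:
        raise ValueError("dilutions and cts must have equal length")
    if np.unique(d).size < 3:
        raise ValueError("efficiency fit needs at least 3 distinct dilution levels")
    if (d <= 0).any():
        raise ValueError("dilutions must be positive")
    fit = stats.linregress(np.log10(d), c)
    if fit.slope >= 0:
        raise ValueError(f"invalid assay for {gene or 'gene'}: non-negative slope {fit.slope:.3g}")
    return EfficiencyFit(
        gene=gene,
        slope=float(fit.slope),
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# experiment container
# ---------------------------------------------------------------------------

@dataclass
class QpcrExperiment:
    """Long-format Ct measurements plus per-gene efficiencies.

    ``measurements`` columns: sample, condition, time_h, gene, experiment,
    replicate, ct. Efficiencies are linear-scale E values in (1, 2.2].
    """

    measurements: pd.DataFrame
    efficiencies: dict[str, float]
    normalizer: str = "tef1"
    calibrator: str = "glc_8h"

    REQUIRED = ("sample", "condition", "time_h", "gene", "experiment", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.measurements.columns]
        if missing:
            raise ValueError(f"measurement table lacks columns {missing}")
        ct = self.measurements["ct"].to_numpy(dtype=float)
        if ((ct <= 0) | (ct >= 45)).any():
            raise ValueError("Ct values must lie in (0, 45)")
        for gene, e in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                raise ValueError(f"efficiency for {gene!r} outside (1, 2.2]: {e}")
        samples = set(self.measurements["sample"])
        with_norm = set(
            self.measurements.loc[self.measurements["gene"] == self.normalizer, "sample"]
        )
        if samples - with_norm:
            raise ValueError(
                f"samples without normalizer ({self.normalizer!r}) Cts: {sorted(samples - with_norm)}"
            )

    def cts(self, gene: str, sample: str) -> np.ndarray:
        """Replicate Ct values for one (gene, sample), pooled over experiments."""
        m = self.measurements
        sel = m[(m["gene"] == gene) & (m["sample"] == sample)]
        if sel.empty:
            raise KeyError(f"no Ct values for gene {gene!r} in sample {sample!r}")
        return sel.sort_values(["experiment", "replicate"])["ct"].to_numpy(dtype=float)

    def efficiency(self, gene: str) -> float:
        if gene not in self.efficiencies:
            raise KeyError(f"no efficiency for gene {gene!r}")
        return self.efficiencies[gene]

    def to_tsv(self, path) -> None:
        out = self.measurements.copy()
        out["efficiency"] = out["gene"].map(self.efficiencies)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, normalizer: str = "tef1", calibrator: str = "glc_8h") -> "QpcrExperiment":
        t = pd.read_csv(path, sep="\t")
        eff = t.groupby("gene")["efficiency"].first().to_dict()
        return cls(
            t.drop(columns=["efficiency"]),
            {str(g): float(e) for g, e in eff.items()},
            normalizer=normalizer,
            calibrator=calibrator,
        )


@dataclass
class RelativeExpression:
    """Efficiency-corrected expression ratio of a gene in a sample vs the calibrator."""

    gene: str
    sample: str
    ratio: float
    se: float
    p_randomization: float | None = None


# ---------------------------------------------------------------------------
# ratios and tests
# ---------------------------------------------------------------------------

def _log_ratio(
    e_gene: float,
    e_norm: float,
    gene_cal: np.ndarray,
    gene_sam: np.ndarray,
    norm_cal: np.ndarray,
    norm_sam: np.ndarray,
) -> float:
    dct_gene = gene_cal.mean() - gene_sam.mean()
    dct_norm = norm_cal.mean() - norm_sam.mean()
    return dct_gene * np.log(e_gene) - dct_norm * np.log(e_norm)


def pfaffl_ratio(
    experiment: QpcrExperiment,
    gene: str,
    sample: str,
    max_combinations: int = 4096,
    seed: int | None = None,
) -> RelativeExpression:
    """Efficiency-corrected relative expression with a resampling-based SE.

    The ratio uses replicate-mean Cts. The standard error comes from the
    spread of ratios over replicate combinations (one replicate drawn per
    (gene/normalizer x sample/calibrator) group; exhaustive when the
    cartesian product is small, seeded subsampling otherwise).
    """
    e_gene = experiment.efficiency(gene)
    e_norm = experiment.efficiency(experiment.normalizer)
    g_cal = experiment.cts(gene, experiment.calibrator)
    g_sam = experiment.cts(gene, sample)
    n_cal = experiment.cts(experiment.normalizer, experiment.calibrator)
    n_sam = experiment.cts(experiment.normalizer, sample)

    log_r = _log_ratio(e_gene, e_norm, g_cal, g_sam, n_cal, n_sam)

    sizes = (g_cal.size, g_sam.size, n_cal.size, n_sam.size)
    total = int(np.prod(sizes))
    if total <= max_combinations:
        combos = itertools.product(g_cal, g_sam, n_cal, n_sam)
        logs = np.array(
            [
                (a - b) * np.log(e_gene) - (c - d) * np.log(e_norm)
                for a, b, c, d in combos
            ]
        )
    else:
        rng = np.random.default_rng(seed)
        logs = (
            rng.choice(g_cal, max_combinations) - rng.choice(g_sam, max_combinations)
        ) * np.log(e_gene) - (
            rng.choice(n_cal, max_combinations) - rng.choice(n_sam, max_combinations)
        ) * np.log(e_norm)
    ratios = np.exp(logs)
    return RelativeExpression(
        gene=gene,
        sample=sample,
        ratio=float(np.exp(log_r)),
        se=float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
    )


def rest_randomization_test(
    experiment: QpcrExperiment,
    gene: str,
    sample: str,
    n_iter: int = 2000,
    seed: int | None = None,
) -> float:
    """Fixed-reallocation randomization p-value for H0: ratio = 1.

    Per-replicate (target Ct, normalizer Ct) pairs from the sample and the
    calibrator are pooled and randomly reallocated to two groups of the
    original sizes; the efficiency-corrected log ratio is recomputed each
    time. Two-sided p = fraction of reallocations with |log ratio| at least
    the observed one, with the +1/(n_iter+1) small-sample correction.
    """
    e_gene = experiment.efficiency(gene)
    e_norm = experiment.efficiency(experiment.normalizer)
    g_cal = experiment.cts(gene, experiment.calibrator)
    g_sam = experiment.cts(gene, sample)
    n_cal = experiment.cts(experiment.normalizer, experiment.calibrator)
    n_sam = experiment.cts(experiment.normalizer, sample)
    if min(g_cal.size, g_sam.size) < 3:
        raise ValueError("randomization test needs >=3 replicates per group")
    if g_cal.size != n_cal.size or g_sam.size != n_sam.size:
        raise ValueError("target and normalizer replicate counts must pair up")

    obs = abs(_log_ratio(e_gene, e_norm, g_cal, g_sam, n_cal, n_sam))

    gene_all = np.concatenate([g_sam, g_cal])
    norm_all = np.concatenate([n_sam, n_cal])
    n_s = g_sam.size
    n_tot = gene_all.size
    rng = np.random.default_rng(seed)
    # vectorized reallocations: each row of idx is a permutation of 0..n_tot-1
    idx = np.argsort(rng.random((n_iter, n_tot)), axis=1)
    g_perm = gene_all[idx]
    n_perm = norm_all[idx]
    dct_gene = g_perm[:, n_s:].mean(axis=1) - g_perm[:, :n_s].mean(axis=1)
    dct_norm = n_perm[:, n_s:].mean(axis=1) - n_perm[:, :n_s].mean(axis=1)
    log_r = dct_gene * np.log(e_gene) - dct_norm * np.log(e_norm)
    count = int((np.abs(log_r) >= obs - 1e-12).sum())
    return (count + 1.0) / (n_iter + 1.0)


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch unequal-variance t-test: returns (t, df, two-sided p).

    Conventions for degenerate inputs: both variances zero with equal means
    -> p = 1; both zero with different means -> p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test needs >=2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, float(a.size + b.size - 2), 1.0
        warnings.warn("both groups have zero variance but different means", stacklevel=2)
        return float(np.inf if diff > 0 else -np.inf), float(a.size + b.size - 2), 0.0
    se2 = va / a.size + vb / b.size
    t = diff / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.size**2 * (a.size - 1)) + vb**2 / (b.size**2 * (b.size - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

@dataclass
class GrowthSample:
    """One growth-curve point: protein measurement and derived dry weight."""

    time_h: float
    protein_g_per_l: float
    substrate_control_g_per_l: float = 0.0
    protein_per_dry_mass: float = PROTEIN_PER_DRY_MASS
    dry_weight_g_per_l: float = field(init=False)

    def __post_init__(self) -> None:
        self.dry_weight_g_per_l = biomass_from_protein(
            self.protein_g_per_l, self.substrate_control_g_per_l, self.protein_per_dry_mass
        )


def biomass_from_protein(
    protein_g_per_l: float,
    control_g_per_l: float = 0.0,
    protein_per_dry_mass: float = PROTEIN_PER_DRY_MASS,
) -> float:
    """Dry biomass (g/L) from intracellular protein, substrate-control corrected.

    dry_weight = max(0, protein - control) / protein_per_dry_mass. A control
    above the measurement yields 0 with a warning.
    """
    if protein_g_per_l < 0 or control_g_per_l < 0:
        raise ValueError("protein measurements must be non-negative")
    if protein_per_dry_mass <= 0:
        raise ValueError("protein_per_dry_mass must be positive")
    corrected = protein_g_per_l - control_g_per_l
    if corrected < 0:
        warnings.warn("substrate control exceeds measured protein; biomass floored at 0", stacklevel=2)
        return 0.0
    return corrected / protein_per_dry_mass
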
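"""Expression matrices, differential expression and transcript-group classification.

The central object is :class:`ExpressionMatrix`: a genes x samples table of
log2 expression values where each sample is a (condition, replicate) pair.
Differential expression against a glucose reference, combined with a direct
wheat-straw-vs-lactose contrast, partitions the gene universe into the five
transcript groups used throughout the analysis:

A   up on wheat straw only
B   up on lactose only
C   up on both, >= wl_fold_min stronger on wheat straw
D   up on both, >= wl_fold_min stronger on lactose
E   up on both, comparably strong
CONSTITUTIVE   expressed on all carbon sources within a +/-1.4-fold band
NONE           everything else (not expressed, or not significantly induced)

"Up" means a fold change of at least ``fold_change_min`` (linear scale,
computed from differences of log2 condition means, i.e. geometric-mean
ratios) at ``p < p_max`` from a two-sample test on the log2 replicate values.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("A", "B", "C", "D", "E", "CONSTITUTIVE", "NONE")

#: display clipping range used by the heat maps (log2 units)
DISPLAY_RANGE = (0.0, 16.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with (condition, replicate) columns.

    ``values`` is indexed by gene_id and carries a two-level column index
    (condition, replicate). Values must be finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.columns, pd.MultiIndex) or v.columns.nlevels != 2:
            raise ValueError("values must have (condition, replicate) MultiIndex columns")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id rows: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].tolist()
            raise ValueError(f"duplicate (condition, replicate) columns: {dups}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        self.values = v.astype(float)

    # -- basic accessors ----------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond, _ in self.values.columns:
            seen.setdefault(cond, None)
        return list(seen)

    def n_replicates(self, condition: str) -> int:
        return sum(1 for c, _ in self.values.columns if c == condition)

    def condition_values(self, condition: str) -> np.ndarray:
        """Replicate values for one condition as a (genes, replicates) array."""
        cols = [c for c in self.values.columns if c[0] == condition]
        if not cols:
            raise KeyError(f"condition {condition!r} not present")
        return self.values.loc[:, cols].to_numpy(dtype=float)

    def condition_means(self) -> pd.DataFrame:
        """Per-gene arithmetic mean of log2 replicate values, per condition."""
        out = {}
        for cond in self.conditions:
            out[cond] = self.condition_values(cond).mean(axis=1)
        return pd.DataFrame(out, index=self.values.index)

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{c}.{r}" for c, r in flat.columns]
        flat.index.name = "gene_id"
        flat.to_csv(path, sep="\t")


def read_expression(path, raw: bool = False) -> ExpressionMatrix:
    """Read a gene x sample TSV whose header encodes samples as ``condition.replicate``.

    With ``raw=True`` intensities are transformed by log2(x + 1).
    Non-numeric cells, duplicate gene ids and malformed headers are rejected
    with messages naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    cols = []
    for name in df.columns:
        cond, dot, rep = str(name).rpartition(".")
        if not dot or not rep.isdigit():
            raise ValueError(f"sample column {name!r} is not of the form condition.replicate")
        cols.append((cond, int(rep)))
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric value at gene {row!r}, column {col!r}")
        df[col] = coerced
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_id rows: {dups}")
    values = df.astype(float)
    if raw:
        if (values.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative for log2(x+1)")
        values = np.log2(values + 1.0)
    values.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"])
    return ExpressionMatrix(values)


@dataclass
class Thresholds:
    """Cutoffs of the transcript-group classification.

    fold_change_min   linear fold change calling a gene "up" vs glucose (default 2.0)
    p_max             significance cutoff for the per-gene test (default 0.05)
    constitutive_band linear band for "comparable level" across conditions (default 1.4)
    expression_floor  log2 level below which a gene counts as not expressed (default 1.0)
    wl_fold_min       linear fold change splitting C/D from E on the direct
                      wheat-straw-vs-lactose contrast (default 2.0)
    """

    fold_change_min: float = 2.0
    p_max: float = 0.05
    constitutive_band: float = 1.4
    expression_floor: float = 1.0
    wl_fold_min: float = 2.0

    def __post_init__(self) -> None:
        if not self.fold_change_min > 1:
            raise ValueError("fold_change_min must exceed 1")
        if not (1 < self.constitutive_band < self.fold_change_min):
            raise ValueError("constitutive_band must lie strictly between 1 and fold_change_min")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must be in (0, 1]")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

DEMethod = Literal["student", "welch", "permutation"]


def differential_expression(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    method: DEMethod = "student",
    n_perm: int = 1999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene contrast of two conditions on log2 replicate values.

    Returns a DataFrame indexed by gene_id with columns log2_fc, p_value,
    mean_a, mean_b where log2_fc = mean(log2 a) - mean(log2 b). The default
    test is the pooled-variance two-sample t; "welch" and "permutation"
    (mean-difference randomization) are available. No multiple-testing
    correction is applied.

    Degenerate convention: if both groups have zero variance the p-value is
    1 when the means agree and 0 when they differ.
    """
    a = matrix.condition_values(cond_a)
    b = matrix.condition_values(cond_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(
            f"differential expression needs >=2 replicates per condition "
            f"(got {na} for {cond_a!r}, {nb} for {cond_b!r})"
        )
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    diff = ma - mb

    if method == "student":
        df_t = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df_t
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        p = 2.0 * stats.t.sf(np.abs(t), df_t)
    elif method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = va / na + vb / nb
            t = diff / np.sqrt(se2)
            df_t = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df_t)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b], axis=1)
        n = na + nb
        count = np.zeros(pooled.shape[0], dtype=int)
        absdiff = np.abs(diff)
        for _ in range(n_perm):
            idx = rng.permutation(n)
            pa = pooled[:, idx[:na]].mean(axis=1)
            pb = pooled[:, idx[na:]].mean(axis=1)
            count += np.abs(pa - pb) >= absdiff - 1e-12
        p = (count + 1.0) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown DE method {method!r}")

    # zero-variance conventions (student/welch produce nan there)
    if method in ("student", "welch"):
        degenerate = (va == 0) & (vb == 0)
        p = np.where(degenerate & (diff == 0), 1.0, p)
        p = np.where(degenerate & (diff != 0), 0.0, p)
        p = np.where(np.isnan(p), 1.0, p)

    return pd.DataFrame(
        {"log2_fc": diff, "p_value": np.clip(p, 0.0, 1.0), "mean_a": ma, "mean_b": mb},
        index=matrix.values.index,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

_BAND_EPS = 1e-9  # inclusive-boundary tolerance on the log2 scale


def find_constitutive(matrix: ExpressionMatrix, thresholds: Thresholds | None = None) -> list[str]:
    """Genes expressed at a comparable level on every condition.

    A gene qualifies when all condition means exceed ``expression_floor`` and
    every pairwise linear ratio of condition means lies within the closed
    interval [1/band, band] (band = ``constitutive_band``).
    """
    th = thresholds or Thresholds()
    means = matrix.condition_means().to_numpy()
    band_log2 = math.log2(th.constitutive_band) + _BAND_EPS
    above = (means > th.expression_floor).all(axis=1)
    spread = means.max(axis=1) - means.min(axis=1)
    ok = above & (spread <= band_log2)
    return [g for g, keep in zip(matrix.gene_ids, ok) if keep]


def classify_transcript_groups(
    de_ws_glc: pd.DataFrame,
    de_lac_glc: pd.DataFrame,
    de_ws_lac: pd.DataFrame,
    thresholds: Thresholds | None = None,
    constitutive: Iterable[str] = (),
) -> pd.DataFrame:
    """Partition the gene universe into transcript groups A-E / CONSTITUTIVE / NONE.

    The three inputs are `differential_expression` frames for wheat straw vs
    glucose, lactose vs glucose and wheat straw vs lactose over one common
    gene universe. ``constitutive`` (from :func:`find_constitutive`) wins over
    the A-E logic. Returns a frame indexed by gene_id with the group label,
    the up flags and the supporting fold changes / p-values.
    """
    th = thresholds or Thresholds()
    u1, u2, u3 = (set(d.index) for d in (de_ws_glc, de_lac_glc, de_ws_lac))
    if not (u1 == u2 == u3):
        sym = sorted((u1 ^ u2) | (u1 ^ u3))
        raise ValueError(f"gene universes disagree; symmetric difference: {sym}")

    idx = de_ws_glc.index
    de_lac_glc = de_lac_glc.reindex(idx)
    de_ws_lac = de_ws_lac.reindex(idx)

    lfc_min = math.log2(th.fold_change_min)
    wl_min = math.log2(th.wl_fold_min)

    up_ws = (de_ws_glc["log2_fc"] >= lfc_min) & (de_ws_glc["p_value"] < th.p_max)
    up_lac = (de_lac_glc["log2_fc"] >= lfc_min) & (de_lac_glc["p_value"] < th.p_max)
    ws_gt_lac = (de_ws_lac["log2_fc"] >= wl_min) & (de_ws_lac["p_value"] < th.p_max)
    lac_gt_ws = (-de_ws_lac["log2_fc"] >= wl_min) & (de_ws_lac["p_value"] < th.p_max)

    group = pd.Series("NONE", index=idx, dtype=object)
    group[up_ws & ~up_lac] = "A"
    group[~up_ws & up_lac] = "B"
    both = up_ws & up_lac
    group[both] = "E"
    group[both & ws_gt_lac] = "C"
    group[both & lac_gt_ws] = "D"
    const = [g for g in constitutive if g in idx]
    group.loc[const] = "CONSTITUTIVE"

    return pd.DataFrame(
        {
            "group": group,
            "up_ws": up_ws,
            "up_lac": up_lac,
            "log2_fc_ws_glc": de_ws_glc["log2_fc"],
            "p_ws_glc": de_ws_glc["p_value"],
            "log2_fc_lac_glc": de_lac_glc["log2_fc"],
            "p_lac_glc": de_lac_glc["p_value"],
            "log2_fc_ws_lac": de_ws_lac["log2_fc"],
            "p_ws_lac": de_ws_lac["p_value"],
        },
        index=idx,
    )


def classify(
    matrix: ExpressionMatrix,
    thresholds: Thresholds | None = None,
    glucose: str = "glucose",
    lactose: str = "lactose",
    wheat_straw: str = "wheat_straw",
    method: DEMethod = "student",
) -> pd.DataFrame:
    """End-to-end classification: three DE contrasts + constitutive set."""
    th = thresholds or Thresholds()
    de_ws = differential_expression(matrix, wheat_straw, glucose, method=method)
    de_lac = differential_expression(matrix, lactose, glucose, method=method)
    de_wl = differential_expression(matrix, wheat_straw, lactose, method=method)
    const = find_constitutive(matrix, th)
    return classify_transcript_groups(de_ws, de_lac, de_wl, th, const)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene functional labels (FunCat codes, KOG class, CAZy families, flags).

    Backed by a DataFrame indexed by gene_id with columns: funcat_codes and
    cazy_families (lists), kog_class (single letter or ''), secreted / sscp /
    orphan / unknown (bool), display_name (str).
    """

    table: pd.DataFrame

    _LIST_COLS = ("funcat_codes", "cazy_families")
    _FLAG_COLS = ("secreted", "sscp", "orphan", "unknown")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate gene_id rows in annotation")
        for col in self._LIST_COLS:
            if col not in t.columns:
                t[col] = [[] for _ in range(len(t))]
        for col in self._FLAG_COLS:
            if col not in t.columns:
                t[col] = False
            t[col] = t[col].astype(bool)
        if "kog_class" not in t.columns:
            t["kog_class"] = ""
        if "display_name" not in t.columns:
            t["display_name"] = ""
        t["kog_class"] = t["kog_class"].fillna("")
        t["display_name"] = t["display_name"].fillna("")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def in_category(self, category: str, scheme: str = "funcat") -> pd.Series:
        """Boolean membership of every annotated gene in one category."""
        t = self.table
        if scheme == "funcat":
            return t["funcat_codes"].map(lambda codes: category in codes)
        if scheme == "kog":
            return t["kog_class"] == category
        if scheme == "cazy_family":
            return t["cazy_families"].map(lambda fams: category in fams)
        raise ValueError(f"unknown annotation scheme {scheme!r}")

    def categories(self, scheme: str = "funcat") -> list[str]:
        t = self.table
        if scheme == "funcat":
            vals = {c for codes in t["funcat_codes"] for c in codes}
        elif scheme == "kog":
            vals = {k for k in t["kog_class"] if k}
        elif scheme == "cazy_family":
            vals = {f for fams in t["cazy_families"] for f in fams}
        else:
            raise ValueError(f"unknown annotation scheme {scheme!r}")
        return sorted(vals)

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        for col in self._LIST_COLS:
            out[col] = out[col].map(";".join)
        for col in self._FLAG_COLS:
            out[col] = out[col].astype(int)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        t = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
        t = t.set_index("gene_id")
        for col in cls._LIST_COLS:
            t[col] = t[col].map(lambda s: [c for c in str(s).split(";") if c])
        for col in cls._FLAG_COLS:
            t[col] = t[col].astype(int).astype(bool)
        return cls(t)


# ---------------------------------------------------------------------------
# cross-tabulations and panels
# ---------------------------------------------------------------------------

CROSSTAB_GROUPS = ("A", "B", "C", "D", "E")


def _secreted_class(row: pd.Series) -> str | None:
    if not row["secreted"]:
        return None
    if row["cazy_families"]:
        return "CAZyme"
    if row["sscp"]:
        return "SSCP"
    if row["unknown"]:
        return "unknown"
    return "other"


def crosstab_groups(
    assignments: pd.DataFrame,
    annotation: GeneAnnotation,
    facet: str = "funcat",
) -> pd.DataFrame:
    """Counts of genes per (facet level x transcript group A-E), plus totals.

    ``facet`` is one of funcat, cazy_family, secreted_class. Genes missing
    from the annotation are counted in an "unannotated" row; for the funcat
    facet, "unknown" and "orphans" flag rows and an "All genes" totals row
    are included. Genes with several codes count once per code.
    """
    if facet not in ("funcat", "cazy_family", "secreted_class"):
        raise ValueError(f"unknown facet {facet!r}")
    ann = annotation.table
    rows: dict[str, dict[str, int]] = {}

    def bump(level: str, grp: str) -> None:
        rows.setdefault(level, {g: 0 for g in CROSSTAB_GROUPS})[grp] += 1

    sub = assignments[assignments["group"].isin(CROSSTAB_GROUPS)]
    for gene, grp in sub["group"].items():
        if gene not in ann.index:
            bump("unannotated", grp)
            continue
        arow = ann.loc[gene]
        if facet == "funcat":
            codes = arow["funcat_codes"]
            if codes:
                for code in codes:
                    bump(code, grp)
            else:
                bump("unannotated", grp)
            if arow["unknown"]:
                bump("unknown", grp)
            if arow["orphan"]:
                bump("orphans", grp)
        elif facet == "cazy_family":
            fams = arow["cazy_families"]
            if fams:
                for fam in fams:
                    bump(fam, grp)
            else:
                bump("unannotated", grp)
        else:
            cls = _secreted_class(arow)
            bump(cls if cls is not None else "not_secreted", grp)

    totals = sub["group"].value_counts().reindex(CROSSTAB_GROUPS, fill_value=0)
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    table = table.reindex(columns=list(CROSSTAB_GROUPS), fill_value=0)
    table.loc["All genes"] = totals.to_numpy()
    table = table.sort_index()
    table.index.name = facet
    return table


@dataclass
class PanelReport:
    """Per-gene condition-vs-baseline ratio table plus warnings for absent genes."""

    table: pd.DataFrame
    missing: list[str] = field(default_factory=list)


def panel_report(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    baseline: str = "glucose",
    thresholds: Thresholds | None = None,
    method: DEMethod = "student",
) -> PanelReport:
    """Linear expression ratios of a gene panel against a baseline condition.

    For each panel gene and each non-baseline condition the report carries
    the ratio 2^(mean_cond - mean_baseline), the DE p-value of that contrast
    and a flag for (ratio >= fold_change_min and p < p_max). Panel genes
    missing from the matrix go to ``missing`` with a warning, not an error.
    """
    th = thresholds or Thresholds()
    present = [g for g in panel if g in matrix.values.index]
    missing = [g for g in panel if g not in matrix.values.index]
    if missing:
        warnings.warn(f"panel genes missing from matrix: {missing}", stacklevel=2)
    records = []
    for cond in matrix.conditions:
        if cond == baseline:
            continue
        de = differential_expression(matrix, cond, baseline, method=method)
        for g in present:
            lfc = de.at[g, "log2_fc"]
            p = de.at[g, "p_value"]
            ratio = 2.0**lfc
            records.append(
                {
                    "gene_id": g,
                    "condition": cond,
                    "baseline": baseline,
                    "ratio": ratio,
                    "p_value": p,
                    "significant_up": bool(ratio >= th.fold_change_min and p < th.p_max),
                }
            )
    table = pd.DataFrame.from_records(
        records, columns=["gene_id", "condition", "baseline", "ratio", "p_value", "significant_up"]
    )
    return PanelReport(table=table, missing=missing)


def group_sizes(assignments: pd.DataFrame) -> dict[str, int]:
    """Count of genes per transcript group (all seven labels)."""
    counts = assignments["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in GROUPS}
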
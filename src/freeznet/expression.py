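"""qPCR relative expression (2^-dCt) and group-difference statistics.

c-fos is an immediate early gene whose transcription marks recent neuronal
activity; expression is measured by qPCR in four microdissected brain
nuclei (Dm, Vv, Vs, POA) against 18S rRNA as the reference gene.  Relative
quantity per (fish, nucleus) is ``E**-dCt`` with ``dCt = Ct(c-fos) -
Ct(18s)`` and amplification efficiency ``E`` (2.0 assumes perfect
doubling).  An optional calibrator treatment turns this into ddCt-style
fold changes.  Group comparisons use a per-nucleus one-way ANOVA plus
pairwise t tests over a declared comparison family, corrected with the
Holm step-down ("sequential Bonferroni") procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NUCLEI",
    "TARGET_GENE",
    "REFERENCE_GENE",
    "read_ct_table",
    "relative_expression",
    "holm_correct",
    "group_expression_test",
    "GroupTestResult",
]

NUCLEI = ("Dm", "Vv", "Vs", "POA")
TARGET_GENE = "cfos"
REFERENCE_GENE = "18s"

_GENE_ALIASES = {
    "cfos": TARGET_GENE,
    "c-fos": TARGET_GENE,
    "fos": TARGET_GENE,
    "18s": REFERENCE_GENE,
    "18s rrna": REFERENCE_GENE,
    "18srrna": REFERENCE_GENE,
}


def read_ct_table(path) -> pd.DataFrame:
    """Read and validate a ``fish_id,treatment,nucleus,gene,ct`` CSV.

    Gene names are normalized (``c-fos``/``cfos``, ``18s rRNA``/``18s``).
    Ct values must be finite; unknown genes raise.
    """
    df = pd.read_csv(path)
    required = {"fish_id", "treatment", "nucleus", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    genes = df["gene"].astype(str).str.strip().str.lower()
    unknown = sorted(set(genes) - set(_GENE_ALIASES))
    if unknown:
        raise ValueError(f"{path}: unknown genes {unknown}")
    df["gene"] = genes.map(_GENE_ALIASES)
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if not np.isfinite(df["ct"]).all():
        raise ValueError(f"{path}: non-finite Ct values")
    return df


def relative_expression(
    ct: pd.DataFrame,
    *,
    efficiency: float = 2.0,
    calibrator: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Relative quantity per treatment: fish x nucleus grids of ``E**-dCt``.

    Parameters
    ----------
    ct
        Tidy Ct table as returned by :func:`read_ct_table` (or equivalent).
    efficiency
        Amplification efficiency ``E``; 2.0 is the perfect-doubling
        assumption of the classic 2^-dCt method.
    calibrator
        If given, each nucleus column is divided by the mean relative
        quantity of this treatment for that nucleus (ddCt-style fold
        change).

    A (fish, nucleus) cell missing either gene is NaN — explicitly flagged,
    never imputed.
    """
    if not efficiency > 1.0:
        raise ValueError("efficiency must exceed 1")
    wide = ct.pivot_table(
        index=["treatment", "fish_id", "nucleus"],
        columns="gene",
        values="ct",
        aggfunc="mean",
    )
    for gene in (TARGET_GENE, REFERENCE_GENE):
        if gene not in wide.columns:
            wide[gene] = np.nan
    dct = wide[TARGET_GENE] - wide[REFERENCE_GENE]
    rq = np.power(float(efficiency), -dct)
    grid = rq.reset_index().pivot(
        index=["treatment", "fish_id"], columns="nucleus", values=0
    )
    nuclei = [n for n in NUCLEI if n in grid.columns] + [
        n for n in grid.columns if n not in NUCLEI
    ]
    grid = grid[nuclei]

    out: dict[str, pd.DataFrame] = {}
    for treatment in grid.index.get_level_values("treatment").unique():
        sub = grid.loc[treatment]
        sub.columns.name = None
        out[str(treatment)] = sub
    if calibrator is not None:
        if calibrator not in out:
            raise ValueError(f"calibrator treatment {calibrator!r} not in table")
        baseline = out[calibrator].mean(axis=0, skipna=True)
        out = {k: v / baseline for k, v in out.items()}
    return out


def holm_correct(pvals) -> np.ndarray:
    """Holm step-down ("sequential Bonferroni") adjusted p-values.

    Sort ascending; the i-th smallest raw p becomes
    ``max_{j<=i} min(1, (m - j + 1) * p_(j))``; values are returned in the
    original order.  Controls the family-wise error rate at any level
    without the full Bonferroni penalty on every comparison.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class GroupTestResult:
    """Outcome of :func:`group_expression_test`.

    ``omnibus``: per-nucleus one-way ANOVA F and p across all treatments.
    ``pairwise``: one row per declared (nucleus, treatment pair) with group
    means, the t statistic, raw p and Holm-adjusted p (corrected over the
    whole declared family).
    """

    means: pd.DataFrame
    omnibus: pd.DataFrame
    pairwise: pd.DataFrame


def group_expression_test(
    expr: dict[str, pd.DataFrame],
    comparisons: list[tuple[str, str]] | None = None,
) -> GroupTestResult:
    """Per-nucleus ANOVA plus Holm-corrected pairwise comparisons.

    ``comparisons`` declares the pairs of treatments to test (the Holm
    family is exactly these pairs across all nuclei); ``None`` means all
    treatment pairs.  Every treatment must have at least 3 fish.
    """
    treatments = list(expr)
    if len(treatments) < 2:
        raise ValueError("need at least 2 treatments")
    for name, grid in expr.items():
        if len(grid) < 3:
            raise ValueError(f"treatment {name!r} has fewer than 3 fish")
    if comparisons is None:
        comparisons = [
            (treatments[i], treatments[j])
            for i in range(len(treatments))
            for j in range(i + 1, len(treatments))
        ]
    for a, b in comparisons:
        for name in (a, b):
            if name not in expr:
                raise ValueError(f"comparison names unknown treatment {name!r}")

    nuclei = list(expr[treatments[0]].columns)
    means = pd.DataFrame(
        {t: expr[t].mean(axis=0, skipna=True) for t in treatments}
    ).T.loc[treatments, nuclei]

    omni_rows = []
    for nucleus in nuclei:
        groups = [expr[t][nucleus].dropna().to_numpy() for t in treatments]
        f, p = stats.f_oneway(*groups)
        omni_rows.append({"nucleus": nucleus, "F": float(f), "p": float(p)})
    omnibus = pd.DataFrame(omni_rows)

    pair_rows = []
    for nucleus in nuclei:
        for a, b in comparisons:
            xa = expr[a][nucleus].dropna().to_numpy()
            xb = expr[b][nucleus].dropna().to_numpy()
            t_stat, p = stats.ttest_ind(xa, xb, equal_var=True)
            pair_rows.append(
                {
                    "nucleus": nucleus,
                    "treatment_a": a,
                    "treatment_b": b,
                    "mean_a": float(np.mean(xa)),
                    "mean_b": float(np.mean(xb)),
                    "t": float(t_stat),
                    "p": float(p),
                }
            )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_holm"] = holm_correct(pairwise["p"].to_numpy())
    return GroupTestResult(means=means, omnibus=omnibus, pairwise=pairwise)
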
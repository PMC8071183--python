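"""Cross-ligand statistics and report tables.

Contains the exact-permutation Spearman correlation used to relate
functional potency (pEC50) to kinetic affinity (pK_d) across ligands, a
two-way ANOVA computed from summary statistics (mean, SEM, n per cell),
the Sidak multiple-comparison adjustment, and builders for the two
summary tables (rate-constant table and WT-to-mutant arrow grid).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dose_response import SigmoidFit
from .kinetics import KineticEstimate, classify_shift

#: Largest n for which the full n! permutation distribution is enumerated.
EXACT_N_MAX = 9


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its two-sided p-value."""

    rho: float
    p_two_sided: float
    n: int
    method: str   # "exact_permutation" or "t_approximation"

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho out of range: {self.rho}")
        if not 0.0 < self.p_two_sided <= 1.0:
            raise ValueError(f"p out of range: {self.p_two_sided}")


@dataclass(frozen=True)
class SummaryCell:
    """Per-group summary statistics (mean, SEM, group size)."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


def spearman_exact(x, y) -> CorrelationResult:
    """Spearman correlation with an exact two-sided permutation p-value.

    rho is computed from the rank-difference formula
    ``1 - 6*sum(d^2)/(n*(n^2-1))``.  For tie-free samples of n <= 9 the
    p-value enumerates all n! rank pairings and counts those with
    ``|rho*| >= |rho|`` (integer arithmetic on sum(d^2), so no tolerance
    is involved).  Larger n, or ties, fall back to the t approximation
    (ties additionally emit a warning because the d^2 formula and exact
    enumeration assume distinct ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 pairs")

    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if has_ties:
        warnings.warn("ties present: falling back to the t approximation",
                      stacklevel=2)
    if has_ties or n > EXACT_N_MAX:
        rho, p = sps.spearmanr(x, y)
        return CorrelationResult(rho=float(rho), p_two_sided=float(p),
                                 n=n, method="t_approximation")

    rx = sps.rankdata(x).astype(np.int64)
    ry = sps.rankdata(y).astype(np.int64)
    m = n * (n * n - 1) // 6                     # sum(d^2) scale: rho = 1 - S/m
    s_obs = int(np.sum((rx - ry) ** 2))
    rho = 1.0 - s_obs / m

    perms = np.array(list(permutations(range(1, n + 1))), dtype=np.int64)
    s_all = np.sum((perms - rx[None, :]) ** 2, axis=1)
    count = int(np.sum(np.abs(m - s_all) >= abs(m - s_obs)))
    p = count / len(perms)
    return CorrelationResult(rho=rho, p_two_sided=p, n=n,
                             method="exact_permutation")


def anova_two_way_summary(cells) -> dict:
    """Between-subjects two-way ANOVA from per-cell summary statistics.

    ``cells`` is a complete 2-D grid (nested sequence, shape a x b) of
    :class:`SummaryCell`.  Uses the unweighted-means solution, appropriate
    when cell sizes are unequal or only approximately known: effect sums
    of squares are computed from the unweighted cell means scaled by the
    harmonic mean cell size, and the error mean square pools the cell
    variances with their exact degrees of freedom.

    Returns a dict with F statistics and degrees of freedom for the row
    factor (``F_rows``), column factor (``F_cols``) and interaction
    (``F_interaction``), plus ``mse`` and ``df_error``.
    """
    grid = np.asarray(cells, dtype=object)
    if grid.ndim != 2:
        raise ValueError("cells must form a 2-D grid")
    a, b = grid.shape
    if any(cell is None for cell in grid.ravel()):
        raise ValueError("missing cell in the summary grid")

    means = np.array([[grid[i, j].mean for j in range(b)] for i in range(a)])
    ns = np.array([[grid[i, j].n for j in range(b)] for i in range(a)])
    sds = np.array([[grid[i, j].sd for j in range(b)] for i in range(a)])

    df_error = int(np.sum(ns - 1))
    if df_error <= 0:
        raise ValueError("no within-cell degrees of freedom")
    mse = float(np.sum((ns - 1) * sds ** 2) / df_error)
    n_h = grid.size / np.sum(1.0 / ns)          # harmonic mean cell size

    grand = means.mean()
    row_eff = means.mean(axis=1) - grand
    col_eff = means.mean(axis=0) - grand
    inter = means - grand - row_eff[:, None] - col_eff[None, :]

    ss_rows = n_h * b * float(np.sum(row_eff ** 2))
    ss_cols = n_h * a * float(np.sum(col_eff ** 2))
    ss_inter = n_h * float(np.sum(inter ** 2))
    df_rows, df_cols = a - 1, b - 1
    df_inter = df_rows * df_cols

    def f_of(ss, df):
        return float(ss / df / mse) if df > 0 else float("nan")

    result = {
        "F_rows": f_of(ss_rows, df_rows), "df_rows": df_rows,
        "F_cols": f_of(ss_cols, df_cols), "df_cols": df_cols,
        "F_interaction": f_of(ss_inter, df_inter), "df_interaction": df_inter,
        "df_error": df_error, "mse": mse,
    }
    for key, df in (("rows", df_rows), ("cols", df_cols),
                    ("interaction", df_inter)):
        f = result[f"F_{key}"]
        result[f"p_{key}"] = (float(sps.f.sf(f, df, df_error))
                              if df > 0 else float("nan"))
    return result


def sidak_adjust(p_values) -> np.ndarray:
    """Sidak multiple-comparison adjustment ``1 - (1-p)**m``, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


# ---------------------------------------------------------------------------
# Report tables

#: Column layout of the rate-constant summary table.
TABLE1_COLUMNS = ("ligand", "receptor", "pEC50", "pEC50_sem", "EC50_nM",
                  "k_off", "k_off_sem", "k_on", "k_on_sem", "pKd", "pKd_sem")


def build_summary_table(estimates: list[KineticEstimate],
                        fits: dict[tuple[str, str], SigmoidFit]
                        ) -> pd.DataFrame:
    """Combine kinetic estimates and potency fits into the summary table.

    ``fits`` maps ``(ligand, receptor)`` to the corresponding
    concentration-response fit; every estimate must have a matching fit.
    Returns one row per ligand x receptor with potency, rate constants
    and kinetic affinity (columns of :data:`TABLE1_COLUMNS`).
    """
    rows = []
    for est in estimates:
        key = (est.ligand, est.receptor)
        if key not in fits:
            raise KeyError(f"no concentration-response fit for {key}")
        fit = fits[key]
        rows.append({
            "ligand": est.ligand, "receptor": est.receptor,
            "pEC50": fit.pec50, "pEC50_sem": fit.pec50_sem,
            "EC50_nM": fit.ec50 * 1e9,
            "k_off": est.k_off, "k_off_sem": est.k_off_sem,
            "k_on": est.k_on, "k_on_sem": est.k_on_sem,
            "pKd": est.pkd, "pKd_sem": est.pkd_sem,
        })
    return pd.DataFrame(rows, columns=list(TABLE1_COLUMNS))


def build_shift_table(summary: pd.DataFrame,
                      tops: dict[tuple[str, str], float],
                      wt_label: str = "WT",
                      mut_label: str = "S193A") -> pd.DataFrame:
    """Arrow grid of WT-to-mutant changes per ligand.

    For each ligand present at both receptors, classifies the change in
    potency (EC50), relative efficacy (Top), k_off and k_on into ordinal
    arrow categories.  ``tops`` maps ``(ligand, receptor)`` to the fitted
    relative efficacy.
    """
    rows = []
    by_key = summary.set_index(["ligand", "receptor"])
    ligands = summary["ligand"].drop_duplicates()
    for lig in ligands:
        if (lig, wt_label) not in by_key.index or (lig, mut_label) not in by_key.index:
            continue
        wt = by_key.loc[(lig, wt_label)]
        mut = by_key.loc[(lig, mut_label)]
        rows.append({
            "ligand": lig,
            "potency": classify_shift(wt["EC50_nM"], mut["EC50_nM"], "potency"),
            "efficacy": classify_shift(tops[(lig, wt_label)],
                                       tops[(lig, mut_label)], "efficacy"),
            "k_off": classify_shift(wt["k_off"], mut["k_off"], "rate"),
            "k_on": classify_shift(wt["k_on"], mut["k_on"], "rate"),
        })
    return pd.DataFrame(rows, columns=["ligand", "potency", "efficacy",
                                       "k_off", "k_on"])


_TSV_FORMATS = {
    "pEC50": "{:.2f}", "pEC50_sem": "{:.2f}", "EC50_nM": "{:.6g}",
    "k_off": "{:.3f}", "k_off_sem": "{:.3f}", "k_on": "{:.3e}",
    "k_on_sem": "{:.3e}", "pKd": "{:.2f}", "pKd_sem": "{:.2f}",
}


def summary_table_to_tsv(summary: pd.DataFrame) -> str:
    """Serialize the summary table as TSV at the conventional precision
    (pEC50/pK_d to 2 decimals, k_off to 3, k_on to 3 significant digits)."""
    out = summary.copy()
    for col, fmt in _TSV_FORMATS.items():
        out[col] = [fmt.format(v) for v in out[col]]
    return out.to_csv(sep="\t", index=False)


def read_summary_table_tsv(text: str) -> pd.DataFrame:
    """Parse a TSV produced by :func:`summary_table_to_tsv`."""
    from io import StringIO
    return pd.read_csv(StringIO(text), sep="\t")
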
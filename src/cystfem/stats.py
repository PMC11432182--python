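"""Nonparametric statistics over a scenario x body-weight stress table.

The analysis treats body weights as repeated-measures blocks and scenarios
as treatments: a Friedman rank test across the seven scenarios, Wilcoxon
matched-pairs (signed-rank) tests for every scenario pair, a Pearson
correlation of stress against body weight per scenario, descriptive means
with the *population* standard deviation (divide by n, the convention the
published summary row follows — the sample form does not reproduce it),
and per-kilogram ordinary-least-squares slopes reported rounded to two
decimals.

The Wilcoxon default is exact enumeration of the 2^n sign assignments.
With six blocks the smallest achievable exact two-sided p is 2/64 =
0.03125, so a published "all p < 0.03" can only arise from the normal
approximation; both modes are provided and the report records which one
satisfies that bound.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "round_half_up",
    "describe",
    "friedman",
    "wilcoxon_signed_rank",
    "wilcoxon_pairs",
    "stats_report",
    "StatsReport",
    "FriedmanResult",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the convention of published tables.

    Binary floats sit a hair below exact decimal halves (1.475 is stored as
    1.47499...), so plain ``round``/formatting can disagree with a printed
    value; rounding through a noise-stripped decimal restores the tabular
    convention.
    """
    from decimal import ROUND_HALF_UP, Decimal

    cleaned = Decimal(repr(round(float(x), ndigits + 6)))
    return float(cleaned.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float


@dataclass
class StatsReport:
    descriptives: pd.DataFrame
    friedman: FriedmanResult
    pairwise_p: pd.DataFrame
    wilcoxon_mode: str
    all_pairs_below_003: bool

    def to_dict(self) -> dict:
        return {
            "descriptives": {
                s: {k: (None if pd.isna(v) else round(float(v), 6))
                    for k, v in row.items()}
                for s, row in self.descriptives.to_dict("index").items()
            },
            "friedman": {
                "chi2": round(self.friedman.chi2, 6),
                "df": self.friedman.df,
                "p": float(self.friedman.p),
            },
            "wilcoxon": {
                "mode": self.wilcoxon_mode,
                "p_matrix": {
                    a: {b: float(self.pairwise_p.loc[a, b]) for b in self.pairwise_p.columns}
                    for a in self.pairwise_p.index
                },
                "all_offdiagonal_p_below_0.03": self.all_pairs_below_003,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        """Human-readable summary mirroring the published table layout."""
        d = self.descriptives
        lines = ["scenario  mean±SD (MPa)   slope (MPa/kg)  Pearson r"]
        for s, row in d.iterrows():
            r = "nan" if pd.isna(row["r"]) else f"{row['r']:.4f}"
            lines.append(
                f"{s:>8}  {round_half_up(row['mean']):.2f} ± "
                f"{round_half_up(row['sd']):.2f}     "
                f"{row['slope_rounded']:.2f} ({row['slope']:.4f})   {r}"
            )
        lines.append(
            f"Friedman chi2({self.friedman.df}) = {self.friedman.chi2:.2f}, "
            f"p = {self.friedman.p:.2e}"
        )
        lines.append(
            f"Wilcoxon ({self.wilcoxon_mode}): all off-diagonal p < 0.03: "
            f"{self.all_pairs_below_003}"
        )
        return "\n".join(lines)


def describe(table: pd.DataFrame, population_sd: bool = True) -> pd.DataFrame:
    """Per-scenario mean, SD, OLS slope vs weight, and Pearson r.

    ``population_sd=True`` (default) divides by n; the sample (n-1) form is
    available but does not reproduce the published summary row.  A constant
    column yields slope 0 and an undefined (NaN) correlation with a warning.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least two body weights per scenario")
    w = table.index.to_numpy(dtype=float)
    if np.ptp(w) == 0:
        raise ValueError("degenerate design: all body weights identical")
    ddof = 0 if population_sd else 1
    rows = {}
    for s in table.columns:
        y = table[s].to_numpy(dtype=float)
        mean = float(y.mean())
        sd = float(y.std(ddof=ddof))
        if np.ptp(y) == 0:
            warnings.warn(f"{s}: constant stress column, correlation undefined")
            slope, r = 0.0, float("nan")
        else:
            fit = sps.linregress(w, y)
            slope, r = float(fit.slope), float(fit.rvalue)
        rows[s] = {
            "mean": mean,
            "sd": sd,
            "slope": slope,
            "slope_rounded": round_half_up(slope, 2),
            "r": r,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def friedman(table: pd.DataFrame) -> FriedmanResult:
    """Friedman rank test: scenarios as treatments, weights as blocks.

    chi2 = 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1) with average ranks for
    within-block ties; p from the chi-square distribution with k-1 df.
    """
    k = table.shape[1]
    n = table.shape[0]
    if k < 2 or n < 2:
        raise ValueError("Friedman test needs >= 2 scenarios and >= 2 blocks")
    if table.isna().any().any():
        raise ValueError("incomplete grid")
    ranks = np.apply_along_axis(sps.rankdata, 1, table.to_numpy(dtype=float))
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((R**2).sum()) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return FriedmanResult(chi2=chi2, df=df, p=p)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the rank vector."""
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    mode: Literal["exact", "approx"] = "exact",
    continuity: bool = False,
) -> float:
    """Two-sided Wilcoxon matched-pairs p-value.

    Zero differences are discarded (with a warning); if every difference is
    zero the pair is reported as p = 1.  ``exact`` enumerates all 2^n sign
    assignments of the (possibly tied, average-) ranks; ``approx`` uses the
    normal approximation with tie-corrected variance and, optionally, a
    continuity correction (off by default).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    nz = d != 0
    if not nz.any():
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    if nz.sum() < d.size:
        warnings.warn(f"discarding {d.size - nz.sum()} zero difference(s)")
    d = d[nz]
    n = d.size
    if n < 5:
        warnings.warn(f"only {n} non-zero pairs; the test has little power")
    w_plus, ranks = _signed_rank_statistic(d)
    if mode == "exact":
        if n > 24:
            raise ValueError("exact enumeration limited to n <= 24 pairs")
        # null distribution of W+ over all sign assignments
        sums = np.zeros(1)
        for rk in ranks:
            sums = np.concatenate([sums, sums + rk])
        le = np.count_nonzero(sums <= w_plus + 1e-12) / sums.size
        ge = np.count_nonzero(sums >= w_plus - 1e-12) / sums.size
        return min(1.0, 2.0 * min(le, ge))
    if mode == "approx":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(((counts**3 - counts) / 48.0).sum())
        if var <= 0:
            return 1.0
        z = w_plus - mu
        if continuity:
            z -= 0.5 * np.sign(z)
        z /= np.sqrt(var)
        return float(2.0 * sps.norm.sf(abs(z)))
    raise ValueError(f"unknown mode {mode!r}")


def wilcoxon_pairs(
    table: pd.DataFrame,
    mode: Literal["exact", "approx"] = "exact",
    continuity: bool = False,
) -> pd.DataFrame:
    """Symmetric matrix of two-sided p-values over all scenario pairs.

    Diagonal entries use the convention p = 1 (a scenario against itself).
    """
    cols = list(table.columns)
    if table.shape[0] < 5:
        warnings.warn("fewer than 5 paired observations; p-values are coarse")
    P = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a, b in itertools.combinations(cols, 2):
            p = wilcoxon_signed_rank(
                table[a].to_numpy(), table[b].to_numpy(), mode=mode, continuity=continuity
            )
            P.loc[a, b] = P.loc[b, a] = p
    return P


def stats_report(
    table: pd.DataFrame,
    mode: Literal["exact", "approx"] = "exact",
    population_sd: bool = True,
    correction: Literal[None, "bonferroni", "holm"] = None,
) -> StatsReport:
    """Full statistical elaboration of a stress table.

    No multiple-testing correction is applied by default (none is part of
    the original analysis); ``correction`` switches on Bonferroni or Holm
    via statsmodels for exploratory use.
    """
    desc = describe(table, population_sd=population_sd)
    fr = friedman(table)
    P = wilcoxon_pairs(table, mode=mode)
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        cols = list(P.columns)
        pairs = list(itertools.combinations(cols, 2))
        raw = [P.loc[a, b] for a, b in pairs]
        method = {"bonferroni": "bonferroni", "holm": "holm"}[correction]
        adj = multipletests(raw, method=method)[1]
        for (a, b), p in zip(pairs, adj):
            P.loc[a, b] = P.loc[b, a] = p
    off = P.values[~np.eye(len(P), dtype=bool)]
    return StatsReport(
        descriptives=desc,
        friedman=fr,
        pairwise_p=P,
        wilcoxon_mode=mode,
        all_pairs_below_003=bool((off < 0.03).all()),
    )
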
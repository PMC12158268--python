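"""Two-factor ANOVA with replication, from the sums-of-squares formulas.

The study design crosses PEG concentration (factor A, 3 levels) with BTB
concentration (factor B, 3 levels), with equal replication per cell (20
films each over the pooled pH levels), and asks whether either factor, or
their interaction, shifts the film's response time. The decomposition is
the standard balanced two-way layout:

    SS_A  = b r sum_i (ybar_i.. - ybar...)^2
    SS_B  = a r sum_j (ybar_.j. - ybar...)^2
    SS_AB = r sum_ij (ybar_ij. - ybar_i.. - ybar_.j. + ybar...)^2
    SS_W  = sum_ijk (y_ijk - ybar_ij.)^2

with F = MS_effect / MS_within referred to the F distribution. Display
rounding is 2 decimals; full precision is kept internally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SOURCES = ("peg", "btb", "interaction", "within", "total")


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper critical value of the F distribution: the (1 - alpha) quantile."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def complete_table_from_components(
    ss: dict[str, float], df: dict[str, int], alpha: float = 0.05
) -> pd.DataFrame:
    """Fill in MS, F, p and F-critical from per-source SS and df.

    ``ss`` and ``df`` must carry the keys ``peg``, ``btb``, ``interaction``
    and ``within``; the total row is reconstructed by additivity. Returns a
    DataFrame indexed by source with columns ``sum_sq``, ``df``,
    ``mean_sq``, ``F``, ``p_value``, ``F_critical`` (NaN where a quantity
    is undefined for the row). ``alpha`` is recorded as a DataFrame attr.
    """
    effects = ("peg", "btb", "interaction")
    for key in effects + ("within",):
        if key not in ss or key not in df:
            raise ValueError(f"missing source {key!r} in ss/df")
        if df[key] < 1:
            raise ValueError(f"df[{key!r}] must be positive")
    ms = {k: ss[k] / df[k] for k in effects + ("within",)}
    ms_within = ms["within"]
    rows = {}
    for k in effects:
        if ms_within > 0:
            F = ms[k] / ms_within
            p = float(stats.f.sf(F, df[k], df["within"]))
        else:
            F, p = float("nan"), float("nan")
        rows[k] = (ss[k], df[k], ms[k], F, p, f_critical(alpha, df[k], df["within"]))
    rows["within"] = (ss["within"], df["within"], ms_within, np.nan, np.nan, np.nan)
    rows["total"] = (
        sum(ss[k] for k in effects + ("within",)),
        sum(df[k] for k in effects + ("within",)),
        np.nan,
        np.nan,
        np.nan,
        np.nan,
    )
    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["sum_sq", "df", "mean_sq", "F", "p_value", "F_critical"],
    ).reindex(list(SOURCES))
    table.attrs["alpha"] = alpha
    return table


def two_factor_anova(dataset: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Balanced two-way ANOVA of response time on PEG x BTB with interaction.

    ``dataset`` needs columns ``peg_pct``, ``btb_pct``, ``response_time_s``
    (the standard formulation-dataset schema; extra columns such as ``ph``
    are ignored — replicates are pooled within each formulation cell).
    Raises ``ValueError`` for an unbalanced design or fewer than 2
    replicates per cell. When all responses are identical every SS is 0 and
    the F statistics are reported as NaN.
    """
    for col in ("peg_pct", "btb_pct", "response_time_s"):
        if col not in dataset.columns:
            raise ValueError(f"dataset missing column {col!r}")
    y = dataset["response_time_s"].to_numpy(dtype=float)
    a_lab = dataset["peg_pct"].to_numpy()
    b_lab = dataset["btb_pct"].to_numpy()
    a_levels = np.unique(a_lab)
    b_levels = np.unique(b_lab)
    counts = dataset.groupby(["peg_pct", "btb_pct"]).size()
    if len(counts) != a_levels.size * b_levels.size or counts.nunique() != 1:
        raise ValueError("design must be balanced: equal replicates in every PEG x BTB cell")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per cell")

    grand = y.mean()
    cell_means = dataset.groupby(["peg_pct", "btb_pct"])["response_time_s"].mean()
    a_means = dataset.groupby("peg_pct")["response_time_s"].mean()
    b_means = dataset.groupby("btb_pct")["response_time_s"].mean()

    ss_a = b_levels.size * r * float(((a_means - grand) ** 2).sum())
    ss_b = a_levels.size * r * float(((b_means - grand) ** 2).sum())
    ss_ab = r * float(
        sum(
            (cell_means[(ai, bj)] - a_means[ai] - b_means[bj] + grand) ** 2
            for ai in a_levels
            for bj in b_levels
        )
    )
    cell_mean_per_row = dataset.set_index(["peg_pct", "btb_pct"]).index.map(cell_means)
    ss_within = float(((y - np.asarray(cell_mean_per_row, dtype=float)) ** 2).sum())

    ss = {"peg": ss_a, "btb": ss_b, "interaction": ss_ab, "within": ss_within}
    df = {
        "peg": a_levels.size - 1,
        "btb": b_levels.size - 1,
        "interaction": (a_levels.size - 1) * (b_levels.size - 1),
        "within": a_levels.size * b_levels.size * (r - 1),
    }
    return complete_table_from_components(ss, df, alpha=alpha)


def rounded_report(table: pd.DataFrame) -> pd.DataFrame:
    """The display form of an ANOVA table: 2-decimal rounding."""
    return table.round(2)
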
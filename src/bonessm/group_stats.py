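"""Mode-wise comparison of shape parameters across the three study groups.

Groups: CAI (the unstable ankle of a patient), CAI_CONTRA (the same patients'
uninjured ankle) and HEALTHY (control ankles). Per retained mode the analysis
runs

1. a Lilliefors-corrected Kolmogorov-Smirnov normality screen on the pooled
   b values (mean and SD are estimated from the sample, so the naive KS null
   would be anti-conservative);
2. a one-way fixed-effects ANOVA across the three groups, followed by the
   classic Bonferroni post-hoc: pairwise t statistics using the pooled
   within-group variance (MSE with N-k df), raw p multiplied by the number of
   comparisons (3) and capped at 1;
3. an ANCOVA adjusting for age and gender: the group effect is the
   extra-sum-of-squares F test of ``b ~ group + age + gender`` against
   ``b ~ age + gender``.

A mode is flagged significant for a pair of groups when its Bonferroni
adjusted pairwise p is below alpha. No correction is applied across modes.

The three groups are not mutually independent (both ankles of one patient
enter, and optionally both ankles of bilateral controls); the analysis treats
them as independent groups, logs a warning about the shared subjects, and a
``healthy_policy`` switch can restrict bilateral controls to one ankle.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats as sps

__all__ = [
    "GROUPS",
    "CohortTable",
    "ComparisonResult",
    "build_cohort_table",
    "ks_normality",
    "anova_per_mode",
    "ancova_per_mode",
    "run_comparison",
    "plot_mode_boxplots",
]

GROUPS = ("CAI", "CAI_CONTRA", "HEALTHY")
PAIRS = tuple(itertools.combinations(GROUPS, 2))


@dataclass
class CohortTable:
    """Per-instance metadata joined with per-mode shape parameters.

    ``frame`` columns: subject_id, instance_id, group, side, age, gender plus
    one ``b{k}`` column per retained mode (SD units by convention; the tests
    are scale-invariant so raw b gives identical p-values).
    """

    frame: pd.DataFrame
    mode_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.frame
        required = {"subject_id", "instance_id", "group", "side", "age", "gender"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
        if not self.mode_columns:
            self.mode_columns = [c for c in df.columns if c.startswith("b")
                                 and c[1:].isdigit()]
        if not self.mode_columns:
            raise ValueError("cohort table has no mode columns (b1, b2, ...)")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if df[self.mode_columns].isna().any().any():
            raise ValueError("incomplete b vectors in cohort table")
        dup = df.duplicated(subset=["subject_id", "side"])
        if dup.any():
            raise ValueError("a subject contributes more than one instance per side")

    @property
    def n_modes(self) -> int:
        return len(self.mode_columns)

    def restrict_healthy(self, policy: str, seed: int = 0) -> "CohortTable":
        """'both' keeps all control ankles; 'one-per-subject' keeps a single
        (seeded random) ankle per bilateral healthy subject."""
        if policy == "both":
            return self
        if policy != "one-per-subject":
            raise ValueError("healthy policy must be 'both' or 'one-per-subject'")
        df = self.frame
        rng = np.random.default_rng(seed)
        keep = np.ones(len(df), dtype=bool)
        healthy = df[df["group"] == "HEALTHY"]
        for _, sub in healthy.groupby("subject_id"):
            if len(sub) > 1:
                drop = rng.choice(sub.index, size=len(sub) - 1, replace=False)
                keep[df.index.get_indexer(drop)] = False
        return CohortTable(df[keep].reset_index(drop=True), list(self.mode_columns))


@dataclass
class ComparisonResult:
    """Tidy per-mode results plus significance flags."""

    table: pd.DataFrame           # mode, test, comparison, p_raw, p_adjusted, significant
    flags: dict                   # {(mode, (A, B)): bool} from Bonferroni pairwise
    ancova_changed: bool          # did covariate adjustment change any omnibus flag
    alpha: float

    def __post_init__(self) -> None:
        p = self.table[["p_raw", "p_adjusted"]].to_numpy(dtype=float)
        p = p[np.isfinite(p)]
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")

    def significant_modes(self) -> dict:
        out: dict = {}
        for (mode, pair), flag in self.flags.items():
            if flag:
                out.setdefault(mode, []).append(pair)
        return out


def build_cohort_table(metadata: pd.DataFrame, normalized_b: np.ndarray) -> CohortTable:
    """Join instance metadata with SD-unit shape parameters, row-aligned."""
    b = np.atleast_2d(np.asarray(normalized_b, dtype=float))
    if len(b) != len(metadata):
        raise ValueError("metadata and b matrix must have the same number of rows")
    df = metadata.reset_index(drop=True).copy()
    cols = []
    for k in range(b.shape[1]):
        col = f"b{k + 1}"
        df[col] = b[:, k]
        cols.append(col)
    return CohortTable(df, cols)


# -- tests -----------------------------------------------------------------

def ks_normality(values: np.ndarray, method: str = "table", n_mc: int = 10000,
                 seed: int = 0) -> float:
    """Lilliefors-corrected KS test of normality with estimated mean/SD.

    ``method='table'`` uses the statsmodels Lilliefors approximation;
    ``method='mc'`` simulates the null of the studentised KS statistic
    (``n_mc`` draws, seeded). Zero-variance input returns p=0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 values for the normality screen")
    sd = x.std(ddof=1)
    if sd <= np.finfo(float).eps:
        warnings.warn("degenerate (constant) distribution in normality screen",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    if method == "table":
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(min(max(p, 0.0), 1.0))
    if method == "mc":
        stat = sps.kstest(x, "norm", args=(x.mean(), sd)).statistic
        rng = np.random.default_rng(seed)
        null = np.empty(n_mc)
        n = len(x)
        for i in range(n_mc):
            z = rng.standard_normal(n)
            null[i] = sps.kstest(z, "norm", args=(z.mean(), z.std(ddof=1))).statistic
        return float((np.sum(null >= stat) + 1) / (n_mc + 1))
    raise ValueError("method must be 'table' or 'mc'")


def _one_way_anova(samples: list) -> tuple:
    """Omnibus F and p plus pooled MSE and its df (for the post-hoc)."""
    f, p = sps.f_oneway(*samples)
    n_total = sum(len(s) for s in samples)
    k = len(samples)
    sse = sum(np.sum((np.asarray(s) - np.mean(s)) ** 2) for s in samples)
    df_w = n_total - k
    mse = sse / df_w if df_w > 0 else np.nan
    if not np.isfinite(f):  # identical groups: F = 0/0 -> treat as no effect
        f, p = 0.0, 1.0
    return float(f), float(p), float(mse), df_w


def _pairwise_bonferroni(samples: dict, mse: float, df_w: int,
                         welch: bool = False) -> dict:
    """Pairwise t tests with Bonferroni adjustment (x3, capped at 1)."""
    out = {}
    m = len(PAIRS)
    for a, b in PAIRS:
        xa, xb = np.asarray(samples[a]), np.asarray(samples[b])
        if welch:
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
            p = float(p)
        else:
            se = np.sqrt(mse * (1.0 / len(xa) + 1.0 / len(xb)))
            if se <= 0 or not np.isfinite(se):
                p = 1.0
            else:
                t = (xa.mean() - xb.mean()) / se
                p = float(2.0 * sps.t.sf(abs(t), df_w))
        out[(a, b)] = {"p_raw": p, "p_adjusted": min(1.0, m * p)}
    return out


def anova_per_mode(table: CohortTable, welch: bool = False) -> pd.DataFrame:
    """One-way ANOVA + Bonferroni post-hoc for every mode column.

    Returns a tidy frame with one 'anova' row (omnibus) and three 'bonferroni'
    rows per mode. Modes where any group has fewer than 3 instances are
    flagged unavailable (NaN p-values).
    """
    df = table.frame
    groups_present = [g for g in GROUPS if (df["group"] == g).any()]
    if len(groups_present) < 2:
        raise ValueError("need at least two groups for ANOVA")
    rows = []
    for mode in table.mode_columns:
        samples = {g: df.loc[df["group"] == g, mode].to_numpy()
                   for g in groups_present}
        if any(len(s) < 3 for s in samples.values()):
            rows.append({"mode": mode, "test": "anova", "comparison": "omnibus",
                         "p_raw": np.nan, "p_adjusted": np.nan,
                         "available": False})
            continue
        f, p, mse, df_w = _one_way_anova(list(samples.values()))
        rows.append({"mode": mode, "test": "anova", "comparison": "omnibus",
                     "statistic": f, "p_raw": p, "p_adjusted": p,
                     "available": True})
        if len(groups_present) == 3:
            for pair, res in _pairwise_bonferroni(samples, mse, df_w, welch).items():
                rows.append({"mode": mode, "test": "bonferroni",
                             "comparison": f"{pair[0]} vs {pair[1]}",
                             "p_raw": res["p_raw"],
                             "p_adjusted": res["p_adjusted"],
                             "available": True})
    return pd.DataFrame(rows)


def _design_matrices(df: pd.DataFrame):
    """Covariate-only and group-augmented design matrices, dropping
    degenerate covariates with a warning."""
    n = len(df)
    cols = [np.ones(n)]
    age = df["age"].to_numpy(dtype=float)
    if np.ptp(age) > 0:
        cols.append(age)
    else:
        warnings.warn("age is constant; dropped from ANCOVA", RuntimeWarning,
                      stacklevel=3)
    genders = sorted(df["gender"].unique())
    if len(genders) > 1:
        for g in genders[1:]:
            cols.append((df["gender"] == g).to_numpy(dtype=float))
    else:
        warnings.warn("single gender in cohort; dropped from ANCOVA",
                      RuntimeWarning, stacklevel=3)
    X_red = np.column_stack(cols)
    groups = sorted(df["group"].unique())
    gcols = [(df["group"] == g).to_numpy(dtype=float) for g in groups[1:]]
    X_full = np.column_stack([X_red] + gcols)
    return X_red, X_full, len(gcols)


def ancova_per_mode(table: CohortTable) -> pd.DataFrame:
    """Age- and gender-adjusted group effect per mode.

    Extra-sum-of-squares F test of the group factor on top of the covariates.
    """
    df = table.frame
    if df["age"].isna().any() or df["gender"].isna().any():
        raise ValueError("age and gender must be present for every instance")
    X_red, X_full, df_group = _design_matrices(df)
    n = len(df)
    rows = []
    for mode in table.mode_columns:
        y = df[mode].to_numpy(dtype=float)
        rss_red = _rss(X_red, y)
        rss_full = _rss(X_full, y)
        df_resid = n - X_full.shape[1]
        if df_resid <= 0 or rss_full <= 0:
            p = np.nan
        else:
            f = ((rss_red - rss_full) / df_group) / (rss_full / df_resid)
            p = float(sps.f.sf(max(f, 0.0), df_group, df_resid))
        rows.append({"mode": mode, "test": "ancova", "comparison": "omnibus",
                     "p_raw": p, "p_adjusted": p, "available": np.isfinite(p)})
    return pd.DataFrame(rows)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def run_comparison(
    table: CohortTable,
    alpha: float = 0.05,
    healthy_policy: str = "both",
    welch: bool = False,
    ks_method: str = "table",
    seed: int = 0,
) -> ComparisonResult:
    """Full per-mode comparison: KS screen, ANOVA + Bonferroni, ANCOVA.

    Flags: (mode, pair) is significant when the Bonferroni-adjusted pairwise
    p < alpha. ``ancova_changed`` reports whether adjusting for age and gender
    flips any omnibus significance call.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    warnings.warn(
        "groups share subjects (ipsilateral/contralateral ankles); tests "
        "treat them as independent groups",
        UserWarning, stacklevel=2,
    )
    table = table.restrict_healthy(healthy_policy, seed=seed)
    df = table.frame

    ks_rows = []
    for mode in table.mode_columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = ks_normality(df[mode].to_numpy(), method=ks_method, seed=seed)
        ks_rows.append({"mode": mode, "test": "ks_normality",
                        "comparison": "pooled", "p_raw": p, "p_adjusted": p,
                        "available": True})

    anova = anova_per_mode(table, welch=welch)
    ancova = ancova_per_mode(table)

    out = pd.concat([pd.DataFrame(ks_rows), anova, ancova], ignore_index=True)
    out["significant"] = ((out["p_adjusted"] < alpha)
                          | (alpha >= 1.0)).astype(object)
    out.loc[out["test"] == "ks_normality", "significant"] = np.nan

    flags = {}
    sub = out[out["test"] == "bonferroni"]
    for _, row in sub.iterrows():
        a, b = row["comparison"].split(" vs ")
        flags[(row["mode"], (a, b))] = bool(row["significant"])

    changed = False
    for mode in table.mode_columns:
        p_anova = out.loc[(out["test"] == "anova") & (out["mode"] == mode),
                          "p_adjusted"].to_numpy()
        p_ancova = out.loc[(out["test"] == "ancova") & (out["mode"] == mode),
                           "p_adjusted"].to_numpy()
        if p_anova.size and p_ancova.size and np.isfinite(p_anova[0]) and np.isfinite(p_ancova[0]):
            if (p_anova[0] < alpha) != (p_ancova[0] < alpha):
                changed = True
    return ComparisonResult(table=out, flags=flags, ancova_changed=changed,
                            alpha=alpha)


def plot_mode_boxplots(table: CohortTable, modes: list, path) -> None:
    """Box plots of b values per group for the given modes (one panel each)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, max(len(modes), 1),
                             figsize=(4 * max(len(modes), 1), 4), squeeze=False)
    df = table.frame
    for ax, mode in zip(axes[0], modes):
        data = [df.loc[df["group"] == g, mode] for g in GROUPS]
        ax.boxplot(data, tick_labels=GROUPS)
        ax.set_title(mode)
        ax.set_ylabel("shape parameter (SD units)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
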
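"""Muscle × level repeated-measures statistics.

The design has two within-subject factors — muscle (multifidus vs erector
spinae) and vertebral level (L1–S1) — with each omnibus effect tested
against its own subject×factor interaction mean square (the standard
univariate repeated-measures decomposition, as SPSS reports it; no
sphericity correction by default, Greenhouse–Geisser available behind a
flag).  Post hoc per-level comparisons are paired t-tests across subjects
with a Sidak family correction, p_adj = 1 − (1 − p)^m with m = 6 levels.

A covariate-adjusted sensitivity analysis re-runs the same ANOVA on
metric values residualized against a continuous per-cell covariate
(typically the fat signal fraction): the slope is estimated from
within-cell-centered values, so a constant covariate changes nothing and
the design effects themselves never leak into the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .roi import LEVELS, MUSCLES

__all__ = [
    "MuscleLevelANOVA",
    "AnovaResults",
    "sidak_adjust",
    "sidak_posthoc",
    "UnbalancedDataError",
]

EFFECTS = ("muscle", "level", "muscle * level")


class UnbalancedDataError(ValueError):
    """The table is not complete/balanced after dropping incomplete subjects."""


def sidak_adjust(p_raw: float, m: int = 6) -> float:
    """Sidak-adjusted p-value, 1 − (1 − p)^m.

    Evaluated as -expm1(m·log1p(−p)) so tiny p-values keep full precision
    (the adjustment never drops below the raw p).
    """
    p = min(max(float(p_raw), 0.0), 1.0)
    if p == 1.0:
        return 1.0
    return float(-math.expm1(m * math.log1p(-p)))


def sidak_posthoc(table: pd.DataFrame, metric: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-level paired comparisons (multifidus − erector spinae).

    Exact ties (zero mean difference with zero variance) get p = 1; a
    nonzero constant difference is an exact separation and gets p = 0.
    """
    rows = []
    m = len(LEVELS)
    for level in LEVELS:
        sub = table[table["level"] == level].pivot(
            index="subject", columns="muscle", values=metric
        )
        diff = (sub["multifidus"] - sub["erector_spinae"]).to_numpy(dtype=float)
        mean_diff = float(diff.mean())
        if np.allclose(diff.std(ddof=1), 0.0):
            p_raw = 1.0 if math.isclose(mean_diff, 0.0, abs_tol=1e-300) else 0.0
        else:
            p_raw = float(sps.ttest_rel(sub["multifidus"], sub["erector_spinae"]).pvalue)
        p_adj = sidak_adjust(p_raw, m)
        rows.append(
            dict(
                level=level,
                mean_diff=mean_diff,
                p_raw=p_raw,
                p_sidak=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaResults:
    """Omnibus effects, per-level post hocs, and a text summary."""

    metric: str
    effects: pd.DataFrame  # effect, F, df1, df2, p
    posthoc: pd.DataFrame
    alpha: float
    n_subjects: int
    dropped_subjects: list = field(default_factory=list)
    covariate: str | None = None
    matches_unadjusted: bool | None = None

    def effect(self, name: str) -> pd.Series:
        return self.effects.set_index("effect").loc[name]

    @property
    def significant_effects(self) -> dict[str, bool]:
        return {
            r["effect"]: bool(r["p"] < self.alpha) for _, r in self.effects.iterrows()
        }

    def summary(self) -> str:
        title = f"Repeated-measures ANOVA — metric: {self.metric}"
        if self.covariate:
            title += f" (covariate: {self.covariate})"
        lines = [title, f"subjects: {self.n_subjects}  alpha: {self.alpha}"]
        if self.dropped_subjects:
            lines.append(f"dropped incomplete subjects: {self.dropped_subjects}")
        lines.append("")
        lines.append(f"{'effect':<16}{'F':>10}{'df1':>5}{'df2':>5}{'p':>12}")
        for _, r in self.effects.iterrows():
            p = "nan" if np.isnan(r["p"]) else f"{r['p']:.4g}"
            F = "nan" if np.isnan(r["F"]) else f"{r['F']:.4f}"
            lines.append(
                f"{r['effect']:<16}{F:>10}{int(r['df1']):>5}{int(r['df2']):>5}{p:>12}"
            )
        lines.append("")
        lines.append("post hoc (multifidus − erector spinae), Sidak-adjusted:")
        lines.append(f"{'level':<6}{'mean diff':>14}{'p raw':>12}{'p Sidak':>12}  sig")
        for _, r in self.posthoc.iterrows():
            lines.append(
                f"{r['level']:<6}{r['mean_diff']:>14.5g}{r['p_raw']:>12.4g}"
                f"{r['p_sidak']:>12.4g}  {'*' if r['significant'] else ''}"
            )
        if self.matches_unadjusted is not None:
            lines.append("")
            lines.append(
                "significance pattern matches the unadjusted analysis: "
                + ("yes" if self.matches_unadjusted else "NO")
            )
        return "\n".join(lines)


class MuscleLevelANOVA:
    """Two-way repeated-measures model for a tidy muscle×level table.

    Parameters
    ----------
    table : DataFrame
        Tidy records with columns subject, muscle, level and metric columns.
    metric : str
        The column to analyse.
    alpha : float
        Significance threshold (default 0.05).
    sphericity_correction : bool
        Report Greenhouse–Geisser-corrected p-values instead of the
        uncorrected ones.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        metric: str,
        alpha: float = 0.05,
        sphericity_correction: bool = False,
    ):
        if metric not in table.columns:
            raise KeyError(f"metric column {metric!r} not in table")
        self.metric = metric
        self.alpha = float(alpha)
        self.sphericity_correction = bool(sphericity_correction)

        df = table[["subject", "muscle", "level", metric]].copy()
        if "missing" in table.columns:
            df.loc[table["missing"].to_numpy(dtype=bool), metric] = np.nan
        n_cells = len(MUSCLES) * len(LEVELS)
        counts = df.dropna(subset=[metric]).groupby("subject").size()
        complete = counts[counts == n_cells].index
        self.dropped_subjects = sorted(set(df["subject"]) - set(complete))
        df = df[df["subject"].isin(complete)]
        dup = df.duplicated(subset=["subject", "muscle", "level"])
        if dup.any() or (len(df) != len(complete) * n_cells):
            bad = sorted(df[dup]["subject"].unique()) if dup.any() else sorted(complete)
            raise UnbalancedDataError(
                f"table is not balanced after dropping incomplete subjects: {bad}"
            )
        if len(complete) < 3:
            raise UnbalancedDataError("need at least 3 complete subjects")
        self.table = df.reset_index(drop=True)
        self.n_subjects = len(complete)

    # -- fitting -----------------------------------------------------------
    def _omnibus(self, df: pd.DataFrame) -> pd.DataFrame:
        if np.allclose(df[self.metric].std(ddof=0), 0.0):
            # no variance anywhere: all effects undefined; report F=nan, p=1
            rows = [
                dict(effect=e, F=np.nan, df1=d1, df2=d1 * (self.n_subjects - 1), p=1.0)
                for e, d1 in zip(EFFECTS, (1, 5, 5))
            ]
            return pd.DataFrame(rows)
        aov = pg.rm_anova(
            data=df,
            dv=self.metric,
            within=["muscle", "level"],
            subject="subject",
            detailed=True,
        )
        pcol = "p_GG_corr" if self.sphericity_correction else "p_unc"
        rows = []
        for e in EFFECTS:
            r = aov[aov["Source"].str.lower() == e.lower()].iloc[0]
            p = r[pcol] if pcol in aov.columns and not pd.isna(r[pcol]) else r["p_unc"]
            rows.append(
                dict(
                    effect=e,
                    F=float(r["F"]) if np.isfinite(r["F"]) else np.nan,
                    df1=int(r["ddof1"]),
                    df2=int(r["ddof2"]),
                    p=float(p) if np.isfinite(p) else 1.0,
                )
            )
        return pd.DataFrame(rows)

    def fit(self) -> AnovaResults:
        """Omnibus F tests plus Sidak post hocs."""
        effects = self._omnibus(self.table)
        posthoc = sidak_posthoc(self.table, self.metric, self.alpha)
        return AnovaResults(
            metric=self.metric,
            effects=effects,
            posthoc=posthoc,
            alpha=self.alpha,
            n_subjects=self.n_subjects,
            dropped_subjects=self.dropped_subjects,
        )

    def fit_ancova(
        self, source_table: pd.DataFrame, covariate: str = "fat_fraction"
    ) -> AnovaResults:
        """Covariate-adjusted sensitivity analysis.

        The covariate is taken per subject×muscle×level cell from
        `source_table`, centered within each cell; a pooled slope is fitted
        to the likewise-centered metric, the metric is residualized, and the
        same repeated-measures ANOVA/post hocs are run on the adjusted
        values.  The result records whether every significance flag matches
        the unadjusted fit.
        """
        base = self.fit()
        cov = source_table[["subject", "muscle", "level", covariate]]
        df = self.table.merge(cov, on=["subject", "muscle", "level"], how="left")
        if df[covariate].isna().any():
            raise UnbalancedDataError("covariate missing for some cells")
        grp = df.groupby(["muscle", "level"], observed=True)
        xc = df[covariate] - grp[covariate].transform("mean")
        yc = df[self.metric] - grp[self.metric].transform("mean")
        sxx = float((xc**2).sum())
        slope = float((xc * yc).sum() / sxx) if sxx > 1e-30 else 0.0
        adj = df.copy()
        adj[self.metric] = df[self.metric] - slope * (
            df[covariate] - df[covariate].mean()
        )
        effects = self._omnibus(adj[["subject", "muscle", "level", self.metric]])
        posthoc = sidak_posthoc(adj, self.metric, self.alpha)
        matches = bool(
            (effects["p"] < self.alpha).equals(base.effects["p"] < self.alpha)
            and posthoc["significant"].equals(base.posthoc["significant"])
        )
        return AnovaResults(
            metric=self.metric,
            effects=effects,
            posthoc=posthoc,
            alpha=self.alpha,
            n_subjects=self.n_subjects,
            dropped_subjects=self.dropped_subjects,
            covariate=covariate,
            matches_unadjusted=matches,
        )
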
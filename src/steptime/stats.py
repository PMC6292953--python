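"""Mixed-design statistics: 2x2 mixed ANOVA, partial eta-squared, Scheffe, Pearson.

The study design is a 2 (group: SMT vs control, between subjects) x 2 (test:
pre vs post, within subjects) mixed ANOVA run separately per outcome, with
partial eta-squared effect sizes and Scheffe post hoc contrasts on the four
cell means.  With two within levels the analysis reduces exactly to three
orthogonal F tests, each with (1, N - 2) degrees of freedom for N analysis
units:

* group: one-way ANOVA on the unit means over the two test occasions,
* test: the (unweighted) grand mean of the post-minus-pre differences,
* group x test: the between-group contrast of those differences.

The *analysis unit* may be a participant (one value per participant x test,
trials averaged first) or a trial (pre/post pairs of the same participant and
trial index treated as units, reproducing the study's trial-level error
degrees of freedom).  Sphericity is trivially satisfied with two within
levels, so the Greenhouse-Geisser correction is an identity pass-through.

Usage follows the model/results convention::

    res = MixedAnova(df, dv="correct_taps").fit()
    print(res.summary())
    res.scheffe()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "MixedAnova",
    "MixedAnovaResults",
    "partial_eta_squared",
    "scheffe_posthoc",
    "pearson",
]


def partial_eta_squared(F: float, df_effect: float, df_error: float) -> float:
    """Partial eta-squared from an F statistic and its degrees of freedom.

    ``eta_p^2 = F * df_effect / (F * df_effect + df_error)``, the share of
    effect-plus-error variance attributable to the effect.
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if df_effect <= 0 or df_error <= 0:
        raise ValueError("degrees of freedom must be positive")
    return (F * df_effect) / (F * df_effect + df_error)


@dataclass(frozen=True)
class AnovaEffect:
    effect: str  # "group" | "test" | "group x test"
    F: float
    df_effect: float
    df_error: float
    p: float
    eta_p2: float


class MixedAnova:
    """2 (between) x 2 (within) mixed ANOVA model.

    Parameters
    ----------
    data
        Long-format table with one row per unit x within-level.
    dv, between, within, subject
        Column names of the dependent variable and the design factors.
        ``subject`` identifies the analysis unit; every unit must appear in
        exactly one between group and contribute exactly one value per
        within level (aggregate or drop incomplete units first, e.g. with
        :meth:`aggregate_trials`).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        between: str = "group",
        within: str = "test",
        subject: str = "participant_id",
    ) -> None:
        for col in (dv, between, within, subject):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data[[subject, between, within, dv]].copy()
        self.dv, self.between, self.within, self.subject = dv, between, within, subject

        groups = sorted(data[between].unique())
        levels = list(pd.unique(data[within]))
        if len(groups) != 2 or len(levels) != 2:
            raise ValueError("the design must have exactly 2 groups and 2 within levels")
        # keep a pre/post-like presentation order if recognizable
        if set(levels) == {"pre", "post"}:
            levels = ["pre", "post"]
        self.groups, self.levels = groups, levels

        counts = data.groupby([subject, within]).size()
        if (counts > 1).any():
            raise ValueError(
                "multiple values per unit and within level; aggregate trials first "
                "(see MixedAnova.aggregate_trials)"
            )
        wide = data.pivot(index=[subject, between], columns=within, values=dv)
        if wide.isna().any().any():
            bad = wide[wide.isna().any(axis=1)].index.get_level_values(0).tolist()
            raise ValueError(f"unbalanced data: unit(s) missing a within level: {bad}")
        for lev, grp in wide.groupby(level=1):
            if len(grp) < 2:
                raise ValueError(f"fewer than 2 units in group cell {lev!r}")
        self._wide = wide

    @staticmethod
    def aggregate_trials(
        data: pd.DataFrame,
        dv: str,
        between: str = "group",
        within: str = "test",
        participant: str = "participant_id",
        trial: str = "trial_index",
        unit: str = "participant",
    ) -> pd.DataFrame:
        """Prepare trial-level records for a chosen analysis unit.

        ``unit="participant"`` averages trials within participant x test;
        ``unit="trial"`` pairs each participant's trial index across tests
        (dropping incomplete pairs) and treats the pair as the unit.
        """
        df = data.dropna(subset=[dv]).copy()
        if unit == "participant":
            out = (
                df.groupby([participant, between, within], as_index=False)[dv].mean()
            )
            return out.rename(columns={participant: "unit_id"})
        if unit == "trial":
            df["unit_id"] = (
                df[participant].astype(str) + "_t" + df[trial].astype(int).astype(str)
            )
            complete = df.groupby("unit_id")[within].nunique() == 2
            keep = complete[complete].index
            return df[df["unit_id"].isin(keep)][["unit_id", between, within, dv]]
        raise ValueError("unit must be 'participant' or 'trial'")

    def fit(self) -> "MixedAnovaResults":
        g0, g1 = self.groups
        w = self._wide
        pre, post = self.levels
        y = {g: w.xs(g, level=1)[[pre, post]].to_numpy() for g in (g0, g1)}
        n = {g: len(y[g]) for g in (g0, g1)}
        N = n[g0] + n[g1]
        df_err = N - 2

        means = {g: y[g].mean(axis=0) for g in (g0, g1)}  # per test level
        subj_mean = {g: y[g].mean(axis=1) for g in (g0, g1)}
        d = {g: y[g][:, 1] - y[g][:, 0] for g in (g0, g1)}

        # group effect: one-way ANOVA on subject means (x2 for the two
        # repeated measures, which cancels in F)
        mall = np.concatenate([subj_mean[g0], subj_mean[g1]])
        ss_between = sum(
            n[g] * (subj_mean[g].mean() - mall.mean()) ** 2 for g in (g0, g1)
        )
        ss_within_subj = sum(((subj_mean[g] - subj_mean[g].mean()) ** 2).sum() for g in (g0, g1))
        F_group = _safe_f(ss_between, ss_within_subj / df_err)

        # within effects from the post-minus-pre differences
        var_d = sum(((d[g] - d[g].mean()) ** 2).sum() for g in (g0, g1)) / df_err
        h = 0.5 * (d[g0].mean() + d[g1].mean())  # unweighted grand mean
        se_h2 = var_d * 0.25 * (1.0 / n[g0] + 1.0 / n[g1])
        F_test = _safe_f(h**2, se_h2)
        diff = d[g0].mean() - d[g1].mean()
        F_int = _safe_f(diff**2, var_d * (1.0 / n[g0] + 1.0 / n[g1]))

        effects = []
        for name, F in (("group", F_group), ("test", F_test), ("group x test", F_int)):
            p = float(sps.f.sf(F, 1, df_err))
            effects.append(
                AnovaEffect(name, float(F), 1.0, float(df_err), p, partial_eta_squared(F, 1, df_err))
            )

        cells = pd.DataFrame(
            {lev: {g: means[g][k] for g in (g0, g1)} for k, lev in enumerate(self.levels)}
        )
        cell_n = pd.DataFrame(
            {lev: {g: n[g] for g in (g0, g1)} for lev in self.levels}
        )
        # pooled error variance across the between- and within-subject strata,
        # used by the Scheffe contrasts on the four cell means
        ss_ts = sum(((d[g] - d[g].mean()) ** 2).sum() for g in (g0, g1)) / 2.0
        ms_pooled = (2.0 * ss_within_subj + ss_ts) / (2 * df_err)
        return MixedAnovaResults(
            model=self,
            effects=tuple(effects),
            cell_means=cells,
            cell_n=cell_n,
            ms_error_pooled=float(ms_pooled),
            df_error_pooled=2 * df_err,
            n_units=N,
        )


def _safe_f(ss_effect: float, ms_error: float) -> float:
    if ms_error <= 0:
        return 0.0
    return ss_effect / ms_error


@dataclass
class MixedAnovaResults:
    """Fitted mixed ANOVA: effects, effect sizes, cell means, post hoc tests."""

    model: MixedAnova
    effects: tuple[AnovaEffect, ...]
    cell_means: pd.DataFrame
    cell_n: pd.DataFrame
    ms_error_pooled: float
    df_error_pooled: float
    n_units: int
    greenhouse_geisser_epsilon: float = 1.0  # identity with 2 within levels

    def __post_init__(self) -> None:
        for e in self.effects:
            ref = partial_eta_squared(e.F, e.df_effect, e.df_error)
            assert abs(e.eta_p2 - ref) < 1e-12

    @property
    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.effect,
                    "F": e.F,
                    "df_effect": e.df_effect,
                    "df_error": e.df_error,
                    "p": e.p,
                    "eta_p2": e.eta_p2,
                }
                for e in self.effects
            ]
        )

    def __getitem__(self, effect: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def scheffe(self, alpha: float = 0.05) -> pd.DataFrame:
        """Scheffe post hoc contrasts over all pairs of the four cell means."""
        return scheffe_posthoc(
            self.cell_means,
            self.cell_n,
            self.ms_error_pooled,
            self.df_error_pooled,
            alpha=alpha,
        )

    def plot_cell_means(self, ax=None):
        """Pre/post cell means per group (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g in self.cell_means.index:
            ax.plot(self.cell_means.columns, self.cell_means.loc[g], marker="o", label=g)
        ax.set_xlabel(self.model.within)
        ax.set_ylabel(self.model.dv)
        ax.legend(title=self.model.between)
        return ax

    def summary(self) -> str:
        lines = [
            f"Mixed ANOVA ({self.model.between} x {self.model.within}), "
            f"dv={self.model.dv!r}, N={self.n_units} units",
            "",
            "Cell means:",
            self.cell_means.round(3).to_string(),
            "",
            f"{'effect':<14}{'F':>10}{'df':>10}{'p':>10}{'eta_p2':>9}",
        ]
        for e in self.effects:
            dfs = f"(1,{int(e.df_error)})"
            lines.append(
                f"{e.effect:<14}{e.F:>10.2f}{dfs:>10}{e.p:>10.4f}{e.eta_p2:>9.3f}"
            )
        return "\n".join(lines)


def scheffe_posthoc(
    cell_means: pd.DataFrame,
    cell_n: pd.DataFrame,
    ms_error: float,
    df_error: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scheffe simultaneous pairwise contrasts of a table of cell means.

    For k cells, the pair (i, j) is significant when
    ``(m_i - m_j)^2 / (MS_e (1/n_i + 1/n_j))`` exceeds ``(k-1) F_alpha(k-1,
    df_e)``; the Scheffe p-value is the survival function of that statistic
    divided by ``k - 1``.  The criterion protects all possible contrasts, so
    it is conservative relative to unadjusted pairwise tests.
    """
    cells = [(g, lev) for g in cell_means.index for lev in cell_means.columns]
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    if ms_error <= 0:
        raise ValueError("non-positive error variance")
    k = len(cells)
    crit = (k - 1) * sps.f.isf(alpha, k - 1, df_error)
    rows = []
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            (ga, la), (gb, lb) = cells[a], cells[b]
            ma, mb = cell_means.loc[ga, la], cell_means.loc[gb, lb]
            na, nb = cell_n.loc[ga, la], cell_n.loc[gb, lb]
            stat = (ma - mb) ** 2 / (ms_error * (1.0 / na + 1.0 / nb))
            rows.append(
                {
                    "cell_a": f"{ga}:{la}",
                    "cell_b": f"{gb}:{lb}",
                    "mean_diff": float(ma - mb),
                    "statistic": float(stat),
                    "critical": float(crit),
                    "p": float(sps.f.sf(stat / (k - 1), k - 1, df_error)),
                    "significant": bool(stat > crit),
                }
            )
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
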
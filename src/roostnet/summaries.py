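"""Tracking-effort summaries and observation-bias checks.

Covers the descriptive telemetry statistics of a colony-year (roost
switching interval, roosts per bat, relocations per bat, bats and uses
per roost), the Poisson GLM check that roosts-used is not merely an
artifact of tracking effort (with deviance explained D^2 and its adjusted
variant), and the correlation between tagged-bat roost use and maximum
emergence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SummaryStats",
    "GLMResult",
    "roost_switching_stats",
    "per_bat_effort",
    "poisson_glm_roosts_vs_relocs",
    "emergence_correlation",
]


@dataclass
class SummaryStats:
    """Colony-year telemetry summary (mean +/- SD per stated unit)."""

    mean_switch_interval_days: float
    sd_switch_interval_days: float
    #: same statistic aggregated over runs instead of over bats
    mean_switch_interval_days_runs: float
    sd_switch_interval_days_runs: float
    mean_roosts_per_bat: float
    sd_roosts_per_bat: float
    mean_relocs_per_bat: float
    sd_relocs_per_bat: float
    mean_bats_per_roost: float
    sd_bats_per_roost: float
    mean_uses_per_roost: float
    sd_uses_per_roost: float
    n_bats: int
    n_roosts: int
    n_relocations: int
    n_gap_broken_runs: int

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class GLMResult:
    """Poisson regression of roosts used on relocation count."""

    beta: float
    ci_95: tuple[float, float]
    intercept: float
    D2: float
    adj_D2: float
    n: int
    meta: dict = field(default_factory=dict)


def _runs(relocs: pd.DataFrame) -> tuple[list[int], int]:
    """Same-roost run lengths (days) for one bat, split at tracking gaps.

    A run is a maximal sequence of consecutive calendar days at one roost;
    a gap of more than one day between relocations breaks the run even if
    the roost is unchanged.  Returns (run lengths, number of gap breaks).
    """
    r = relocs.sort_values("date", kind="stable")
    dates = pd.to_datetime(r["date"]).to_numpy()
    roosts = r["roost_id"].to_numpy()
    lengths: list[int] = []
    gap_breaks = 0
    cur = 1
    for i in range(1, len(r)):
        gap = (dates[i] - dates[i - 1]) / np.timedelta64(1, "D")
        if gap == 1 and roosts[i] == roosts[i - 1]:
            cur += 1
        else:
            if gap > 1 and roosts[i] == roosts[i - 1]:
                gap_breaks += 1
            lengths.append(cur)
            cur = 1
    lengths.append(cur)
    return lengths, gap_breaks


def roost_switching_stats(relocations: pd.DataFrame) -> SummaryStats:
    """Roost-switching and roost-use summary of a relocation table.

    The switch interval is the mean length (days) of same-roost runs of
    consecutive tracked days; runs broken by tracking gaps are split and
    the number of such breaks reported.  Aggregations both over bats
    (mean of per-bat means) and over runs are emitted.
    """
    if relocations is None or len(relocations) == 0:
        raise ValueError("empty relocation table")
    per_bat_means = []
    all_runs: list[int] = []
    gap_broken = 0
    relocs_per_bat = []
    roosts_per_bat = []
    for _, grp in relocations.groupby("bat_id", sort=True):
        lengths, breaks = _runs(grp)
        gap_broken += breaks
        per_bat_means.append(float(np.mean(lengths)))
        all_runs.extend(lengths)
        relocs_per_bat.append(len(grp))
        roosts_per_bat.append(grp["roost_id"].nunique())
    by_roost = relocations.groupby("roost_id", sort=True)
    bats_per_roost = by_roost["bat_id"].nunique().to_numpy(dtype=float)
    uses_per_roost = by_roost.size().to_numpy(dtype=float)

    def _ms(x):
        x = np.asarray(x, dtype=float)
        return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0

    m_bat, s_bat = _ms(per_bat_means)
    m_run, s_run = _ms(all_runs)
    m_rpb, s_rpb = _ms(roosts_per_bat)
    m_lpb, s_lpb = _ms(relocs_per_bat)
    m_bpr, s_bpr = _ms(bats_per_roost)
    m_upr, s_upr = _ms(uses_per_roost)
    return SummaryStats(
        mean_switch_interval_days=m_bat,
        sd_switch_interval_days=s_bat,
        mean_switch_interval_days_runs=m_run,
        sd_switch_interval_days_runs=s_run,
        mean_roosts_per_bat=m_rpb,
        sd_roosts_per_bat=s_rpb,
        mean_relocs_per_bat=m_lpb,
        sd_relocs_per_bat=s_lpb,
        mean_bats_per_roost=m_bpr,
        sd_bats_per_roost=s_bpr,
        mean_uses_per_roost=m_upr,
        sd_uses_per_roost=s_upr,
        n_bats=relocations["bat_id"].nunique(),
        n_roosts=relocations["roost_id"].nunique(),
        n_relocations=len(relocations),
        n_gap_broken_runs=gap_broken,
    )


def per_bat_effort(relocations: pd.DataFrame) -> pd.DataFrame:
    """Per-bat table of relocation count and distinct roosts used."""
    g = relocations.groupby("bat_id", sort=True)
    return pd.DataFrame(
        {
            "bat_id": list(g.groups),
            "n_relocs": g.size().to_numpy(),
            "n_roosts": g["roost_id"].nunique().to_numpy(),
        }
    )


def poisson_glm_roosts_vs_relocs(per_bat: pd.DataFrame) -> GLMResult:
    """Log-link Poisson GLM of roosts used on relocation count.

    Deviance explained D^2 = (null - residual deviance)/null deviance;
    adjusted D^2 = 1 - [(n-1)/(n-p)] (1 - D^2).  The slope CI is Wald.
    """
    if len(per_bat) < 3:
        raise ValueError("need >= 3 bats")
    y = per_bat["n_roosts"].to_numpy(dtype=float)
    x = sm.add_constant(per_bat["n_relocs"].to_numpy(dtype=float))
    model = sm.GLM(y, x, family=sm.families.Poisson())
    fit = model.fit()
    if not fit.converged:
        raise RuntimeError(f"Poisson GLM did not converge: {fit.mle_retvals}")
    if fit.null_deviance < 1e-10:
        d2 = 0.0  # constant response: the null model already saturates
    else:
        d2 = float((fit.null_deviance - fit.deviance) / fit.null_deviance)
    n, p = len(y), 2
    adj = float(1.0 - ((n - 1) / (n - p)) * (1.0 - d2))
    lo, hi = fit.conf_int()[1]
    return GLMResult(
        beta=float(fit.params[1]),
        ci_95=(float(lo), float(hi)),
        intercept=float(fit.params[0]),
        D2=d2,
        adj_D2=adj,
        n=n,
        meta={
            "null_deviance": float(fit.null_deviance),
            "deviance": float(fit.deviance),
        },
    )


def emergence_correlation(
    roost_days: np.ndarray, max_counts: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between days-used and maximum
    emergence count per roost."""
    x = np.asarray(roost_days, dtype=float)
    y = np.asarray(max_counts, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired roost values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
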
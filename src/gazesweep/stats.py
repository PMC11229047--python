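"""Group x time mixed ANCOVA with covariate retention and Holm post-hocs.

Each metric is analysed with a 3 (training group, between participants)
x 2 (time: pre/post, within participants) split-plot model, optionally
with a between-participant covariate (participant pool).  The split-plot
decomposition is fit as two orthogonal strata:

* between stratum — participant means (pre + post)/2 regressed on group
  (and the covariate): tests the group main effect and the covariate;
* within stratum — participant change scores (post - pre) regressed on
  group (and the covariate): the intercept tests the time main effect
  and the group term tests the group-by-time interaction.

With a 2-level within factor this is exactly the classical mixed ANOVA
(no sphericity correction is needed).  The covariate enters both strata,
so its retention costs one denominator degree of freedom in every test,
matching the conventional ANCOVA table for this design.  Retention
follows a pure rule: the covariate stays in the model iff its
between-stratum p-value is below alpha (default .05).

Effect sizes are partial eta squared, SS_effect / (SS_effect +
SS_error-of-stratum).  Post-hoc comparisons (pairwise between groups at
each phase, paired pre/post within each group) are Holm-corrected within
each family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("gazesweep")

__all__ = [
    "EffectResult",
    "AnovaResult",
    "mixed_anova_2x3",
    "holm_adjust",
    "posthoc_battery",
    "analyze_study",
    "report",
]


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq: float

    def __str__(self):
        return (f"F({self.df_num},{self.df_den}) = {self.F:.2f}, "
                f"p = {self.p:.3f}, eta_sq = {self.eta_sq:.2f}")


@dataclass
class AnovaResult:
    dv: str
    n: int
    effects: dict
    covariate: Optional[str] = None
    covariate_retained: bool = False
    covariate_test: Optional[EffectResult] = None
    posthoc: list = field(default_factory=list)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _effects_coding(groups: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero coding: k-1 columns, last level coded -1."""
    cols = []
    for lv in levels[:-1]:
        c = np.where(groups == lv, 1.0, 0.0)
        c[groups == levels[-1]] = -1.0
        cols.append(c)
    return np.column_stack(cols)


def _stratum_tests(y, G, z):
    """F-tests of each term in y ~ 1 + G (+ z) by model comparison.

    Returns dict term -> EffectResult for terms 'intercept', 'group' and
    (if z is not None) 'covariate'.
    """
    n = len(y)
    ones = np.ones((n, 1))
    blocks = {"intercept": ones, "group": G}
    if z is not None:
        blocks["covariate"] = z.reshape(-1, 1)
    X_full = np.column_stack(list(blocks.values()))
    p_full = X_full.shape[1]
    df_den = n - p_full
    if df_den <= 0:
        raise ValueError("insufficient data: no residual degrees of freedom")
    rss_full = _rss(X_full, y)
    if rss_full <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("degenerate data: zero error variance")
    mse = rss_full / df_den
    out = {}
    for term, block in blocks.items():
        others = [b for t, b in blocks.items() if t != term]
        rss_red = _rss(np.column_stack(others), y) if others else float(y @ y)
        df_num = block.shape[1]
        ss = max(0.0, rss_red - rss_full)
        F = (ss / df_num) / mse
        p = float(sps.f.sf(F, df_num, df_den))
        out[term] = EffectResult(F=float(F), df_num=df_num, df_den=df_den, p=p,
                                 eta_sq=float(ss / (ss + rss_full)) if ss + rss_full > 0 else 0.0)
    return out


def _complete_cases(data: pd.DataFrame, dv: str, covariate: Optional[str],
                    phases=("pre", "post")):
    cols = ["participant", "group", "phase", dv] + ([covariate] if covariate else [])
    d = data[cols].dropna()
    wide = d.pivot_table(index=["participant", "group"]
                         + ([covariate] if covariate else []),
                         columns="phase", values=dv, aggfunc="first")
    missing = [p for p in phases if p not in wide.columns]
    if missing:
        raise ValueError(f"insufficient data: no observations of {dv!r} "
                         f"in phase(s) {', '.join(missing)}")
    wide = wide.dropna(subset=list(phases)).reset_index()
    return wide


def mixed_anova_2x3(
    data: pd.DataFrame,
    dv: str,
    covariate: Optional[str] = None,
    alpha_cov: float = 0.05,
    phases=("pre", "post"),
) -> AnovaResult:
    """Mixed (split-plot) 3 x 2 ANCOVA on a tidy participant-phase table.

    ``data`` needs columns participant, group, phase, the dv, and the
    covariate if supplied.  Participants missing either phase are
    dropped (listwise deletion).  A supplied covariate is dropped and
    the model refit without it when its p >= alpha_cov.

    Returns an AnovaResult with effects 'time', 'group', 'group x time'
    and, when retained, 'covariate'.
    """
    wide = _complete_cases(data, dv, covariate, phases)
    levels = sorted(data["group"].dropna().unique().tolist())
    counts = wide["group"].value_counts()
    if any(counts.get(lv, 0) < 2 for lv in levels):
        raise ValueError("insufficient data: need >= 2 complete participants per group")

    groups = wide["group"].to_numpy()
    pre = wide[phases[0]].to_numpy(dtype=float)
    post = wide[phases[1]].to_numpy(dtype=float)
    mean_s = (pre + post) / 2.0
    diff_s = post - pre
    G = _effects_coding(groups, levels)

    z = None
    if covariate is not None:
        zc = wide[covariate]
        if not pd.api.types.is_numeric_dtype(zc):
            lvls = sorted(zc.unique().tolist())
            if len(lvls) > 2:
                raise ValueError("a categorical covariate must have at most 2 levels")
            zc = zc.map({lv: float(k) for k, lv in enumerate(lvls)})
        z = zc.to_numpy(dtype=float)
        z = z - z.mean()
        if np.all(z == 0):  # constant covariate carries no information
            z = None

    def fit(zv):
        between = _stratum_tests(mean_s, G, zv)
        within = _stratum_tests(diff_s, G, zv)
        return between, within

    covariate_test = None
    retained = False
    if z is not None:
        between, within = fit(z)
        covariate_test = between["covariate"]
        retained = covariate_test.p < alpha_cov
        if not retained:
            between, within = fit(None)
    else:
        between, within = fit(None)

    effects = {
        "group": between["group"],
        "time": within["intercept"],
        "group x time": within["group"],
    }
    if retained:
        effects["covariate"] = covariate_test
    return AnovaResult(dv=dv, n=len(wide), effects=effects,
                       covariate=covariate, covariate_retained=retained,
                       covariate_test=covariate_test)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (order preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def posthoc_battery(
    data: pd.DataFrame,
    dv: str,
    interaction_significant: bool = True,
    phases=("pre", "post"),
) -> list:
    """Pairwise group comparisons at each phase plus within-group change.

    Emitted only when the interaction reached (or neared) significance;
    otherwise returns an empty list.  Between-group comparisons use
    independent-samples t-tests, pre/post change uses paired t-tests;
    Holm correction is applied within each of the three families.
    """
    if not interaction_significant:
        return []
    wide = _complete_cases(data, dv, None, phases)
    levels = sorted(wide["group"].unique().tolist())
    comparisons = []

    for phase in phases:
        fam = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = wide.loc[wide["group"] == levels[i], phase].to_numpy()
                b = wide.loc[wide["group"] == levels[j], phase].to_numpy()
                t, p = sps.ttest_ind(a, b)
                fam.append({"family": f"between_{phase}",
                            "label": f"{levels[i]} v {levels[j]} ({phase})",
                            "t": float(t), "df": len(a) + len(b) - 2,
                            "p_raw": float(p)})
        adj = holm_adjust([c["p_raw"] for c in fam])
        for c, pa in zip(fam, adj):
            c["p_holm"] = float(pa)
        comparisons.extend(fam)

    fam = []
    for lv in levels:
        sub = wide[wide["group"] == lv]
        t, p = sps.ttest_rel(sub[phases[1]].to_numpy(), sub[phases[0]].to_numpy())
        fam.append({"family": "pre_post_change", "label": f"{lv} pre-post change",
                    "t": float(t), "df": len(sub) - 1, "p_raw": float(p)})
    adj = holm_adjust([c["p_raw"] for c in fam])
    for c, pa in zip(fam, adj):
        c["p_holm"] = float(pa)
    comparisons.extend(fam)
    return comparisons


def analyze_study(
    data: pd.DataFrame,
    metrics: Optional[list] = None,
    covariate: Optional[str] = "pool",
    alpha: float = 0.05,
    posthoc_band: float = 0.06,
) -> dict:
    """Run the full statistical battery over a study dataset.

    ``data`` is tidy long by phase and wide by metric.  Post-hoc tests
    are emitted when the interaction p falls at or below
    ``posthoc_band`` (slightly above alpha, so near-threshold
    interactions are still explored).
    """
    reserved = {"participant", "group", "pool", "phase"}
    if metrics is None:
        metrics = [c for c in data.columns if c not in reserved]
    results = {}
    for m in sorted(metrics):
        try:
            res = mixed_anova_2x3(data, m, covariate=covariate, alpha_cov=alpha)
        except ValueError as err:
            if "insufficient data" in str(err):
                log.warning("skipping %s: %s", m, err)
                continue
            raise
        inter_p = res.effects["group x time"].p
        res.posthoc = posthoc_battery(data, m, interaction_significant=inter_p <= posthoc_band)
        results[m] = res
    if not results:
        raise ValueError("no metric had sufficient data for analysis")
    return results


def report(results: dict) -> tuple:
    """Render analysis results as (text, machine-readable dict).

    Metrics are ordered alphabetically; regenerating from the same
    inputs is byte-identical.
    """
    if not results:
        raise ValueError("need at least one result to report")
    payload = {}
    lines = []
    for m in sorted(results):
        res = results[m]
        lines.append(f"== {m} (n = {res.n}) ==")
        if res.covariate is not None:
            ct = res.covariate_test
            decision = "retained" if res.covariate_retained else "removed"
            lines.append(f"covariate {res.covariate}: {ct} -> {decision}")
        for name in ("time", "group", "group x time", "covariate"):
            if name in res.effects:
                lines.append(f"{name}: {res.effects[name]}")
        if res.posthoc:
            lines.append("post-hoc (Holm-adjusted):")
            for c in res.posthoc:
                lines.append(f"  {c['label']}: t = {c['t']:.2f}, "
                             f"p = {c['p_raw']:.3f}, p_holm = {c['p_holm']:.3f}")
        else:
            lines.append("post-hoc: interaction not significant, none run")
        lines.append("")
        payload[m] = {
            "n": res.n,
            "covariate_retained": res.covariate_retained,
            "effects": {
                name: {"F": e.F, "df_num": e.df_num, "df_den": e.df_den,
                       "p": e.p, "eta_sq": e.eta_sq}
                for name, e in res.effects.items()
            },
            "posthoc": res.posthoc,
        }
    return "\n".join(lines), payload


def report_json(results: dict) -> str:
    return json.dumps(report(results)[1], indent=2, sort_keys=True)
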
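"""Expression–editing screening and survival association.

Implements the two-group log-rank statistic (needed per-cutpoint for the
maximally selected rank statistic), the maxstat cutpoint search over an
admissible quantile range, a Newton-fitted binary-covariate Cox model
with Breslow tie handling, Kaplan–Meier curves (via lifelines), the
gene-expression Pearson screen and the logFC * -log10(p) ranking.

A note on the maxstat procedure: selecting the cutpoint that maximises
the standardized log-rank statistic and then quoting the log-rank p at
that cutpoint is anti-conservative (the selection inflates type-I
error). The cutpoint and the uncorrected p are both reported, and it is
the caller's responsibility to interpret the p accordingly.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from editscan.config import PipelineConfig
from editscan.model import CohortRecord, CutpointResult

log = logging.getLogger(__name__)


# ------------------------------------------------------------- log-rank

def logrank_z(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> float:
    """Standardized two-group log-rank statistic Z = (O1-E1)/sqrt(V).

    Positive Z means group 1 experienced more events than expected under
    the null of identical hazards. Returns 0.0 when the variance is zero
    (no admissible comparison).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int((event == 1)[time == t].sum())
        d1 = int(((event == 1) & g1)[time == t].sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return o_minus_e / np.sqrt(var)


def logrank(
    time_a: Sequence[float],
    event_a: Sequence[int],
    time_b: Sequence[float],
    event_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p with 1 df)."""
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([np.asarray(time_a, float), np.asarray(time_b, float)])
    event = np.concatenate([np.asarray(event_a, int), np.asarray(event_b, int)])
    if event.sum() == 0:
        raise ValueError("no events in either group")
    g1 = np.concatenate([np.zeros(len(time_a), bool), np.ones(len(time_b), bool)])
    z = logrank_z(time, event, g1)
    chi2 = z * z
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# -------------------------------------------------------------- maxstat

def maxstat_cutpoint(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    cfg: Optional[PipelineConfig] = None,
) -> CutpointResult:
    """Maximally selected rank statistic over admissible cutpoints.

    Every distinct covariate value v whose split proportion lies within
    the configured quantile bounds defines a candidate split (<= v versus
    > v); the v maximising |Z| is returned, ties broken toward smaller v.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    q_lo, q_hi = cfg.maxstat_quantile_bounds
    n = len(x)
    order = np.sort(np.unique(x))
    candidates = [
        v for v in order[:-1] if q_lo <= (x <= v).mean() <= q_hi
    ]
    if not candidates:
        raise ValueError("no admissible cutpoint within the quantile bounds")
    best_v, best_abs, best_z = None, -1.0, 0.0
    for v in candidates:
        z = logrank_z(t, e, x <= v)
        if abs(z) > best_abs + 1e-12:
            best_v, best_abs, best_z = v, abs(z), z
    high = x > best_v
    hr, ci, wald_p = cox_hr_binary(high.astype(int), t, e)
    chi2 = best_z * best_z
    return CutpointResult(
        cutoff=float(best_v),
        max_std_logrank=float(best_abs),
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        hr=hr,
        hr_ci_low=ci[0],
        hr_ci_high=ci[1],
        logrank_p=float(stats.chi2.sf(chi2, df=1)),
    )


# ------------------------------------------------------------------ Cox

def cox_hr_binary(
    group: Sequence[int],
    time: Sequence[float],
    event: Sequence[int],
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[Optional[float], tuple[Optional[float], Optional[float]], Optional[float]]:
    """Cox proportional-hazards fit for one binary covariate.

    Newton maximisation of the Breslow partial likelihood; returns
    (HR, (ci95_low, ci95_high), wald_p). With all events in one group the
    likelihood is monotone in beta and the HR is reported non-estimable
    as (None, (None, None), None).
    """
    g = np.asarray(group, dtype=int)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("both groups must be non-empty")
    d1_total = int(e[g == 1].sum())
    d0_total = int(e[g == 0].sum())
    if e.sum() == 0:
        raise ValueError("no events")
    if d1_total == 0 or d0_total == 0:
        log.warning("cox_hr_binary: all events in one group, monotone likelihood")
        return None, (None, None), None

    event_times = np.unique(t[e == 1])
    # per event time: events in each group and risk-set sizes
    rows = []
    for et in event_times:
        at_risk = t >= et
        rows.append(
            (
                int(((t == et) & (e == 1) & (g == 1)).sum()),
                int(((t == et) & (e == 1)).sum()),
                int((at_risk & (g == 0)).sum()),
                int((at_risk & (g == 1)).sum()),
            )
        )
    d1s = np.array([r[0] for r in rows], float)
    ds = np.array([r[1] for r in rows], float)
    n0s = np.array([r[2] for r in rows], float)
    n1s = np.array([r[3] for r in rows], float)

    beta = 0.0
    for _ in range(max_iter):
        eb = np.exp(beta)
        denom = n0s + n1s * eb
        score = float(np.sum(d1s - ds * n1s * eb / denom))
        info = float(np.sum(ds * n0s * n1s * eb / denom**2))
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < tol:
            break
    if abs(beta) > 15:
        log.warning("cox_hr_binary: beta diverged (%.2f), HR non-estimable", beta)
        return None, (None, None), None
    eb = np.exp(beta)
    info = float(np.sum(ds * n0s * n1s * eb / (n0s + n1s * eb) ** 2))
    se = 1.0 / np.sqrt(info)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    wald_p = float(2 * stats.norm.sf(abs(beta) / se))
    return hr, ci, wald_p


# ------------------------------------------------------------------- KM

def km_curve(
    time: Sequence[float], event: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier product-limit estimate; returns (times, S(t)) at the
    distinct observed times, starting at (0, 1)."""
    from lifelines import KaplanMeierFitter

    if len(time) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


# ------------------------------------------------------- screen & ranking

def pearson_by_gene(editing: np.ndarray, expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pearson r (and two-sided t p) of expression vs editing.

    Genes with zero variance get r = NaN. Vectorized over the full matrix.
    """
    x = np.asarray(editing, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    M = expr.to_numpy(dtype=float)
    xc = x - x.mean()
    Mc = M - M.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sg = np.sqrt((Mc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Mc.T @ xc) / (sg * sx)
    r[sg == 0] = np.nan
    if sx == 0:
        r[:] = np.nan
    rr = np.clip(r, -0.999999999999, 0.999999999999)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    return pd.DataFrame({"gene": expr.columns, "r": r, "p": p}).set_index("gene")


def pearson_screen(
    cohorts: Sequence[tuple[Sequence[float], pd.DataFrame]],
) -> pd.DataFrame:
    """Rank genes by unweighted mean Pearson r across cohorts.

    ``cohorts`` is a list of (editing values, samples x genes expression
    frame) pairs with genes matched by column name. Ties in mean r are
    broken by the smaller Fisher-combined p. Genes with r missing in all
    cohorts are excluded from the ranking head (placed last).
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    per = [pearson_by_gene(np.asarray(ed, float), expr) for ed, expr in cohorts]
    genes = per[0].index
    for tab in per[1:]:
        genes = genes.intersection(tab.index)
    rs = pd.concat([tab.loc[genes, "r"] for tab in per], axis=1)
    ps = pd.concat([tab.loc[genes, "p"] for tab in per], axis=1)
    rs.columns = [f"r_cohort{i + 1}" for i in range(len(per))]
    mean_r = rs.mean(axis=1, skipna=True)
    # Fisher's combined p over cohorts where r is defined
    chi = (-2 * np.log(ps.where(rs.notna().to_numpy()))).sum(axis=1, skipna=True)
    k = rs.notna().sum(axis=1)
    combined_p = pd.Series(
        np.where(k > 0, stats.chi2.sf(chi, df=2 * k.clip(lower=1)), np.nan),
        index=genes,
    )
    out = rs.copy()
    out["mean_r"] = mean_r
    out["combined_p"] = combined_p
    out = out.sort_values(
        by=["mean_r", "combined_p"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def de_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Rank differential-expression results by logFC * -log10(p).

    Expects columns ``logfc`` and ``p``; p = 0 is clamped to the smallest
    positive float and flagged in a ``p_clamped`` column.
    """
    df = table.copy()
    if not {"logfc", "p"}.issubset(df.columns):
        raise ValueError("table must have 'logfc' and 'p' columns")
    if ((df["p"] < 0) | (df["p"] > 1)).any() or not np.isfinite(df["logfc"]).all():
        raise ValueError("p must lie in [0,1] and logfc must be finite")
    clamped = df["p"] == 0
    if clamped.any():
        log.warning("de_rank: %d zero p-values clamped", int(clamped.sum()))
    df["p_clamped"] = clamped
    tiny = np.nextafter(0, 1)
    df["score"] = df["logfc"] * -np.log10(df["p"].where(~clamped, tiny))
    return df.sort_values("score", ascending=False, kind="mergesort")


# ------------------------------------------------------ cohort endpoints

def endpoint_arrays(
    records: Sequence[CohortRecord], endpoint: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (editing_pct, time, event) for one endpoint, dropping
    samples with missing follow-up. Endpoints: 'os' or 'tt'."""
    ed, tt, ev = [], [], []
    for r in records:
        t = r.time_os if endpoint == "os" else r.time_tt
        e = r.event_os if endpoint == "os" else r.event_tt
        if t is None or e is None:
            continue
        ed.append(r.editing_pct)
        tt.append(t)
        ev.append(e)
    return np.asarray(ed), np.asarray(tt), np.asarray(ev)
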
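"""Model assessment: calibration by strata and risk quantiles, chi-square
goodness of fit, horizon-restricted ROC/AUC and DeLong's test for
correlated AUCs.

The discrimination endpoint is status at a fixed horizon (default 10
years): an *event* is a breast-cancer death at or before the horizon, a
*non-event* is a patient known to be alive (with respect to breast
cancer) at the horizon — which includes deaths from other causes before
the horizon, since the endpoint is cause-specific.  Patients censored
alive before the horizon have unknown status; the default policy
excludes them from ROC analyses and reports how many were dropped.
"""

from __future__ import annotations

import json
import warnings
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort
from .engine import ModelConfig, RiskPrediction, predict_cohort

__all__ = [
    "observed_outcomes",
    "CalibrationStratum",
    "calibration_table",
    "strata_by_variable",
    "strata_by_quantile",
    "GofResult",
    "quantile_gof",
    "AucResult",
    "roc_auc",
    "DeLongComparison",
    "delong_test",
    "validation_report",
]

EVENT, NON_EVENT, CENSORED, COMPETING = "event", "non_event", "censored", "competing"


# --------------------------------------------------------------------------
# outcome classification at a horizon
# --------------------------------------------------------------------------

def observed_outcomes(cohort: Cohort, horizon: float = 10.0) -> list[str]:
    """Classify each patient at the horizon.

    ``event``: breast-cancer death at or before the horizon.
    ``non_event``: followed beyond the horizon (alive, censored later, or
    dying of any cause after the horizon), or dying of another cause
    after the horizon.
    ``competing``: other-cause death before the horizon (a non-event for
    breast-cancer-specific mortality, flagged distinctly).
    ``censored``: censored alive before the horizon; status unknown.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = []
    for r in cohort.records:
        t, o = r.follow_up_years, r.outcome
        if t < 0:
            raise ValueError(f"record {r.id}: negative follow-up")
        if o == "bc_death":
            out.append(EVENT if t <= horizon else NON_EVENT)
        elif o == "other_death":
            out.append(COMPETING if t < horizon else NON_EVENT)
        else:  # censored
            out.append(NON_EVENT if t >= horizon else CENSORED)
    return out


def _binary_labels(statuses: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(labels, keep-mask) for ROC under the exclude-censored policy."""
    statuses = np.asarray(statuses)
    keep = statuses != CENSORED
    labels = (statuses == EVENT).astype(int)
    return labels, keep


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

@dataclass
class CalibrationStratum:
    """Observed vs expected breast-cancer deaths in one stratum."""

    label: str
    n: int
    observed_deaths: int
    expected_v2: float
    expected_v3: float
    ci_low: float
    ci_high: float


def poisson_ci(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count."""
    low = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2
    high = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    return float(low), float(high)


def _expected(preds: list[RiskPrediction], ids: set[str], horizon: int) -> float:
    return float(sum(p.cuminc_bc[horizon] for p in preds if p.id in ids))


def calibration_table(
    cohort: Cohort,
    preds_v2: list[RiskPrediction],
    preds_v3: list[RiskPrediction],
    strata: "OrderedDict[str, list[str]]",
    horizon: int = 10,
) -> list[CalibrationStratum]:
    """Observed vs expected deaths within each stratum of a partition.

    ``strata`` maps labels to patient-id lists and must partition the
    cohort exactly.  Expected deaths are sums of predicted cumulative
    breast-cancer mortality at the horizon; the 95% CI on the observed
    count is the exact Poisson interval.
    """
    all_ids = [r.id for r in cohort.records]
    strat_ids = [i for ids in strata.values() for i in ids]
    if sorted(strat_ids) != sorted(all_ids):
        raise ValueError("strata do not partition the cohort")
    statuses = dict(zip(all_ids, observed_outcomes(cohort, horizon)))

    out = []
    for label, ids in strata.items():
        idset = set(ids)
        obs = sum(1 for i in ids if statuses[i] == EVENT)
        lo, hi = poisson_ci(obs)
        out.append(
            CalibrationStratum(
                label=label,
                n=len(ids),
                observed_deaths=obs,
                expected_v2=_expected(preds_v2, idset, horizon),
                expected_v3=_expected(preds_v3, idset, horizon),
                ci_low=lo,
                ci_high=hi,
            )
        )
    return out


_AGE_BANDS = [("<40", 0, 40), ("40-49", 40, 50), ("50-59", 50, 60), ("60+", 60, 200)]
_SIZE_BANDS = [("<10", 0, 10), ("10-19", 10, 20), ("20-29", 20, 30),
               ("30-49", 30, 50), ("50+", 50, 1e9)]
_NODE_BANDS = [("negative", 0, 1), ("1", 1, 2), ("2-4", 2, 5),
               ("5-9", 5, 10), ("10+", 10, 1e9)]


def strata_by_variable(cohort: Cohort, variable: str) -> "OrderedDict[str, list[str]]":
    """Clinical-characteristic strata (age, size, nodes, grade, HER2).

    Fractional (imputed) grades, markers or nodal codes fall in a
    ``missing`` stratum, mirroring how imputed patients are tabulated
    separately from observed categories.
    """
    strata: OrderedDict[str, list[str]] = OrderedDict()

    def put(label, rid):
        strata.setdefault(label, []).append(rid)

    if variable == "age":
        for label, *_ in _AGE_BANDS:
            strata[label] = []
        for r in cohort.records:
            for label, lo, hi in _AGE_BANDS:
                if lo <= r.age_dx < hi:
                    put(label, r.id)
                    break
    elif variable == "size":
        for label, *_ in _SIZE_BANDS:
            strata[label] = []
        strata["missing"] = []
        for r in cohort.records:
            if r.size_mm is None:
                put("missing", r.id)
                continue
            for label, lo, hi in _SIZE_BANDS:
                if lo <= r.size_mm < hi:
                    put(label, r.id)
                    break
    elif variable == "nodes":
        for label, *_ in _NODE_BANDS:
            strata[label] = []
        strata["missing"] = []
        for r in cohort.records:
            if r.nodes_pos is None:
                put("missing", r.id)
                continue
            for label, lo, hi in _NODE_BANDS:
                if lo <= r.nodes_pos < hi:
                    put(label, r.id)
                    break
    elif variable == "grade":
        for label in ("1", "2", "3", "missing"):
            strata[label] = []
        for r in cohort.records:
            if r.grade in (0.0, 1.0, 2.0):
                put(str(int(r.grade) + 1), r.id)
            else:
                put("missing", r.id)
    elif variable == "her2":
        for label in ("negative", "positive", "missing"):
            strata[label] = []
        for r in cohort.records:
            if r.her2 == 0.0:
                put("negative", r.id)
            elif r.her2 == 1.0:
                put("positive", r.id)
            else:
                put("missing", r.id)
    else:
        raise ValueError(f"unknown stratification variable {variable!r}")
    return OrderedDict((k, v) for k, v in strata.items() if v)


def strata_by_quantile(
    preds: list[RiskPrediction], k: int, horizon: int = 10
) -> "OrderedDict[str, list[str]]":
    """Quantile bins of predicted cumulative mortality at the horizon.

    Ties are broken by a stable sort on (predicted value, id) so the
    binning is reproducible.
    """
    if k < 2:
        raise ValueError("need at least 2 quantile bins")
    if len(preds) < k:
        raise ValueError(f"cannot form {k} bins from {len(preds)} predictions")
    order = sorted(preds, key=lambda p: (p.cuminc_bc[horizon], p.id))
    splits = np.array_split(np.arange(len(order)), k)
    out: OrderedDict[str, list[str]] = OrderedDict()
    for b, idx in enumerate(splits, start=1):
        out[f"q{b}"] = [order[i].id for i in idx]
    return out


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

@dataclass
class GofResult:
    chi2: float
    df: int
    p: float


def quantile_gof(
    cohort: Cohort,
    preds: list[RiskPrediction],
    k: int = 5,
    df: int | None = None,
    horizon: int = 10,
) -> GofResult:
    """Chi-square goodness of fit over quantiles of predicted mortality.

    ``chi2 = sum (O - E)^2 / E`` over the k bins; the upper-tail p-value
    uses ``df`` degrees of freedom (default k, matching a 5-d.f. test on
    quintiles).  A bin with expected 0 but observed > 0 is an error.
    """
    bins = strata_by_quantile(preds, k, horizon)
    statuses = dict(
        zip((r.id for r in cohort.records), observed_outcomes(cohort, horizon))
    )
    chi2 = 0.0
    for label, ids in bins.items():
        idset = set(ids)
        e = _expected(preds, idset, horizon)
        o = sum(1 for i in ids if statuses[i] == EVENT)
        if e == 0:
            if o > 0:
                raise ValueError(
                    f"bin {label}: expected 0 deaths but observed {o}"
                )
            continue
        chi2 += (o - e) ** 2 / e
    dof = k if df is None else df
    return GofResult(chi2=float(chi2), df=dof, p=float(stats.chi2.sf(chi2, dof)))


# --------------------------------------------------------------------------
# ROC / AUC and DeLong
# --------------------------------------------------------------------------

@dataclass
class AucResult:
    """AUC with DeLong variance and the empirical ROC curve."""

    auc: float
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (m, 2) array of (FPR, TPR) points
    variance: float


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (structural components) for both classes.

    ``v10[i]`` is the fraction of negatives scored below positive i (ties
    count one half); ``v01[j]`` the fraction of positives scored above
    negative j.  Their means both equal the Mann-Whitney AUC.
    """
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)  # midranks handle ties
    rpos, rneg = ranks[:m], ranks[m:]
    rpos_within = stats.rankdata(pos)
    rneg_within = stats.rankdata(neg)
    v10 = (rpos - rpos_within) / n
    v01 = 1.0 - (rneg - rneg_within) / m
    return v10, v01


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC polygon from (0,0) to (1,1), one vertex per threshold."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / max(tp[-1], 1)]
    fpr = np.r_[0.0, fp / max(fp[-1], 1)]
    return np.column_stack([fpr, tpr])


def roc_auc(scores, labels) -> AucResult:
    """Mann-Whitney AUC (ties count one half) with DeLong variance.

    ``labels`` are 1 for events and 0 for non-events; censored patients
    must already be excluded by the caller's policy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one event and one non-event")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)) \
        if len(pos) > 1 and len(neg) > 1 else 0.0
    return AucResult(
        auc=auc,
        n_pos=len(pos),
        n_neg=len(neg),
        curve=_roc_points(scores, labels),
        variance=var,
    )


@dataclass
class DeLongComparison:
    """Paired-AUC comparison by DeLong's placement-value method."""

    auc_a: float
    auc_b: float
    delta: float
    var_delta: float
    z: float
    p: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong z-test for the difference of two correlated AUCs.

    Both score vectors must be aligned to the same patients and labels.
    The variance of ``delta = auc_b - auc_a`` uses the 2x2 covariance of
    the placement values within each class, which accounts for the
    pairing.  A zero variance (e.g. identical scores) yields p = 1 with
    the ``degenerate`` flag set.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("score vectors and labels must align")
    posmask = labels == 1
    if posmask.all() or (~posmask).all():
        raise ValueError("need at least one event and one non-event")
    v10a, v01a = _placements(a[posmask], a[~posmask])
    v10b, v01b = _placements(b[posmask], b[~posmask])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    delta = auc_b - auc_a
    m, n = int(posmask.sum()), int((~posmask).sum())
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        var = float(
            (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        )
        var = max(var, 0.0)
    else:
        var = 0.0
    if var <= 0.0:
        degenerate = True
        z = 0.0
        p = 1.0
        if delta != 0.0:
            warnings.warn("DeLong variance is zero but AUCs differ", stacklevel=2)
    else:
        degenerate = False
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(
        auc_a=auc_a, auc_b=auc_b, delta=float(delta), var_delta=var,
        z=float(z), p=p, degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# full validation report
# --------------------------------------------------------------------------

def _stratum_dicts(table: list[CalibrationStratum]) -> list[dict]:
    return [
        {
            "label": s.label,
            "n": s.n,
            "observed": s.observed_deaths,
            "expected_v2": round(s.expected_v2, 6),
            "expected_v3": round(s.expected_v3, 6),
            "ci_low": round(s.ci_low, 6),
            "ci_high": round(s.ci_high, 6),
        }
        for s in table
    ]


def _subset_report(
    cohort: Cohort,
    preds_v2: list[RiskPrediction],
    preds_v3: list[RiskPrediction],
    horizon: int,
    k: int,
) -> dict:
    statuses = observed_outcomes(cohort, horizon)
    labels, keep = _binary_labels(statuses)
    ids = [r.id for r in cohort.records]

    whole = OrderedDict([("all", list(ids))])
    calib: dict = {
        "overall": _stratum_dicts(
            calibration_table(cohort, preds_v2, preds_v3, whole, horizon)
        ),
        "by_variable": {},
        "by_quantile": {},
    }
    for var in ("age", "size", "nodes", "grade", "her2"):
        strata = strata_by_variable(cohort, var)
        calib["by_variable"][var] = _stratum_dicts(
            calibration_table(cohort, preds_v2, preds_v3, strata, horizon)
        )
    gof: dict = {}
    for version, preds in (("v2", preds_v2), ("v3", preds_v3)):
        if len(preds) >= k:
            qs = strata_by_quantile(preds, k, horizon)
            calib["by_quantile"][version] = _stratum_dicts(
                calibration_table(cohort, preds_v2, preds_v3, qs, horizon)
            )
            g = quantile_gof(cohort, preds, k=k, horizon=horizon)
            gof[version] = {"chi2": round(g.chi2, 6), "df": g.df, "p": round(g.p, 6)}

    disc: dict
    n_pos = int(labels[keep].sum())
    n_neg = int((1 - labels[keep]).sum())
    if n_pos >= 1 and n_neg >= 1:
        scores_v2 = np.array([p.cuminc_bc[horizon] for p in preds_v2])[keep]
        scores_v3 = np.array([p.cuminc_bc[horizon] for p in preds_v3])[keep]
        auc2 = roc_auc(scores_v2, labels[keep])
        auc3 = roc_auc(scores_v3, labels[keep])
        cmp_ = delong_test(scores_v2, scores_v3, labels[keep])
        disc = {
            "available": True,
            "n_events": n_pos,
            "n_non_events": n_neg,
            "n_censored_excluded": int((~keep).sum()),
            "auc_v2": round(auc2.auc, 6),
            "auc_v3": round(auc3.auc, 6),
            "delong": {
                "delta": round(cmp_.delta, 6),
                "z": round(cmp_.z, 6),
                "p": round(cmp_.p, 8),
                "degenerate": cmp_.degenerate,
            },
        }
    else:
        disc = {"available": False, "n_events": n_pos, "n_non_events": n_neg}
    return {
        "n": len(cohort),
        "observed_deaths": int(labels[keep].sum()),
        "calibration": calib,
        "gof": gof,
        "discrimination": disc,
    }


def validation_report(
    cohort: Cohort,
    config: ModelConfig,
    horizon: int | None = None,
    k: int = 5,
    censor_policy: str = "exclude",
    outdir=None,
    make_plots: bool = False,
) -> dict:
    """Full calibration + discrimination report for v2 and v3.

    Runs predictions for both model versions, then reports calibration
    (overall, by clinical strata, by quantile of predicted risk),
    goodness of fit, AUCs and the DeLong comparison — for all patients
    and for the ER+ subset.  The cohort must already be filtered and
    imputed.  Deterministic: no randomness enters anywhere.
    """
    if censor_policy != "exclude":
        raise ValueError("only the 'exclude' censoring policy is implemented")
    horizon = config.horizon_years if horizon is None else horizon
    preds_v2 = predict_cohort(cohort, config, "v2", with_benefits=False)
    preds_v3 = predict_cohort(cohort, config, "v3", with_benefits=False)

    report = {
        "horizon_years": horizon,
        "quantile_bins": k,
        "censor_policy": censor_policy,
        "subsets": {},
    }
    subsets = {"all": cohort}
    er_pos_ids = {r.id for r in cohort.records if r.er == "pos"}
    if er_pos_ids:
        subsets["er_pos"] = cohort.subset(er_pos_ids, provenance="ER+ subset")
    for name, sub in subsets.items():
        ids = {r.id for r in sub.records}
        report["subsets"][name] = _subset_report(
            sub,
            [p for p in preds_v2 if p.id in ids],
            [p for p in preds_v3 if p.id in ids],
            horizon,
            k,
        )
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        if make_plots:
            _write_plots(cohort, preds_v2, preds_v3, report, horizon, outdir)
    return report


def _write_plots(cohort, preds_v2, preds_v3, report, horizon, outdir) -> None:
    """Calibration (observed with 95% CI vs expected by quantile) and ROC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report["subsets"].get("er_pos", report["subsets"]["all"])
    quant = sub["calibration"]["by_quantile"].get("v3")
    if quant:
        fig, ax = plt.subplots(figsize=(5, 5))
        exp = [q["expected_v3"] for q in quant]
        obs = [q["observed"] for q in quant]
        lo = [q["observed"] - q["ci_low"] for q in quant]
        hi = [q["ci_high"] - q["observed"] for q in quant]
        ax.errorbar(exp, obs, yerr=[lo, hi], fmt="o", capsize=3)
        lim = max(max(exp, default=1), max(obs, default=1)) * 1.1
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("Predicted deaths")
        ax.set_ylabel("Observed deaths (95% CI)")
        ax.set_title("Calibration by quantile of predicted risk (v3)")
        fig.tight_layout()
        fig.savefig(outdir / "calibration.png", dpi=120)
        plt.close(fig)

    statuses = observed_outcomes(cohort, horizon)
    labels, keep = _binary_labels(statuses)
    if labels[keep].sum() >= 1 and (1 - labels[keep]).sum() >= 1:
        fig, ax = plt.subplots(figsize=(5, 5))
        for version, preds in (("v2", preds_v2), ("v3", preds_v3)):
            scores = np.array([p.cuminc_bc[horizon] for p in preds])[keep]
            res = roc_auc(scores, labels[keep])
            ax.plot(res.curve[:, 0], res.curve[:, 1],
                    label=f"{version} (AUC {res.auc:.4f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        ax.set_title(f"ROC for {horizon}-year breast-cancer mortality")
        fig.tight_layout()
        fig.savefig(outdir / "roc.png", dpi=120)
        plt.close(fig)
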
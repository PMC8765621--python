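"""Trial-level mixed linear model of late ERP amplitude, FDR, correlations.

Single-trial amplitudes (mean voltage over a temporal ROI at one
electrode, default 450–630 ms where the late modulation is expected)
are modeled with a linear mixed model with a random intercept per
participant and nine fixed effects:

    amplitude = int + EmoLSF + EmoHSF + EmoLSF:HSF + pASD
                + pASD:EmoLSF + pASD:EmoHSF + pASD:EmoLSF:HSF + Sex

where EmoLSF / EmoHSF indicate happiness in the low / high spatial
frequency band (happiness coded 1), their product captures the
congruent-happy integration effect, and pASD indicates the parent
group.  The condition <-> indicator mapping is a bijection: HH=(1,1),
AA=(0,0), HA=(1,0), AH=(0,1).  Fits are maximum likelihood with Wald
p-values on the fixed effects (a likelihood-ratio alternative is
available per term); the same model fitted at every electrode is
corrected across electrodes per coefficient with Benjamini–Hochberg
FDR at q = 0.05.

Severity links are Spearman rank correlations; the partial variant
correlates the rank residuals of both variables after regressing out
the ranks of a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .epochs import EpochSet
from .layout import SensorLayout

__all__ = [
    "TRIAL_MODEL_TERMS",
    "CONDITION_CODING",
    "design_matrix",
    "trial_roi_amplitudes",
    "TrialModelFit",
    "fit_trial_model",
    "fit_trial_model_scalp",
    "fdr_select",
    "severity_correlation",
]

# happiness coded 1 in each spatial-frequency band
CONDITION_CODING = {"HH": (1, 1), "AA": (0, 0), "HA": (1, 0), "AH": (0, 1)}

TRIAL_MODEL_TERMS = ("int", "EmoLSF", "EmoHSF", "EmoLSFxHSF", "pASD",
                     "pASD:EmoLSF", "pASD:EmoHSF", "pASD:EmoLSFxHSF", "Sex")


def design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Expand trial rows into the nine-column fixed-effect design.

    ``table`` needs columns ``condition``, ``group`` and optionally
    ``sex`` (coded 0/1, reference 0 = female; absent -> all zeros).
    Indicators are 0/1 and the product column equals EmoLSF * EmoHSF.
    """
    cond = table["condition"]
    unknown = set(cond) - set(CONDITION_CODING)
    if unknown:
        raise ValueError(f"unknown conditions {unknown}")
    lsf = cond.map(lambda c: CONDITION_CODING[c][0]).astype(float)
    hsf = cond.map(lambda c: CONDITION_CODING[c][1]).astype(float)
    pasd = (table["group"] == "pASD").astype(float)
    sex = (table["sex"].astype(float) if "sex" in table.columns
           else pd.Series(0.0, index=table.index))
    X = pd.DataFrame({
        "int": 1.0,
        "EmoLSF": lsf,
        "EmoHSF": hsf,
        "EmoLSFxHSF": lsf * hsf,
        "pASD": pasd,
        "pASD:EmoLSF": pasd * lsf,
        "pASD:EmoHSF": pasd * hsf,
        "pASD:EmoLSFxHSF": pasd * lsf * hsf,
        "Sex": sex,
    }, index=table.index)
    return X


def trial_roi_amplitudes(
    epochs: EpochSet,
    window_ms: tuple[float, float],
    electrode: str,
    layout: SensorLayout,
    sex: int = 0,
) -> pd.DataFrame:
    """Per-trial mean voltage over the window at one electrode.

    Clean trials only; rows carry the labels needed by
    :func:`design_matrix` (participant, group, condition, sex).
    """
    tmask = epochs.time_mask(window_ms)
    ch = layout.index(electrode)
    clean = epochs.clean_mask()
    amp = epochs.data[clean][:, ch, :][:, tmask].mean(axis=1)
    return pd.DataFrame({
        "participant": epochs.participant,
        "group": epochs.group,
        "condition": epochs.condition[clean],
        "sex": sex,
        "amplitude": amp,
    })


@dataclass
class TrialModelFit:
    """Per-electrode coefficient table of the trial-level mixed model."""

    coefficients: pd.DataFrame  # term, estimate, se, z, p
    random_intercept_var: float
    residual_var: float
    loglik: float
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "estimate"])


def fit_trial_model(table: pd.DataFrame,
                    random_intercept: bool = True) -> TrialModelFit:
    """Fit the trial-level model at one electrode.

    Maximum-likelihood linear mixed model with a participant random
    intercept; ``random_intercept=False`` falls back to ordinary least
    squares on the identical design (the limit of zero random-intercept
    variance).  Raises on singular designs — e.g. a missing group or
    condition.
    """
    for col in ("participant", "group", "condition", "amplitude"):
        if col not in table.columns:
            raise ValueError(f"table must have column {col!r}")
    if table["group"].nunique() < 2:
        raise ValueError("both groups must be present (design is singular)")
    if set(table["condition"]) != set(CONDITION_CODING):
        raise ValueError("all four conditions must be present")
    X = design_matrix(table)
    keep = [c for c in X.columns if c == "int" or X[c].nunique() > 1]
    y = table["amplitude"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X[keep].to_numpy())
    if rank < len(keep):
        raise ValueError("singular fixed-effect design")

    if random_intercept:
        model = sm.MixedLM(y, X[keep].to_numpy(),
                           groups=table["participant"].to_numpy())
        res = model.fit(reml=False)
        estimates = res.fe_params
        se = res.bse_fe
        re_var = float(np.asarray(res.cov_re)[0, 0])
        resid_var = float(res.scale)
        llf = float(res.llf)
        converged = bool(res.converged)
    else:
        res = sm.OLS(y, X[keep].to_numpy()).fit()
        estimates, se = res.params, res.bse
        re_var, resid_var = 0.0, float(res.scale)
        llf, converged = float(res.llf), True

    z = np.asarray(estimates) / np.asarray(se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame({"term": keep, "estimate": np.asarray(estimates),
                         "se": np.asarray(se), "z": z, "p": p})
    # report dropped terms as NaN so every fit exposes the full term list
    missing = [t for t in TRIAL_MODEL_TERMS if t not in keep]
    if missing:
        coef = pd.concat([coef, pd.DataFrame(
            {"term": missing, "estimate": np.nan, "se": np.nan,
             "z": np.nan, "p": np.nan})], ignore_index=True)
    coef["term"] = pd.Categorical(coef["term"], categories=TRIAL_MODEL_TERMS,
                                  ordered=True)
    coef = coef.sort_values("term").reset_index(drop=True)
    return TrialModelFit(coefficients=coef, random_intercept_var=re_var,
                         residual_var=resid_var, loglik=llf,
                         converged=converged)


def fit_trial_model_scalp(
    epochs_by_participant: dict[str, EpochSet],
    layout: SensorLayout,
    window_ms: tuple[float, float] = (450.0, 630.0),
    electrodes: list[str] | None = None,
    sex_by_participant: dict[str, int] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Fit the model at every electrode and FDR-correct across electrodes.

    Returns a tidy table (electrode, term, estimate, se, p, fdr_pass)
    where the Benjamini–Hochberg mask is computed per coefficient across
    electrodes.
    """
    if electrodes is None:
        electrodes = list(layout.names)
    rows = []
    for el in electrodes:
        parts = []
        for pid, ep in epochs_by_participant.items():
            sex = (sex_by_participant or {}).get(pid, 0)
            parts.append(trial_roi_amplitudes(ep, window_ms, el, layout, sex))
        fit = fit_trial_model(pd.concat(parts, ignore_index=True))
        for _, r in fit.coefficients.iterrows():
            rows.append(dict(electrode=el, term=str(r["term"]),
                             estimate=r["estimate"], se=r["se"], p=r["p"]))
    out = pd.DataFrame(rows)
    out["fdr_pass"] = False
    for term, sub in out.groupby("term"):
        pvals = sub["p"].to_numpy()
        if np.isnan(pvals).all():
            continue
        mask = fdr_select(np.nan_to_num(pvals, nan=1.0), q=q)
        out.loc[sub.index, "fdr_pass"] = mask
    return out


def fdr_select(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up selection mask at FDR level q."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


def severity_correlation(
    roi_values: np.ndarray,
    severity: np.ndarray,
    covariate: np.ndarray | None = None,
) -> dict[str, float]:
    """Spearman correlation between a per-parent ERP measure and severity.

    With a covariate, additionally reports the partial Spearman
    correlation: both variables are rank-transformed, the covariate's
    ranks are regressed out of each, and the residuals correlated; the
    p-value uses the t approximation with n - 3 degrees of freedom.
    """
    x = np.asarray(roi_values, dtype=float)
    y = np.asarray(severity, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("roi_values and severity must be equal-length 1-D")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    out = {"rho": float(rho), "p": float(p), "n": n}
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if c.shape != x.shape:
            raise ValueError("covariate must match length")
        rx, ry, rc = (stats.rankdata(v) for v in (x, y, c))
        Z = np.column_stack([np.ones(n), rc])
        res_x = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        denom = np.sqrt((res_x ** 2).sum() * (res_y ** 2).sum())
        if denom == 0:
            raise ValueError("partial correlation undefined (constant ranks)")
        pr = float((res_x * res_y).sum() / denom)
        df = n - 3
        t = pr * np.sqrt(df / max(1e-12, 1.0 - pr ** 2))
        out["partial_rho"] = pr
        out["partial_p"] = float(2.0 * stats.t.sf(abs(t), df))
    return out
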
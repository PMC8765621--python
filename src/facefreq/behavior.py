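"""Behavioral statistics: accuracy, d-prime, response biases, rank tests.

The task is a two-alternative forced choice (happiness vs anger) on
hybrid faces.  Accuracy is only defined on congruent trials (AA, HH),
where the two frequency bands agree on the emotion.  On incongruent
trials (AH, HA) two biases are measured, both bounded in [-0.5, 0.5]:

* spatial-frequency bias — P(response matches the HSF emotion) - 0.5;
* emotional bias — P(respond "happy") - 0.5.

A raw happiness bias partly reflects that happy faces are easier, so a
corrected emotional bias subtracts half the congruent accuracy gap:
``corrected = raw - (acc_HH - acc_AA) / 2`` per participant.  The
published description of this correction is verbal only; this closed
form is the package's reading of it, kept isolated in one function.

Sensitivity is d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate); when a
rate is degenerate (0 or 1) the log-linear remedy adds 0.5 successes
and 1 trial to the cell before the quantile transform.

Two-sample comparisons use Wilcoxon tests (exact null distribution for
n <= 25 without ties, normal approximation with continuity correction
otherwise) with the effect size r = |Z| / sqrt(n); condition x group
analyses of the happiness-response rate and reaction time use a mixed
ANOVA (4 within-levels x 2 groups) with generalized eta squared and
sphericity diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .epochs import CONDITIONS

__all__ = [
    "accuracy_measures",
    "dprime",
    "sdt_summary",
    "bias_measures",
    "nonparametric_tests",
    "happiness_rate_anova",
    "rt_anova",
    "behavior_summary",
]

CONGRUENT = ("AA", "HH")
INCONGRUENT = ("AH", "HA")
_HAPPY = "happy"


def _check_table(table: pd.DataFrame) -> None:
    for col in ("participant", "condition", "response"):
        if col not in table.columns:
            raise ValueError(f"behavior table must have column {col!r}")
    bad = set(table["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {bad}")
    bad = set(table["response"]) - {"happy", "anger"}
    if bad:
        raise ValueError(f"responses must be happy/anger, got {bad}")


def accuracy_measures(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy on congruent trials (global, HH, AA).

    A response is correct when it names the emotion shown congruently in
    both bands; incongruent trials have no defined correct answer and
    are excluded.
    """
    _check_table(table)
    cong = table[table["condition"].isin(CONGRUENT)]
    if cong.empty:
        raise ValueError("no congruent trials")
    correct = ((cong["condition"] == "HH") & (cong["response"] == _HAPPY)) | \
              ((cong["condition"] == "AA") & (cong["response"] == "anger"))
    df = cong.assign(correct=correct.astype(float))
    out = df.groupby("participant").agg(
        accuracy=("correct", "mean"),
        n_congruent=("correct", "size"),
    )
    by_cond = df.pivot_table(index="participant", columns="condition",
                             values="correct", aggfunc="mean")
    out["acc_HH"] = by_cond.get("HH")
    out["acc_AA"] = by_cond.get("AA")
    if "group" in table.columns:
        out["group"] = table.groupby("participant")["group"].first()
    return out.reset_index()


def _z(rate: float) -> float:
    return float(stats.norm.ppf(rate))


def dprime(hit_rate: float, fa_rate: float,
           n_signal: int | None = None, n_noise: int | None = None) -> float:
    """Sensitivity d' = Z(hit rate) - Z(false-alarm rate).

    Degenerate rates (exactly 0 or 1) are corrected with the log-linear
    rule — (x + 0.5) / (n + 1) — which requires the trial count for the
    affected cell.
    """
    for name, r in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    def corrected(rate, n):
        if 0.0 < rate < 1.0:
            return rate
        if n is None:
            raise ValueError("degenerate rate needs the cell trial count "
                             "for the log-linear correction")
        return (rate * n + 0.5) / (n + 1)

    return _z(corrected(hit_rate, n_signal)) - _z(corrected(fa_rate, n_noise))


def sdt_summary(table: pd.DataFrame, signal: str = "happy-congruent"
                ) -> pd.DataFrame:
    """Per-participant hit/false-alarm rates and d' for a signal definition.

    ``signal`` chooses what counts as the signal trial class:

    * ``"happy-congruent"`` — HH trials are signal, AA noise; a "happy"
      response is a hit / false alarm (global emotion sensitivity);
    * ``"hsf-incongruent"`` — on incongruent trials the HSF emotion is
      the signal: hits are happy responses on AH, false alarms happy
      responses on HA;
    * ``"lsf-incongruent"`` — the mirror definition for the LSF band.
    """
    _check_table(table)
    defs = {
        "happy-congruent": ("HH", "AA"),
        "hsf-incongruent": ("AH", "HA"),
        "lsf-incongruent": ("HA", "AH"),
    }
    if signal not in defs:
        raise ValueError(f"signal must be one of {sorted(defs)}")
    sig_cond, noise_cond = defs[signal]
    rows = []
    for pid, sub in table.groupby("participant"):
        sig = sub[sub["condition"] == sig_cond]
        noi = sub[sub["condition"] == noise_cond]
        if sig.empty or noi.empty:
            raise ValueError(f"participant {pid}: missing signal/noise trials")
        hit = (sig["response"] == _HAPPY).mean()
        fa = (noi["response"] == _HAPPY).mean()
        rows.append(dict(
            participant=pid, signal=signal, hit_rate=hit, fa_rate=fa,
            dprime=dprime(hit, fa, len(sig), len(noi)),
        ))
    return pd.DataFrame(rows)


def bias_measures(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant SF bias, emotional bias and corrected emotional bias."""
    _check_table(table)
    inc = table[table["condition"].isin(INCONGRUENT)]
    if inc.empty:
        raise ValueError("no incongruent trials")
    acc = accuracy_measures(table).set_index("participant")
    rows = []
    for pid, sub in inc.groupby("participant"):
        happy = sub["response"] == _HAPPY
        # response matches the HSF emotion: happy on AH (HSF=H), anger on HA
        hsf_match = np.where(sub["condition"] == "AH", happy, ~happy)
        emo_bias = happy.mean() - 0.5
        sf_bias = hsf_match.mean() - 0.5
        gap = float(acc.loc[pid, "acc_HH"] - acc.loc[pid, "acc_AA"])
        rows.append(dict(
            participant=pid,
            sf_bias=float(sf_bias),
            emotional_bias=float(emo_bias),
            corrected_emotional_bias=float(emo_bias - gap / 2.0),
        ))
    return pd.DataFrame(rows)


def nonparametric_tests(
    values: np.ndarray,
    design: str,
    other: np.ndarray | None = None,
    mu: float = 0.0,
) -> dict[str, float]:
    """Wilcoxon signed-rank / rank-sum test with effect size r = |Z|/sqrt(n).

    ``design`` is ``"one-sample"`` (vs the constant ``mu``),
    ``"paired"`` or ``"unpaired"``.  Z is recovered from the two-sided
    p-value.  Degenerate all-zero differences are reported with p = 1
    and a ``degenerate`` flag rather than an error.
    """
    x = np.asarray(values, dtype=float)
    out: dict[str, float] = {}
    if design in ("one-sample", "paired"):
        d = x - (mu if design == "one-sample" else np.asarray(other, float))
        n = d.size
        if np.all(d == 0):
            return {"statistic": 0.0, "p": 1.0, "r": 0.0, "n": n,
                    "degenerate": True}
        mode = "exact" if (n <= 25 and np.unique(np.abs(d[d != 0])).size
                           == np.count_nonzero(d)) else "approx"
        res = stats.wilcoxon(d, method=mode, correction=(mode == "approx"))
        stat, p = float(res.statistic), float(res.pvalue)
    elif design == "unpaired":
        y = np.asarray(other, dtype=float)
        n = x.size + y.size
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("design must be one-sample, paired or unpaired")
    z = stats.norm.isf(min(max(p, 1e-300), 1.0) / 2.0)
    out.update(statistic=stat, p=p, r=float(abs(z) / np.sqrt(n)), n=n,
               degenerate=False)
    return out


def _per_participant_rates(table: pd.DataFrame, value: str) -> pd.DataFrame:
    _check_table(table)
    if "group" not in table.columns:
        raise ValueError("table must have a group column")
    df = table.assign(happy=(table["response"] == _HAPPY).astype(float))
    col = "happy" if value == "happy" else "rt_ms"
    rates = (df.groupby(["participant", "group", "condition"], observed=True)
             [col].mean().reset_index(name="value"))
    counts = rates.groupby("participant")["condition"].nunique()
    if (counts < len(CONDITIONS)).any():
        raise ValueError("every participant needs all four conditions")
    return rates


def _mixed_anova(rates: pd.DataFrame) -> pd.DataFrame:
    aov = pg.mixed_anova(rates, dv="value", within="condition",
                         subject="participant", between="group",
                         correction=True, effsize="ng2")
    sph = pg.sphericity(rates, dv="value", within="condition",
                        subject="participant")
    aov.attrs["mauchly_W"] = float(sph.W)
    aov.attrs["mauchly_p"] = float(sph.pval)
    return aov


def happiness_rate_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Mixed ANOVA of P(respond happy): condition (within) x group (between).

    Generalized eta squared effect sizes; Greenhouse–Geisser corrected
    p for the within effect and Mauchly's W attached in ``attrs``.
    """
    return _mixed_anova(_per_participant_rates(table, "happy"))


def rt_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Mixed ANOVA of mean reaction time: condition x group."""
    if "rt_ms" not in table.columns:
        raise ValueError("table must have rt_ms")
    if (table["rt_ms"] <= 0).any():
        raise ValueError("reaction times must be positive")
    return _mixed_anova(_per_participant_rates(table, "rt"))


def behavior_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group-level summary of the headline behavioral measures.

    One row per group x measure with the mean, SE and the one-sample
    Wilcoxon p against the chance value (0.5 for accuracies, 0 for
    biases and d').
    """
    acc = accuracy_measures(table).set_index("participant")
    bias = bias_measures(table).set_index("participant")
    sdt = sdt_summary(table, "happy-congruent").set_index("participant")
    merged = acc.join(bias).join(sdt[["dprime"]])
    rows = []
    chance = {"accuracy": 0.5, "acc_HH": 0.5, "acc_AA": 0.5, "sf_bias": 0.0,
              "emotional_bias": 0.0, "corrected_emotional_bias": 0.0,
              "dprime": 0.0}
    for group, sub in merged.groupby("group"):
        for measure, mu in chance.items():
            v = sub[measure].to_numpy(dtype=float)
            test = nonparametric_tests(v, "one-sample", mu=mu)
            rows.append(dict(group=group, measure=measure,
                             mean=float(v.mean()),
                             se=float(v.std(ddof=1) / np.sqrt(v.size)),
                             p_vs_chance=test["p"], r=test["r"], n=v.size))
    return pd.DataFrame(rows)
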
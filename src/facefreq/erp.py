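"""A-priori ERP component extraction and the condition x laterality x group ANOVA.

The early face-sensitive components are measured on condition-average
ERPs in fixed windows and electrode pairs: P1 as the maximum voltage in
100–150 ms over parieto-occipital electrodes (E35 left, E39 right), N170
as the minimum in 160–200 ms and N250 as the mean in 250–350 ms, both
over temporo-parietal pairs (E27/E30 left, E44/E45 right).  The signal
is averaged over each hemisphere's electrode set before the window
extremum/mean is taken ("extremum" rather than "mean around the
extremum", the other reading of a windowed peak measure; switching the
aggregation order is a one-line change in :func:`component_amplitude`).

The mixed ANOVA treats condition (4) and laterality (2) as within
factors and group as the between factor.  It is implemented through
orthonormal within-cell contrasts: each within effect's contrast scores
are submitted to a one-way between-group analysis, which yields the
classical split-plot F tests, handles unequal group sizes, and puts all
strata on a common sum-of-squares scale so generalized eta squared can
be reported.  Sphericity for the condition-related effects is assessed
with Mauchly's W on the pooled within-group covariance of the contrast
scores, with Greenhouse–Geisser and Huynh–Feldt corrected p-values.
Main within effects use Type II sums of squares by default (weighted
grand mean, i.e. computed ignoring the group interaction); ``ss_type=3``
switches to unweighted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import CONDITIONS, EpochSet
from .layout import SensorLayout

__all__ = [
    "ComponentSpec",
    "default_component_specs",
    "condition_average",
    "component_amplitude",
    "component_table",
    "component_anova",
    "mixed_anova_cells",
]


@dataclass
class ComponentSpec:
    """Measurement rule for one ERP component."""

    name: str
    measure: str  # "max", "min" or "mean"
    window_ms: tuple[float, float]
    electrodes: dict[str, list[str]]  # hemisphere -> electrode names

    def __post_init__(self) -> None:
        if self.measure not in ("max", "min", "mean"):
            raise ValueError("measure must be 'max', 'min' or 'mean'")
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window must be increasing")
        if not self.electrodes:
            raise ValueError("electrode sets required")


def default_component_specs() -> list[ComponentSpec]:
    tp_left, tp_right = ["E27", "E30"], ["E44", "E45"]
    return [
        ComponentSpec("P1", "max", (100.0, 150.0),
                      {"left": ["E35"], "right": ["E39"]}),
        ComponentSpec("N170", "min", (160.0, 200.0),
                      {"left": tp_left, "right": tp_right}),
        ComponentSpec("N250", "mean", (250.0, 350.0),
                      {"left": tp_left, "right": tp_right}),
    ]


def condition_average(
    epochs: EpochSet, return_counts: bool = False
):
    """Average clean trials per condition -> dict cond -> channels x time."""
    clean = epochs.clean_mask()
    avgs, counts = {}, {}
    for cond in CONDITIONS:
        sel = clean & (epochs.condition == cond)
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"no clean trials for condition {cond}")
        avgs[cond] = epochs.data[sel].mean(axis=0)
        counts[cond] = n
    return (avgs, counts) if return_counts else avgs


def component_amplitude(
    avg: np.ndarray,
    times_ms: np.ndarray,
    layout: SensorLayout,
    spec: ComponentSpec,
) -> dict[str, float]:
    """Per-hemisphere amplitude of one component on a channels x time average.

    The signal is first averaged over the hemisphere's electrode set,
    then the window max/min/mean is taken according to the spec.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = spec.window_ms
    if lo < times_ms[0] or hi > times_ms[-1]:
        raise ValueError(f"window {spec.window_ms} outside epoch")
    tmask = (times_ms >= lo) & (times_ms <= hi)
    out = {}
    for hemi, electrodes in spec.electrodes.items():
        idx = layout.indices(electrodes)
        trace = avg[idx].mean(axis=0)[tmask]
        if spec.measure == "max":
            out[hemi] = float(trace.max())
        elif spec.measure == "min":
            out[hemi] = float(trace.min())
        else:
            out[hemi] = float(trace.mean())
    return out


def component_table(
    epochs_by_participant: dict[str, EpochSet],
    layout: SensorLayout,
    specs: list[ComponentSpec] | None = None,
) -> pd.DataFrame:
    """One amplitude row per participant x condition x hemisphere x component."""
    if specs is None:
        specs = default_component_specs()
    rows = []
    for pid, ep in epochs_by_participant.items():
        avgs = condition_average(ep)
        for cond, avg in avgs.items():
            for spec in specs:
                amps = component_amplitude(avg, ep.times, layout, spec)
                for hemi, amp in amps.items():
                    rows.append(dict(participant=pid, group=ep.group,
                                     condition=cond, hemisphere=hemi,
                                     component=spec.name, amplitude=amp))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Split-plot (mixed) ANOVA via orthonormal within-cell contrasts
# ---------------------------------------------------------------------

def _helmert(m: int) -> np.ndarray:
    """Orthonormal contrast matrix (m x (m-1)), columns unit norm."""
    c = np.zeros((m, m - 1))
    for j in range(1, m):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _oneway_ss(z: np.ndarray, groups: np.ndarray, ss_type: int):
    """Intercept, group and residual SS of a one-way layout on scores z."""
    labels = pd.unique(groups)
    k = len(labels)
    n = np.array([(groups == g).sum() for g in labels], dtype=float)
    means = np.array([z[groups == g].mean() for g in labels])
    resid = sum(((z[groups == g] - means[i]) ** 2).sum()
                for i, g in enumerate(labels))
    grand_w = (n * means).sum() / n.sum()
    ss_grp = (n * (means - grand_w) ** 2).sum()
    if ss_type == 2:  # weighted grand mean (intercept ignoring interaction)
        ss_int = n.sum() * grand_w ** 2
    else:             # unweighted means (Type III)
        grand_u = means.mean()
        ss_int = grand_u ** 2 * k ** 2 / (1.0 / n).sum()
    return ss_int, ss_grp, resid, k, n.sum()


def _sphericity(scores: np.ndarray, groups: np.ndarray):
    """Mauchly W/p and GG/HF epsilons from pooled contrast covariance."""
    labels = pd.unique(groups)
    q = scores.shape[1]
    n_e = len(scores) - len(labels)
    pooled = np.zeros((q, q))
    for g in labels:
        zg = scores[groups == g]
        zg = zg - zg.mean(axis=0)
        pooled += zg.T @ zg
    pooled /= n_e
    lam = np.linalg.eigvalsh(pooled)
    lam = np.clip(lam, 0.0, None)
    tr = lam.sum()
    eps_gg = tr ** 2 / (q * (lam ** 2).sum()) if tr > 0 else 1.0
    hf_num = (n_e + 1) * q * eps_gg - 2.0
    hf_den = q * (n_e - q * eps_gg)
    eps_hf = min(1.0, hf_num / hf_den) if hf_den > 0 else 1.0
    if tr > 0 and np.all(lam > 1e-12):
        W = float(np.prod(lam) / (tr / q) ** q)
        d = 1.0 - (2.0 * q ** 2 + q + 2.0) / (6.0 * q * n_e)
        chi2 = -n_e * d * np.log(W)
        dof = q * (q + 1) // 2 - 1
        p = float(stats.chi2.sf(chi2, dof))
    else:
        W, p = 0.0, 0.0
    return W, p, float(eps_gg), float(eps_hf)


def mixed_anova_cells(
    cells: np.ndarray,
    groups: np.ndarray,
    within_shapes: tuple[int, ...],
    within_names: tuple[str, ...],
    between_name: str = "group",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Split-plot ANOVA on a participants x within-cells matrix.

    ``cells`` has one row per participant and one column per within-cell,
    laid out in C order over ``within_shapes`` (e.g. ``(4, 2)`` for
    condition-major, hemisphere-minor).  Returns one row per effect with
    F, dfs, p, generalized eta squared, and sphericity diagnostics with
    GG/HF-corrected p-values for multi-df within effects.
    """
    cells = np.asarray(cells, dtype=float)
    groups = np.asarray(groups)
    if cells.ndim != 2 or cells.shape[1] != int(np.prod(within_shapes)):
        raise ValueError("cells must be participants x prod(within_shapes)")
    if not np.all(np.isfinite(cells)):
        raise ValueError("missing or non-finite cell values")
    if len(groups) != len(cells):
        raise ValueError("one group label per participant required")
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")

    # Orthonormal basis per within factor: unit column + Helmert contrasts.
    factor_bases = []
    for m in within_shapes:
        unit = np.full((m, 1), 1.0 / np.sqrt(m))
        factor_bases.append((unit, _helmert(m)))

    # Kronecker products give one orthonormal column block per effect.
    effects: dict[tuple[int, ...], np.ndarray] = {}
    n_fac = len(within_shapes)
    for mask in range(2 ** n_fac):
        block = np.ones((1, 1))
        sel = []
        for f in range(n_fac):
            use_contrast = (mask >> f) & 1
            block = np.kron(block, factor_bases[f][use_contrast])
            if use_contrast:
                sel.append(f)
        effects[tuple(sel)] = block

    def safe_f(ss_eff, df1, ss_err, df_err):
        """F with degenerate strata handled: 0/0 -> 0, x/0 -> inf."""
        if df1 <= 0 or df_err <= 0:
            return np.nan
        ms_err = ss_err / df_err
        if ms_err == 0.0:
            return 0.0 if ss_eff <= 1e-300 else np.inf
        return (ss_eff / df1) / ms_err

    rows = []
    all_resid = 0.0
    per_effect = {}
    for sel, block in effects.items():
        z = cells @ block  # participants x q scores
        q = z.shape[1]
        ss_int = ss_grp = ss_res = 0.0
        for j in range(q):
            si, sg, sr, k, n_tot = _oneway_ss(z[:, j], groups, ss_type)
            ss_int += si
            ss_grp += sg
            ss_res += sr
        all_resid += ss_res
        per_effect[sel] = (z, ss_int, ss_grp, ss_res, q, k, n_tot)

    for sel, (z, ss_int, ss_grp, ss_res, q, k, n_tot) in per_effect.items():
        df_err = q * (n_tot - k)
        name_w = ":".join(within_names[f] for f in sel)
        if sel == ():
            # Between-subject stratum: group main effect.
            F = safe_f(ss_grp, k - 1, ss_res, n_tot - k)
            rows.append(dict(effect=between_name, F=F, df1=k - 1,
                             df2=n_tot - k, p=stats.f.sf(F, k - 1, n_tot - k),
                             ss=ss_grp, ss_err=ss_res))
            continue
        sphere = _sphericity(z, groups) if q > 1 else (1.0, 1.0, 1.0, 1.0)
        W, p_mauchly, eps_gg, eps_hf = sphere
        for label, ss_eff, df1 in (
            (name_w, ss_int, q),
            (f"{between_name}:{name_w}", ss_grp, q * (k - 1)),
        ):
            F = safe_f(ss_eff, df1, ss_res, df_err)
            df2 = df_err
            row = dict(effect=label, F=F, df1=df1, df2=df2,
                       p=stats.f.sf(F, df1, df2),
                       ss=ss_eff, ss_err=ss_res)
            if q > 1:
                row.update(
                    mauchly_W=W, mauchly_p=p_mauchly,
                    eps_gg=eps_gg, eps_hf=eps_hf,
                    p_gg=stats.f.sf(F, df1 * eps_gg, df2 * eps_gg),
                    p_hf=stats.f.sf(F, df1 * eps_hf, df2 * eps_hf),
                )
            rows.append(row)

    out = pd.DataFrame(rows)
    out["ges"] = out["ss"] / (out["ss"] + all_resid)
    return out


def component_anova(
    table: pd.DataFrame, component: str | None = None, ss_type: int = 2
) -> pd.DataFrame:
    """Condition x laterality x group mixed ANOVA on a component table.

    ``table`` needs columns participant, group, condition, hemisphere,
    amplitude (and component, if more than one is present).  Requires a
    complete, balanced within design: one amplitude per participant per
    condition x hemisphere cell.
    """
    df = table
    if component is not None:
        df = df[df["component"] == component]
    elif "component" in df.columns and df["component"].nunique() > 1:
        raise ValueError("multiple components present; pass component=...")
    hemis = sorted(df["hemisphere"].unique())
    pivot = df.pivot_table(index=["participant", "group"],
                           columns=["condition", "hemisphere"],
                           values="amplitude", aggfunc="first")
    expected = [(c, h) for c in CONDITIONS for h in hemis]
    try:
        pivot = pivot[expected]
    except KeyError as exc:
        raise ValueError("missing condition x hemisphere cells") from exc
    if pivot.isna().any().any():
        raise ValueError("missing cells for some participants")
    cells = pivot.to_numpy()
    groups = np.array([g for _, g in pivot.index])
    return mixed_anova_cells(
        cells, groups, within_shapes=(len(CONDITIONS), len(hemis)),
        within_names=("condition", "laterality"), ss_type=ss_type)
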
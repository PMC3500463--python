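"""Difference-wave and behavioral statistics.

The inferential core of the analysis:

* sample-by-sample paired t-tests of a per-subject difference wave against
  zero inside an a priori window (80-230 ms for the figure-minus-homogenous
  contrast, 200-350 ms for stack-minus-frame), corrected by the
  Benjamini-Hochberg step-up procedure at q = 0.05, with interpolated
  samples excluded from testing and contiguous significant runs reported as
  intervals in ms;
* the cumulative stack-minus-frame statistic: the per-subject sum of the
  difference signal over 227-313 ms, compared between TMS conditions with
  paired t-tests (optionally on correct trials only);
* the behavioral layer: RT and subject-accuracy filters, a from-scratch
  3 x 4 within-subject ANOVA (stimulus kind x TMS window), FDR-flagged
  post-hoc paired tests, and the error-type (confusion) analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from figground.stimuli import STIMULUS_KINDS, TMS_CONDITIONS

#: a priori test windows, ms post-stimulus
EARLY_WINDOW_MS = (80.0, 230.0)
LATE_WINDOW_MS = (200.0, 350.0)
#: window of the cumulative stack-frame statistic
CUMULATIVE_WINDOW_MS = (227.0, 313.0)


class MaskedWindowError(ValueError):
    """The whole test window is interpolated and cannot be tested."""


# ---------------------------------------------------------------- behavior

def filter_behavior(
    table: pd.DataFrame,
    rt_bounds_ms: tuple[float, float] = (100.0, 1500.0),
    min_accuracy: float = 0.67,
) -> tuple[pd.DataFrame, dict]:
    """Apply the trial- and subject-level exclusion rules.

    Trials with RT < 100 ms or > 1500 ms are dropped (bounds themselves are
    retained); subjects whose overall post-RT-filter accuracy fails to
    exceed ``min_accuracy`` are dropped entirely. Returns the filtered
    table and a removal log.
    """
    required = {"subject", "kind", "tms", "response", "rt_ms", "correct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    lo, hi = rt_bounds_ms
    rt_ok = (table["rt_ms"] >= lo) & (table["rt_ms"] <= hi)
    kept = table[rt_ok].copy()
    acc = kept.groupby("subject")["correct"].mean()
    bad_subjects = acc[acc <= min_accuracy].index.tolist()
    out = kept[~kept["subject"].isin(bad_subjects)].reset_index(drop=True)
    log = {
        "n_trials_rt_removed": int((~rt_ok).sum()),
        "excluded_subjects": bad_subjects,
        "subject_accuracy": acc.to_dict(),
    }
    if out.empty:
        raise ValueError("behavior table empty after filtering")
    return out, log


def cell_means(table: pd.DataFrame, value: str = "correct") -> pd.DataFrame:
    """Per-subject 3 x 4 cell means (long format: subject, kind, tms, value)."""
    cm = (
        table.groupby(["subject", "kind", "tms"], sort=True)[value]
        .mean().rename("value").reset_index()
    )
    return cm


def rm_anova_3x4(cells: pd.DataFrame) -> pd.DataFrame:
    """Two-way within-subject ANOVA from first principles.

    ``cells`` must hold one value per subject x kind x tms cell (complete,
    balanced). Sums of squares are computed directly from the cell-mean
    decomposition; each effect is tested against its own effect-by-subject
    interaction (no sphericity correction, matching uncorrected dfs such as
    the (6, 60) interaction at n = 11). Returns a table with effect, df1,
    df2, SS, MS, F, p.
    """
    df = cells.rename(columns={cells.columns[-1]: "value"}) if "value" not in cells else cells
    piv = df.pivot_table(index="subject", columns=["kind", "tms"], values="value")
    if piv.isna().any().any():
        bad = [f"{s}:{c}" for s, row in piv.iterrows() for c in piv.columns[row.isna()]]
        raise ValueError(f"missing design cells: {bad[:5]}")
    subjects = piv.index
    n = len(subjects)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    kinds = sorted(df["kind"].unique())
    conds = sorted(df["tms"].unique())
    a, b = len(kinds), len(conds)
    Y = np.empty((n, a, b))
    for i, s in enumerate(subjects):
        for j, k in enumerate(kinds):
            for l, c in enumerate(conds):
                Y[i, j, l] = piv.loc[s, (k, c)]

    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    # numerically-zero guard: with literally identical cells the error SS is
    # rounding dust; report F = 0 instead of a 0/0 artefact
    tiny = 1e-12 * max(1.0, float(np.abs(Y).max()) ** 2)
    rows = []
    for name, ss_eff, df1, ss_err, df2 in (
        ("kind", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("tms", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("kind:tms", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        degenerate = ms_err <= tiny
        F = ms_eff / ms_err if not degenerate else 0.0
        p = float(sps.f.sf(F, df1, df2)) if not degenerate else 1.0
        rows.append({"effect": name, "df1": df1, "df2": df2, "SS": ss_eff,
                     "SS_error": ss_err, "MS": ms_eff, "F": F, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["SS_total"] = float(ss_total)
    out.attrs["SS_subject"] = float(ss_s)
    out.attrs["SS_components"] = float(ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs + ss_abs)
    return out


# ---------------------------------------------------------------- FDR

def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, p_threshold)``: the largest k with
    p_(k) <= k q / m determines the rejection threshold p_(k) (0 when
    nothing is rejected).
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    thresh = ranked[passing[-1]]
    return p <= thresh, float(thresh)


@dataclass
class SampleTestResult:
    """Per-sample paired-t results over a test window."""

    times_ms: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q_threshold: float
    significant: np.ndarray
    intervals: list[dict]
    window_ms: tuple[float, float]
    n_subjects: int
    tested: np.ndarray  # samples actually entered into the FDR family


def _contiguous_runs(idx: np.ndarray) -> list[np.ndarray]:
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    return np.split(idx, breaks + 1)


def samplewise_fdr_ttest(
    diffs: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    mask: np.ndarray | None = None,
    q: float = 0.05,
) -> SampleTestResult:
    """Mass-univariate paired t-test of difference waves against zero.

    ``diffs`` is (n_subjects, n_times). Samples flagged in ``mask``
    (interpolated TMS segments) are excluded from testing; the BH family is
    the set of tested samples inside ``window_ms``. Contiguous significant
    runs are reported as ms intervals (single-sample runs are flagged).

    Raises
    ------
    MaskedWindowError
        If every sample of the window is interpolated -- that window cannot
        be tested in that condition.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2 or diffs.shape[0] < 2:
        raise ValueError("diffs must be (n_subjects >= 2, n_times)")
    times_ms = np.asarray(times_ms, dtype=float)
    in_win = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not in_win.any():
        raise ValueError(f"window {window_ms} outside the epoch")
    usable = in_win if mask is None else (in_win & ~np.asarray(mask, dtype=bool))
    if not usable.any():
        raise MaskedWindowError(
            f"the {window_ms} ms window could not be tested: all samples are "
            "interpolated over the TMS artifact"
        )
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.full(times_ms.shape, np.nan)
    p = np.full(times_ms.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var & usable):
        warnings.warn("zero-variance samples reported as non-significant")
    tt = np.where(zero_var, 0.0, tt)
    pp = 2 * sps.t.sf(np.abs(tt), df=n - 1)
    pp = np.where(zero_var, 1.0, pp)
    t[usable] = tt[usable]
    p[usable] = pp[usable]

    reject, thresh = bh_fdr(p[usable], q=q)
    significant = np.zeros(times_ms.shape, dtype=bool)
    significant[np.nonzero(usable)[0][reject]] = True

    dt = float(np.median(np.diff(times_ms)))
    intervals = []
    for run in _contiguous_runs(np.nonzero(significant)[0]):
        intervals.append(
            {"start_ms": float(times_ms[run[0]]), "end_ms": float(times_ms[run[-1]]),
             "n_samples": int(run.size), "single_sample": bool(run.size == 1),
             "duration_ms": float(times_ms[run[-1]] - times_ms[run[0]] + dt)}
        )
    return SampleTestResult(
        times_ms=times_ms, t=t, p=p, q_threshold=thresh, significant=significant,
        intervals=intervals, window_ms=tuple(window_ms), n_subjects=n, tested=usable,
    )


def contrast_wave(
    stack: np.ndarray, frame: np.ndarray, homogenous: np.ndarray | None, contrast: str
) -> np.ndarray:
    """Per-subject difference wave for one TMS condition."""
    if contrast == "figure-homogenous":
        if homogenous is None:
            raise ValueError("figure-homogenous contrast needs the homogenous ERP")
        return 0.5 * (stack + frame) - homogenous
    if contrast == "stack-frame":
        return stack - frame
    raise ValueError(f"unknown contrast {contrast!r}")


# ---------------------------------------------------------------- cumulative

def paired_t(x: np.ndarray, y: np.ndarray, tail: str = "two-sided") -> tuple[float, float]:
    """Paired t-test with explicit tail handling; zero-variance differences
    are reported as t=0, p=1 with a warning rather than +/-inf."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if d.std(ddof=1) == 0:
        warnings.warn("zero-variance paired difference; reported non-significant")
        return 0.0, 1.0
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = sps.ttest_rel(x, y, alternative=alt)
    return float(res.statistic), float(res.pvalue)


def cumulative_diff(
    stack: np.ndarray, frame: np.ndarray, times_ms: np.ndarray,
    window_ms: tuple[float, float] = CUMULATIVE_WINDOW_MS,
) -> np.ndarray:
    """Per-subject sum of the stack-frame difference over the window."""
    sel = (np.asarray(times_ms) >= window_ms[0]) & (np.asarray(times_ms) <= window_ms[1])
    if not sel.any():
        raise ValueError(f"window {window_ms} outside epoch")
    return (np.asarray(stack) - np.asarray(frame))[:, sel].sum(axis=1)


def cumulative_diff_test(
    stack_erps: dict[str, np.ndarray],
    frame_erps: dict[str, np.ndarray],
    times_ms: np.ndarray,
    conditions: tuple[str, ...] = ("none", "early", "intermediate"),
    window_ms: tuple[float, float] = CUMULATIVE_WINDOW_MS,
    tail: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative 227-313 ms stack-frame statistic and its condition tests.

    ``stack_erps[cond]`` / ``frame_erps[cond]`` are (n_subjects, n_times)
    pooled traces. Returns ``(values, tests)``: per-subject cumulative
    values per condition, and pairwise paired-t comparisons between the
    requested TMS conditions.
    """
    for c in conditions:
        if c not in stack_erps or c not in frame_erps:
            raise ValueError(f"missing condition {c!r} in the ERP sets")
    vals = {c: cumulative_diff(stack_erps[c], frame_erps[c], times_ms, window_ms)
            for c in conditions}
    n = len(next(iter(vals.values())))
    values = pd.DataFrame(
        [{"subject": i, "tms": c, "cumulative": float(vals[c][i])}
         for c in conditions for i in range(n)]
    )
    rows = []
    for c1, c2 in combinations(conditions, 2):
        t, p = paired_t(vals[c1], vals[c2], tail=tail)
        rows.append({"cond_a": c1, "cond_b": c2, "t": t, "p": p, "n": n})
    return values, pd.DataFrame(rows)


# ---------------------------------------------------------------- errors

def error_type_analysis(table: pd.DataFrame, q: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Misclassification proportions per stimulus kind and TMS condition.

    For every (kind, tms) cell, the proportion of trials answered with each
    of the two wrong responses (the per-stimulus error proportions sum to
    1 - accuracy). Pairwise TMS-condition comparisons of each error type
    across subjects are paired t-tests, BH-corrected within error type.
    """
    rows = []
    for (subj, kind, tms), g in table.groupby(["subject", "kind", "tms"], sort=True):
        for resp in STIMULUS_KINDS:
            if resp == kind:
                continue
            rows.append({"subject": subj, "kind": kind, "tms": tms,
                         "error": f"{kind}->{resp}",
                         "proportion": float((g["response"] == resp).mean())})
    props = pd.DataFrame(rows)
    tests = []
    for err, g in props.groupby("error", sort=True):
        piv = g.pivot_table(index="subject", columns="tms", values="proportion")
        pairs, ps = [], []
        for c1, c2 in combinations([c for c in TMS_CONDITIONS if c in piv.columns], 2):
            sub = piv[[c1, c2]].dropna()
            if len(sub) < 2:
                continue
            t, p = paired_t(sub[c1].to_numpy(), sub[c2].to_numpy())
            pairs.append({"error": err, "cond_a": c1, "cond_b": c2, "t": t, "p": p})
            ps.append(p)
        if pairs:
            reject, _ = bh_fdr(np.array(ps), q=q)
            for r, rej in zip(pairs, reject):
                r["significant_fdr"] = bool(rej)
            tests.extend(pairs)
    return props, pd.DataFrame(tests)


def posthoc_paired(
    cells: pd.DataFrame, kind: str, comparisons: list[tuple[str, str, str]], q: float = 0.05
) -> pd.DataFrame:
    """Post-hoc paired t-tests on one stimulus kind's accuracy across TMS
    conditions; ``comparisons`` entries are (cond_a, cond_b, tail). BH-FDR
    applied across the supplied family."""
    piv = cells[cells["kind"] == kind].pivot_table(
        index="subject", columns="tms", values="value"
    )
    rows, ps = [], []
    for c1, c2, tail in comparisons:
        t, p = paired_t(piv[c1].to_numpy(), piv[c2].to_numpy(), tail=tail)
        rows.append({"kind": kind, "cond_a": c1, "cond_b": c2, "tail": tail, "t": t, "p": p})
        ps.append(p)
    reject, _ = bh_fdr(np.array(ps), q=q)
    for r, rej in zip(rows, reject):
        r["significant_fdr"] = bool(rej)
    return pd.DataFrame(rows)
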
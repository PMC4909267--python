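"""Paired within-subject comparison of stimulation ON vs OFF outcomes.

The analysis mirrors a crossover design with 12 h of each condition per
subject: for every outcome (counts and total durations of short/long breathing
pauses, desaturations below 90/88/85 % and bradycardias below 110/100 bpm) a
paired t-test is run on transformed values — by default ln(x+1), which
normalises right-skewed event counts — while the mean difference (MD), means
and standard errors are reported on the raw scale for interpretability.

Sign conventions: MD = OFF - ON, so a positive MD is a reduction under
stimulation; the per-subject percent-change table uses 100·(ON-OFF)/OFF, so a
*negative* value there is a reduction.  Normality of the paired differences is
screened with Shapiro-Wilk and a Lilliefors-corrected Kolmogorov-Smirnov test;
the screen is reported, never auto-enforced.  p values are two-sided and no
multiple-testing correction is applied (reported in the table's notes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.diagnostic import lilliefors

from .core import OUTCOMES, outcome_stem
from .io import CohortTable

TRANSFORMS = ("sqrt", "log10p1", "lnp1", "identity")


def transform(x, kind: str = "lnp1") -> np.ndarray:
    """Variance-stabilising transform for non-negative counts/durations."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("transform requires non-negative input")
    if kind == "sqrt":
        return np.sqrt(x)
    if kind == "log10p1":
        return np.log10(x + 1.0)
    if kind == "lnp1":
        return np.log1p(x)
    if kind == "identity":
        return x
    raise ValueError(f"unknown transform {kind!r}; choose from {TRANSFORMS}")


@dataclass
class NormalityResult:
    ks_stat: float
    ks_p: float
    shapiro_stat: float
    shapiro_p: float
    degenerate: bool = False


def normality_screen(diffs) -> NormalityResult:
    """Shapiro-Wilk and Lilliefors-KS normality tests on paired differences.

    A constant vector makes both statistics undefined; it is flagged
    ``degenerate`` with NaN statistics rather than raising.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 3:
        raise ValueError("normality screen needs at least 3 differences")
    if np.allclose(diffs, diffs[0]):
        return NormalityResult(np.nan, np.nan, np.nan, np.nan, degenerate=True)
    if diffs.size >= 4:
        ks_stat, ks_p = lilliefors(diffs, dist="norm")
    else:
        ks_stat, ks_p = np.nan, np.nan  # Lilliefors KS needs >= 4 values
    sw_stat, sw_p = sst.shapiro(diffs)
    return NormalityResult(float(ks_stat), float(ks_p), float(sw_stat), float(sw_p))


@dataclass
class PairedTestResult:
    """Raw-scale summary plus the t-test on transformed values for one outcome."""

    outcome: str
    n: int
    mean_off: float
    mean_on: float
    se_off: float
    se_on: float
    md: float  #: raw-scale mean difference, OFF - ON (positive = reduction)
    percent_change: float  #: 100 * MD / OFF mean (positive = reduction)
    t: float
    df: int
    p: float
    transform: str
    degenerate: bool = False
    normality: NormalityResult | None = field(default=None, repr=False)


def paired_test(off, on, transform_kind: str = "lnp1", outcome: str = "") -> PairedTestResult:
    """Paired t-test of OFF vs ON on transformed values; raw-scale MD and means.

    Identical vectors give t = 0; non-zero constant differences on the
    transformed scale make t undefined and are returned flagged degenerate.
    """
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    if off.shape != on.shape or off.ndim != 1:
        raise ValueError("off and on must be equal-length 1-D paired vectors")
    n = off.size
    if n < 2:
        raise ValueError("paired test needs at least 2 pairs")
    toff, ton = transform(off, transform_kind), transform(on, transform_kind)
    d = toff - ton
    mean_off, mean_on = float(off.mean()), float(on.mean())
    md = float((off - on).mean())
    pct = float(100.0 * md / mean_off) if mean_off != 0 else np.nan
    se_off = float(off.std(ddof=1) / np.sqrt(n))
    se_on = float(on.std(ddof=1) / np.sqrt(n))
    degenerate = False
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(d.mean()) * np.inf, 0.0
            degenerate = True
    else:
        t, p = sst.ttest_rel(toff, ton)
    norm = normality_screen(d) if n >= 3 else None
    return PairedTestResult(
        outcome=outcome,
        n=n,
        mean_off=mean_off,
        mean_on=mean_on,
        se_off=se_off,
        se_on=se_on,
        md=md,
        percent_change=pct,
        t=float(t),
        df=n - 1,
        p=float(p),
        transform=transform_kind,
        degenerate=degenerate,
        normality=norm,
    )


def percent_change_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-subject percent change per outcome: 100·(ON-OFF)/OFF.

    Negative values indicate a reduction under stimulation.  Subjects with
    OFF = 0 get a missing value, not an infinity.
    """
    out = {"subject_id": cohort.df["subject_id"].to_numpy()}
    for etype, thr in OUTCOMES:
        stem = outcome_stem(etype, thr)
        for kind in ("count", "dur"):
            off = cohort.column(stem, kind, "off")
            on = cohort.column(stem, kind, "on")
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = 100.0 * (on - off) / off
            pct[off == 0] = np.nan
            out[f"{stem}_{kind}_pct"] = pct
    return pd.DataFrame(out)


def cohort_report(
    cohort: CohortTable, transform_kind: str = "lnp1", alpha: float = 0.05
) -> pd.DataFrame:
    """Full results table: one paired test per outcome (7 counts + 7 durations).

    Returns a DataFrame with raw-scale means ± SE per condition, MD, percent
    change, and t/df/p from the transformed-scale paired t-test, plus the
    normality screen of the transformed differences.  The frame's ``attrs``
    carry alpha, the transform and a note that no multiplicity correction is
    applied.
    """
    rows = []
    for etype, thr in OUTCOMES:
        stem = outcome_stem(etype, thr)
        for kind, unit in (("count", "episodes"), ("dur", "s")):
            name = f"{stem}_{kind}"
            res = paired_test(
                cohort.column(stem, kind, "off"),
                cohort.column(stem, kind, "on"),
                transform_kind,
                outcome=name,
            )
            rows.append(
                {
                    "outcome": name,
                    "unit": unit,
                    "n": res.n,
                    "mean_off": res.mean_off,
                    "se_off": res.se_off,
                    "mean_on": res.mean_on,
                    "se_on": res.se_on,
                    "md": res.md,
                    "percent_change": res.percent_change,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "significant": res.p < alpha,
                    "shapiro_p": res.normality.shapiro_p if res.normality else np.nan,
                    "ks_p": res.normality.ks_p if res.normality else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["alpha"] = alpha
    table.attrs["transform"] = transform_kind
    table.attrs["note"] = (
        "Two-sided paired t-tests on transformed data; raw-scale means/SE/MD; "
        "no multiple-testing correction applied."
    )
    return table


def format_report(table: pd.DataFrame) -> str:
    """Human-readable Markdown rendering of a cohort report."""
    lines = [
        "# Paired stimulation ON vs OFF comparison",
        "",
        f"transform = {table.attrs.get('transform', '?')}, "
        f"alpha = {table.attrs.get('alpha', '?')}, n = {int(table['n'].iloc[0])}",
        "",
        "| outcome | OFF mean±SE | ON mean±SE | MD | %change | t | df | p |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, r in table.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(
            f"| {r['outcome']} | {r['mean_off']:.1f}±{r['se_off']:.1f} | "
            f"{r['mean_on']:.1f}±{r['se_on']:.1f} | {r['md']:.1f} | "
            f"{r['percent_change']:.0f}% | {r['t']:.3f} | {int(r['df'])} | "
            f"{r['p']:.3g}{star} |"
        )
    lines += ["", table.attrs.get("note", "")]
    return "\n".join(lines)
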
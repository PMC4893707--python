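"""Band-level summaries and repeated-measures statistics.

Maps are reduced to one number per animal x timepoint x hemisphere x measure:
the mean z value over the 6-8 Hz band (which carries most SWD power and
coherence), the ictal portion of the rescaled axis (time in [0, 1]) and the
three central electrodes of each 5-electrode row, expressed as percent of the
animal's own baseline.  These summaries feed a two-way repeated-measures
ANOVA with 'time' as between factor and 'cortical side' as within factor, and
per-timepoint post-hoc comparisons against baseline (Bonferroni by default,
Sidak available).  Interictal FFT band amplitudes are compared pre vs post
with a time x frequency-band repeated-measures ANOVA and per-band post-hocs.

Note on the design: declaring 'time' a between factor while the same animals
are measured at every timepoint is internally inconsistent; the as-stated
analysis treats each animal x timepoint cell as an independent subject unit.
A fully-within alternative (``mode='within'``) treats both factors as
repeated on the same animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal_io import Channel
from .spectral import TFMap

#: Conventional rodent-LFP band edges (Hz); 55-65 Hz omitted (mains notch).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 55.0),
    "high_gamma": (65.0, 120.0),
    "epsilon": (120.0, 600.0),
}


class MapRecord(NamedTuple):
    """One seizure map with its experimental coordinates."""

    animal: str
    timepoint: str
    side: str            # 'left' | 'right'
    measure: str         # 'power' | 'coherence'
    electrode: str       # label, or 'pair:A-B' for coherence
    map: TFMap


def central_electrodes(layout: Sequence[Channel], hemisphere: str) -> list[str]:
    """Labels of the middle 3 AP positions of a hemisphere's electrode row."""
    row = sorted((c for c in layout if c.hemisphere == hemisphere),
                 key=lambda c: -c.ap_mm)
    if len(row) < 3:
        raise ValueError(f"{hemisphere} row has {len(row)} electrodes; need >= 3")
    k = (len(row) - 3) // 2
    return [c.label for c in row[k: k + 3]]


def ictal_band_mean(m: TFMap, band: tuple[float, float]) -> float:
    """Mean map value over the band frequencies and the ictal rescaled bins."""
    if not m.rescaled:
        raise ValueError("map must be time-rescaled (unit seizure axis)")
    f = m.grid.freqs
    if band[0] < f[0] - 1e-9 or band[1] > f[-1] + 1e-9:
        raise ValueError(f"band {band} outside grid range ({f[0]}, {f[-1]}) Hz")
    fsel = (f >= band[0]) & (f <= band[1])
    tsel = (m.grid.times >= 0.0) & (m.grid.times <= 1.0)
    return float(m.values[np.ix_(tsel, fsel)].mean())


def band_summary(
    records: Sequence[MapRecord],
    layout: Sequence[Channel],
    band: tuple[float, float] = (6.0, 8.0),
    baseline_timepoint: str = "baseline",
    electrodes: str = "central-3",
) -> pd.DataFrame:
    """Tidy table: one row per animal x timepoint x side x measure.

    ``value`` is the mean over band, ictal bins, seizures and the selected
    electrodes; ``percent_baseline`` is value / the animal-side-measure
    baseline value x 100 (exactly 100 at baseline by construction).
    """
    if electrodes == "central-3":
        keep = {h: set(central_electrodes(layout, h)) for h in ("left", "right")}

        def admit(r: MapRecord) -> bool:
            names = r.electrode.removeprefix("pair:").split("-")
            return all(n in keep[r.side] for n in names)
    else:
        def admit(r: MapRecord) -> bool:
            return True

    rows: dict[tuple, list[float]] = {}
    for r in records:
        if not admit(r):
            continue
        key = (r.animal, r.timepoint, r.side, r.measure)
        rows.setdefault(key, []).append(ictal_band_mean(r.map, band))
    df = pd.DataFrame(
        [(a, tp, s, me, float(np.mean(v))) for (a, tp, s, me), v in rows.items()],
        columns=["animal", "timepoint", "side", "measure", "value"],
    )
    base = df[df.timepoint == baseline_timepoint].set_index(["animal", "side", "measure"]).value
    if base.empty:
        raise ValueError(f"no rows at baseline timepoint {baseline_timepoint!r}")
    df["percent_baseline"] = [
        100.0 * v / base[(a, s, me)]
        for a, s, me, v in zip(df.animal, df.side, df.measure, df.value)
    ]
    return df.sort_values(["measure", "animal", "timepoint", "side"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Balanced mixed-design two-way repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _f_p(ss_num: float, df_num: int, ss_den: float, df_den: int) -> tuple[float, float]:
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom (single subject per cell?)")
    ms_den = ss_den / df_den
    ms_num = ss_num / df_num
    if ms_den <= 0:
        if ms_num <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = ms_num / ms_den
    return f, float(stats.f.sf(f, df_num, df_den))


def rm_anova_2way(
    df: pd.DataFrame,
    dv: str = "percent_baseline",
    between: str = "timepoint",
    within: str = "side",
    subject: str = "animal",
    mode: str = "as-stated",
) -> pd.DataFrame:
    """Two-way ANOVA with a between-subject and a within-subject factor.

    Requires a complete balanced design (every subject at every level of the
    within factor, equal subject counts per between level).  ``mode``:

    * ``'as-stated'`` — between factor as declared; when the same subjects
      appear at several between levels, each subject x between-level cell is
      treated as an independent pseudo-subject.
    * ``'within'`` — both factors repeated on the same subjects (two-way
      fully-within ANOVA with subject x factor interaction error terms).

    Returns an ANOVA table with SS, df, F and p per effect.
    """
    data = df[[subject, between, within, dv]].copy()
    data.columns = ["subject", "A", "B", "y"]
    cells = data.groupby(["subject", "A", "B"], sort=False).size()
    if (cells != 1).any():
        raise ValueError("duplicated subject x cell observations; aggregate first")
    a_levels = list(dict.fromkeys(data.A))
    b_levels = list(dict.fromkeys(data.B))
    missing = [
        (s, a, b)
        for (s, a) in data.groupby(["subject", "A"], sort=False).size().index
        for b in b_levels
        if (s, a, b) not in cells.index
    ]
    if missing:
        raise ValueError(f"incomplete design; missing cells: {missing[:5]}")

    if mode == "within":
        return _anova_two_way_within(data, a_levels, b_levels)
    if mode != "as-stated":
        raise ValueError("mode must be 'as-stated' or 'within'")

    data["unit"] = data.subject.astype(str) + "|" + data.A.astype(str)
    per_a = data.groupby("A").unit.nunique()
    if per_a.nunique() != 1:
        raise ValueError(f"unbalanced between-factor design: units per level {dict(per_a)}")
    n = int(per_a.iloc[0])
    a, b = len(a_levels), len(b_levels)

    y = data.y.to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    mean_a = data.groupby("A").y.mean()
    mean_b = data.groupby("B").y.mean()
    mean_ab = data.groupby(["A", "B"]).y.mean()
    mean_unit = data.groupby("unit").y.mean()
    unit_a = data.drop_duplicates("unit").set_index("unit").A

    ss_a = n * b * float(((mean_a - grand) ** 2).sum())
    ss_b = n * a * float(((mean_b - grand) ** 2).sum())
    ss_ab = n * float(
        sum(
            (mean_ab[(ai, bi)] - mean_a[ai] - mean_b[bi] + grand) ** 2
            for ai, bi in product(a_levels, b_levels)
        )
    )
    ss_subj = b * float(
        sum((mean_unit[u] - mean_a[unit_a[u]]) ** 2 for u in mean_unit.index)
    )
    ss_err = ss_total - ss_a - ss_b - ss_ab - ss_subj

    df_a, df_b = a - 1, b - 1
    df_subj = a * (n - 1)
    df_ab = df_a * df_b
    df_err = df_subj * df_b
    rows = []
    for name, ss, dfn, ss_den, dfd in [
        (between, ss_a, df_a, ss_subj, df_subj),
        (within, ss_b, df_b, ss_err, df_err),
        (f"{between} x {within}", ss_ab, df_ab, ss_err, df_err),
    ]:
        f, p = _f_p(ss, dfn, ss_den, dfd)
        rows.append((name, ss, dfn, f, p))
    rows.append(("subjects", ss_subj, df_subj, np.nan, np.nan))
    rows.append(("error", max(ss_err, 0.0), df_err, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["effect", "SS", "df", "F", "p"])


def _anova_two_way_within(data: pd.DataFrame, a_levels: list, b_levels: list) -> pd.DataFrame:
    subjects = list(dict.fromkeys(data.subject))
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if n < 2:
        raise ValueError("within-mode ANOVA needs >= 2 subjects")
    y = (data.set_index(["subject", "A", "B"]).y
         .reindex(pd.MultiIndex.from_product([subjects, a_levels, b_levels]))
         .to_numpy().reshape(n, a, b))
    grand = y.mean()
    m_s = y.mean(axis=(1, 2)); m_a = y.mean(axis=(0, 2)); m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2); m_sb = y.mean(axis=1); m_ab = y.mean(axis=0)
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_s = a * b * ((m_s - grand) ** 2).sum()
    ss_res = ((y - grand) ** 2).sum() - ss_a - ss_b - ss_ab - ss_sa - ss_sb - ss_s
    rows = []
    for name, ss, dfn, ss_den, dfd in [
        ("A", ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        ("B", ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        ("A x B", ss_ab, (a - 1) * (b - 1), ss_res, (n - 1) * (a - 1) * (b - 1)),
    ]:
        f, p = _f_p(ss, dfn, ss_den, dfd)
        rows.append((name, ss, dfn, f, p))
    return pd.DataFrame(rows, columns=["effect", "SS", "df", "F", "p"])


# ---------------------------------------------------------------------------
# Post-hoc comparisons
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def _adjust(p_unc: np.ndarray, m: int, correction: str) -> np.ndarray:
    if correction == "bonferroni":
        return np.minimum(p_unc * m, 1.0)
    if correction == "sidak":
        return 1.0 - (1.0 - p_unc) ** m
    raise ValueError("correction must be 'bonferroni' or 'sidak'")


def posthoc_vs_baseline(
    df: pd.DataFrame,
    dv: str = "percent_baseline",
    baseline_timepoint: str = "baseline",
    correction: str = "bonferroni",
    paired: bool = True,
) -> pd.DataFrame:
    """Per side, compare every post-baseline timepoint against baseline.

    Paired t across animals by default (same animals at every timepoint);
    corrected over the whole comparison family (sides x timepoints).
    """
    sides = list(dict.fromkeys(df.side))
    times = [t for t in dict.fromkeys(df.timepoint) if t != baseline_timepoint]
    rows = []
    for s, tp in product(sides, times):
        base = df[(df.side == s) & (df.timepoint == baseline_timepoint)].set_index("animal")[dv]
        post = df[(df.side == s) & (df.timepoint == tp)].set_index("animal")[dv]
        common = base.index.intersection(post.index)
        x, y = post[common].to_numpy(), base[common].to_numpy()
        if paired:
            d = x - y
            if np.allclose(d.std(ddof=1), 0.0):
                t, p = (0.0, 1.0) if np.allclose(d.mean(), 0) else (np.inf, 0.0)
            else:
                t, p = stats.ttest_rel(x, y)
        else:
            t, p = stats.ttest_ind(x, y)
        rows.append((s, tp, float(np.mean(x) - np.mean(y)), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["side", "timepoint", "mean_diff", "t", "p_unc"])
    out["p_adj"] = _adjust(out.p_unc.to_numpy(), len(out), correction)
    out["sig"] = [_stars(p) for p in out.p_adj]
    return out


def interictal_band_stats(
    amplitudes: pd.DataFrame,
    correction: str = "bonferroni",
    mode: str = "as-stated",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time x frequency-band repeated-measures ANOVA on interictal amplitudes.

    ``amplitudes``: tidy frame with columns animal, condition ('pre'/'post'),
    band, amplitude; per-animal band sets must match between conditions.
    Returns (ANOVA table, per-band post-hoc table with corrected p values).
    """
    req = {"animal", "condition", "band", "amplitude"}
    if not req <= set(amplitudes.columns):
        raise ValueError(f"amplitudes must have columns {sorted(req)}")
    if amplitudes.animal.nunique() < 2:
        raise ValueError("need >= 2 animals for a repeated-measures analysis")
    by_cond = {c: set(g.band) for c, g in amplitudes.groupby("condition")}
    band_sets = list(by_cond.values())
    if any(s != band_sets[0] for s in band_sets):
        raise ValueError(f"band sets differ between conditions: {by_cond}")
    table = rm_anova_2way(amplitudes, dv="amplitude", between="condition",
                          within="band", subject="animal", mode=mode)
    bands = list(dict.fromkeys(amplitudes.band))
    rows = []
    for bnd in bands:
        sub = amplitudes[amplitudes.band == bnd]
        pre = sub[sub.condition == "pre"].set_index("animal").amplitude
        post = sub[sub.condition == "post"].set_index("animal").amplitude
        common = pre.index.intersection(post.index)
        d = post[common].to_numpy() - pre[common].to_numpy()
        if np.allclose(d.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(d.mean(), 0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(post[common], pre[common])
        rows.append((bnd, float(np.mean(d)), float(t), float(p)))
    post_hoc = pd.DataFrame(rows, columns=["band", "mean_diff", "t", "p_unc"])
    post_hoc["p_adj"] = _adjust(post_hoc.p_unc.to_numpy(), len(post_hoc), correction)
    post_hoc["sig"] = [_stars(p) for p in post_hoc.p_adj]
    return table, post_hoc
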
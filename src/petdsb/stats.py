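"""Analysis of gammaH2AX foci-count tables.

Implements the study's evaluation chain: exclusion of cells with more than
five detected foci (automatic-scorer artifacts), binary damage rates
(percentage of cells with at least one focus, pooled over replicate
slides), within-volunteer excess rates against a pre-exposure benchmark,
the nonparametric test battery (Wilcoxon, Mann-Whitney, Kruskal-Wallis with
Dunn post hoc, Friedman with Tukey-type post hoc, Brown-Forsythe), and the
Monte Carlo power analysis behind the 10-per-arm design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import FOCI_CLASS_COLUMNS, StudyData

__all__ = [
    "MAX_FOCI_PER_CELL",
    "apply_filter",
    "damage_rate",
    "damage_rates_table",
    "mean_foci_per_cell",
    "excess_rates",
    "run_test_battery",
    "power_simulation",
    "min_n_for_power",
    "summarize_study",
]

#: Cells with more than this many foci are excluded from analysis.
MAX_FOCI_PER_CELL = 5

_CLASS_K = np.arange(6)


def apply_filter(foci_table: pd.DataFrame) -> pd.DataFrame:
    """Exclude cells with more than five detected foci.

    Removes the excluded cells from the scanned denominator and zeroes the
    exclusion column, so the operation is idempotent.  The input is not
    modified.
    """
    out = foci_table.copy()
    out["n_cells_scanned"] = out["n_cells_scanned"] - out["n_excluded_gt5"]
    out["n_excluded_gt5"] = 0
    return out


def _is_filtered(table: pd.DataFrame) -> bool:
    return bool((table["n_excluded_gt5"] == 0).all())


def damage_rate(
    filtered: pd.DataFrame,
    volunteer_id: str,
    sampling_point: str,
    incubation_min: int,
) -> dict:
    """Binary damage rate for one volunteer/condition.

    Cells are pooled across the replicate slides of the condition before
    the rate is computed, so every cell carries equal weight.
    Returns a record dict with the retained-cell and with-focus counts and
    the rate in percent.
    """
    sel = filtered[
        (filtered["volunteer_id"] == volunteer_id)
        & (filtered["sampling_point"] == sampling_point)
        & (filtered["incubation_min"] == incubation_min)
    ]
    if sel.empty:
        raise ValueError(f"no slides for {volunteer_id} {sampling_point}/IT{incubation_min}")
    n_retained = int(sel[FOCI_CLASS_COLUMNS].to_numpy().sum())
    if n_retained == 0:
        raise ValueError("no retained cells; damage rate undefined")
    n_with_focus = int(sel[FOCI_CLASS_COLUMNS[1:]].to_numpy().sum())
    return {
        "volunteer_id": volunteer_id,
        "arm": sel["arm"].iloc[0],
        "sampling_point": sampling_point,
        "incubation_min": incubation_min,
        "n_cells_retained": n_retained,
        "n_cells_with_focus": n_with_focus,
        "rate_pct": 100.0 * n_with_focus / n_retained,
    }


def damage_rates_table(foci_table: pd.DataFrame) -> pd.DataFrame:
    """Damage rates for every (volunteer, condition) in the table.

    Applies the >5-foci filter first if the table still carries excluded
    cells.
    """
    filtered = foci_table if _is_filtered(foci_table) else apply_filter(foci_table)
    keys = filtered[["volunteer_id", "sampling_point", "incubation_min"]].drop_duplicates()
    records = [
        damage_rate(filtered, row.volunteer_id, row.sampling_point, int(row.incubation_min))
        for row in keys.itertuples()
    ]
    return pd.DataFrame(records)


def mean_foci_per_cell(filtered: pd.DataFrame | np.ndarray) -> float:
    """Mean foci per retained cell, sum(k * n_k)/sum(n_k) over k = 0..5.

    Accepts a (possibly unfiltered) foci table or a bare length-6 (or 7,
    with a trailing >5 class that is ignored) vector of class counts.
    """
    if isinstance(filtered, pd.DataFrame):
        counts = filtered[FOCI_CLASS_COLUMNS].to_numpy(dtype=float).sum(axis=0)
    else:
        counts = np.asarray(filtered, dtype=float)[:6]
    total = counts.sum()
    if total <= 0:
        raise ValueError("no retained cells")
    return float((_CLASS_K * counts).sum() / total)


def excess_rates(
    rates: pd.DataFrame,
    post: tuple[str, int] = ("SP3", 60),
    pre: tuple[str, int] = ("SP1", 60),
) -> pd.DataFrame:
    """Within-volunteer excess rates: post- minus pre-exposure damage rate.

    ``relative_excess_pct`` is 100 * dR / pre-exposure rate (NaN when the
    benchmark rate is zero).  Volunteers missing either condition are
    returned in the ``skipped`` attribute-style column rather than silently
    dropped: they appear with ``skipped=True`` and NaN excesses.
    """
    def pick(sp_it: tuple[str, int]) -> pd.DataFrame:
        sp, it = sp_it
        sel = rates[(rates["sampling_point"] == sp) & (rates["incubation_min"] == it)]
        return sel.set_index("volunteer_id")

    post_r, pre_r = pick(post), pick(pre)
    rows = []
    for vid in rates["volunteer_id"].unique():
        row: dict = {
            "volunteer_id": vid,
            "arm": rates.loc[rates["volunteer_id"] == vid, "arm"].iloc[0],
            "contrast": f"{post[0]}/IT{post[1]} - {pre[0]}/IT{pre[1]}",
        }
        if vid in post_r.index and vid in pre_r.index:
            r_post = float(post_r.loc[vid, "rate_pct"])
            r_pre = float(pre_r.loc[vid, "rate_pct"])
            row.update(
                excess_pct=r_post - r_pre,
                relative_excess_pct=(100.0 * (r_post - r_pre) / r_pre) if r_pre > 0 else np.nan,
                benchmark_rate_pct=r_pre,
                skipped=False,
            )
        else:
            row.update(excess_pct=np.nan, relative_excess_pct=np.nan, benchmark_rate_pct=np.nan, skipped=True)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Test battery
# ---------------------------------------------------------------------------


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-sum post hoc after Kruskal-Wallis, with tie correction,
    two-sided normal p-values."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            out.append(
                {
                    "test": f"dunn[{a} vs {b}]",
                    "groups": f"{a},{b}",
                    "n": sizes[a] + sizes[b],
                    "statistic": z,
                    "p_value": 2.0 * sps.norm.sf(abs(z)),
                }
            )
    return out


def _friedman_tukey_posthoc(data: np.ndarray, labels: list[str]) -> list[dict]:
    """Tukey-type (Nemenyi) post hoc after Friedman: studentized-range
    p-values on within-block mean-rank differences."""
    n, k = data.shape
    ranks = sps.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * math.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, np.inf))
            out.append(
                {
                    "test": f"tukey[{labels[i]} vs {labels[j]}]",
                    "groups": f"{labels[i]},{labels[j]}",
                    "n": n,
                    "statistic": q,
                    "p_value": p,
                }
            )
    return out


def _record(test: str, groups: str, n: int, statistic: float, p: float, alpha: float) -> dict:
    return {
        "test": test,
        "groups": groups,
        "n": n,
        "statistic": statistic,
        "p_value": p,
        "significant": bool(p < alpha) if np.isfinite(p) else False,
    }


def _not_computable(test: str, groups: str, n: int) -> dict:
    return {"test": test, "groups": groups, "n": n, "statistic": np.nan, "p_value": np.nan, "significant": False}


def run_test_battery(rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """The study's nonparametric test battery on a damage-rates table.

    All tests are two-sided at the given alpha.  Rows report the statistic,
    p-value and per-test sample size; post hoc rows are appended when the
    omnibus test is significant.  Tests whose group sizes are insufficient
    are reported as not computable (NaN) rather than dropped.
    """
    results: list[dict] = []

    def rates_of(arm_list, sp, it) -> pd.DataFrame:
        sel = rates[
            rates["arm"].isin(arm_list)
            & (rates["sampling_point"] == sp)
            & (rates["incubation_min"] == it)
        ]
        return sel.set_index("volunteer_id")["rate_pct"]

    # --- incubation effect: SP1/IT0 vs SP1/IT60, all arms pooled, paired
    all_arms = ["SA1", "SA2", "SA3"]
    r0, r60 = rates_of(all_arms, "SP1", 0), rates_of(all_arms, "SP1", 60)
    common = r0.index.intersection(r60.index)
    if len(common) >= 6:
        st, p = sps.wilcoxon(r0.loc[common], r60.loc[common], zero_method="wilcox")
        results.append(_record("wilcoxon[SP1/IT0 vs SP1/IT60, pooled]", "all arms", len(common), float(st), float(p), alpha))
        bf_st, bf_p = sps.levene(r0.loc[common], r60.loc[common], center="median")
        results.append(_record("brown_forsythe[SP1/IT0 vs SP1/IT60]", "all arms", 2 * len(common), float(bf_st), float(bf_p), alpha))
    else:
        results.append(_not_computable("wilcoxon[SP1/IT0 vs SP1/IT60, pooled]", "all arms", len(common)))

    # --- per-arm exposure effect: SP3/IT60 vs SP1/IT60, paired Wilcoxon
    excess_by_arm: dict[str, np.ndarray] = {}
    for arm in all_arms:
        pre, post = rates_of([arm], "SP1", 60), rates_of([arm], "SP3", 60)
        common = pre.index.intersection(post.index)
        diffs = (post.loc[common] - pre.loc[common]).to_numpy()
        excess_by_arm[arm] = diffs
        if len(common) >= 6 and np.any(diffs != 0):
            st, p = sps.wilcoxon(diffs)
            results.append(_record(f"wilcoxon[SP3/IT60 vs SP1/IT60, {arm}]", arm, len(common), float(st), float(p), alpha))
        else:
            results.append(_not_computable(f"wilcoxon[SP3/IT60 vs SP1/IT60, {arm}]", arm, len(common)))

    # --- synergy: Mann-Whitney on excess rates, SA1 vs SA3
    if excess_by_arm["SA1"].size >= 2 and excess_by_arm["SA3"].size >= 2:
        st, p = sps.mannwhitneyu(excess_by_arm["SA1"], excess_by_arm["SA3"], alternative="two-sided")
        results.append(
            _record("mannwhitney[excess SA1 vs SA3]", "SA1,SA3", excess_by_arm["SA1"].size + excess_by_arm["SA3"].size, float(st), float(p), alpha)
        )

    # --- across arms: Kruskal-Wallis on excess rates, Dunn post hoc
    groups = {a: v for a, v in excess_by_arm.items() if v.size >= 2}
    if len(groups) == 3:
        st, p = sps.kruskal(*groups.values())
        kw = _record("kruskal_wallis[excess by arm]", ",".join(groups), sum(v.size for v in groups.values()), float(st), float(p), alpha)
        results.append(kw)
        if kw["significant"]:
            for row in _dunn_posthoc(groups):
                results.append(_record(row["test"], row["groups"], row["n"], row["statistic"], row["p_value"], alpha))

    # --- incubation series: Friedman across SP3 incubation times
    for arms, label in (( ["SA1", "SA3"], "SA1+SA3"), (["SA2"], "SA2")):
        its = [0, 15, 30, 45, 60]
        series = [rates_of(arms, "SP3", it) for it in its]
        common = series[0].index
        for s in series[1:]:
            common = common.intersection(s.index)
        if len(common) >= 3:
            mat = np.column_stack([s.loc[common].to_numpy() for s in series])
            st, p = sps.friedmanchisquare(*mat.T)
            fr = _record(f"friedman[SP3 over IT, {label}]", label, len(common), float(st), float(p), alpha)
            results.append(fr)
            if fr["significant"]:
                for row in _friedman_tukey_posthoc(mat, [f"IT{it}" for it in its]):
                    results.append(_record(row["test"], row["groups"], row["n"], row["statistic"], row["p_value"], alpha))
        else:
            results.append(_not_computable(f"friedman[SP3 over IT, {label}]", label, len(common)))

    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# Design power
# ---------------------------------------------------------------------------


def _kruskal_wallis_h(data: np.ndarray) -> np.ndarray:
    """Vectorised Kruskal-Wallis H over axis 1 for shape (reps, k, n)
    continuous data (no tie correction; inputs are continuous draws)."""
    reps, k, n = data.shape
    flat = data.reshape(reps, k * n)
    order = np.argsort(flat, axis=1)
    ranks = np.empty_like(flat)
    rows = np.arange(reps)[:, None]
    ranks[rows, order] = np.arange(1, k * n + 1)
    rank_sums = ranks.reshape(reps, k, n).sum(axis=2)
    n_total = k * n
    return 12.0 / (n_total * (n_total + 1)) * (rank_sums**2 / n).sum(axis=1) - 3 * (n_total + 1)


def power_simulation(
    n_per_arm: int,
    effect_sd_multiple: float = 1.5,
    alpha: float = 0.05,
    n_reps: int = 5000,
    seed: int | None = 0,
    effect_on_variance_scale: bool = False,
) -> tuple[float, float]:
    """Monte Carlo power of the three-arm Kruskal-Wallis design.

    Each replicate draws three arms of ``n_per_arm`` standard-normal
    values, shifts one arm by ``effect_sd_multiple`` within-arm SDs (or by
    sqrt(effect_sd_multiple) SDs under the literal variance reading when
    ``effect_on_variance_scale``), and applies the two-sided Kruskal-Wallis
    test at ``alpha``.  Returns (power, binomial standard error).
    """
    if n_per_arm < 2:
        raise ValueError("need at least 2 per arm")
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    shift = math.sqrt(effect_sd_multiple) if effect_on_variance_scale else effect_sd_multiple
    rng = np.random.default_rng(seed)
    crit = sps.chi2.isf(alpha, df=2)
    reject = 0
    batch = max(1, min(n_reps, int(2e6 / (3 * n_per_arm))))
    done = 0
    while done < n_reps:
        m = min(batch, n_reps - done)
        data = rng.standard_normal((m, 3, n_per_arm))
        data[:, 0, :] += shift
        h = _kruskal_wallis_h(data)
        reject += int((h > crit).sum())
        done += m
    power = reject / n_reps
    se = math.sqrt(max(power * (1 - power), 1e-12) / n_reps)
    return power, se


def min_n_for_power(
    target_power: float,
    effect_sd_multiple: float = 1.5,
    alpha: float = 0.05,
    n_reps: int = 5000,
    seed: int | None = 0,
    n_max: int = 200,
    effect_on_variance_scale: bool = False,
) -> int:
    """Smallest per-arm n whose simulated power reaches ``target_power``."""
    if not 0 < target_power < 1:
        raise ValueError("target power must be in (0, 1)")
    for n in range(2, n_max + 1):
        power, _ = power_simulation(
            n, effect_sd_multiple, alpha, n_reps, seed, effect_on_variance_scale
        )
        if power >= target_power:
            return n
    raise RuntimeError(f"target power not reached by n = {n_max}")


# ---------------------------------------------------------------------------
# Study-level summary
# ---------------------------------------------------------------------------


def summarize_study(study: StudyData, alpha: float = 0.05) -> dict:
    """Filter, rates, excess rates and tests for a full study; returns a
    dict of the headline quantities plus the intermediate tables."""
    filtered = apply_filter(study.foci)
    rates = damage_rates_table(filtered)
    excess = excess_rates(rates)
    tests = run_test_battery(rates, alpha=alpha)

    bg = rates[(rates["sampling_point"] == "SP1") & (rates["incubation_min"] == 60)]["rate_pct"]
    fdg = excess[excess["arm"].isin(["SA1", "SA3"]) & ~excess["skipped"]]
    doses60 = [
        r.D_total_mGy[60] for r in study.dose_reports.values() if r.D_invivo_mGy > 0
    ]
    invitro_pct = [
        100.0 * r.D_invitro_mGy[60] / r.D_invivo_mGy
        for r in study.dose_reports.values()
        if r.D_invivo_mGy > 0
    ]
    summary = {
        "n_volunteers": len(study.volunteers),
        "n_cells_scanned": int(study.foci["n_cells_scanned"].sum()),
        "mean_foci_per_cell": mean_foci_per_cell(filtered),
        "median_background_rate_pct": float(np.median(bg)) if len(bg) else np.nan,
        "median_excess_pct": float(np.nanmedian(fdg["excess_pct"])) if len(fdg) else np.nan,
        "median_relative_excess_pct": float(np.nanmedian(fdg["relative_excess_pct"])) if len(fdg) else np.nan,
        "median_total_dose_60_mGy": float(np.median(doses60)) if doses60 else np.nan,
        "mean_invitro_to_invivo_pct": float(np.mean(invitro_pct)) if invitro_pct else np.nan,
    }
    return {"summary": summary, "rates": rates, "excess": excess, "tests": tests}
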
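"""Individual-differences pipeline for decision surveys.

Given binary scenario decisions, Likert trait-scale responses and
demographics for one cohort, this module applies the exclusion rules
(attention check first, then a +/-3 SD completion-latency trim), scores the
scales (un-flipping reverse-keyed items), dissociates each participant's
(AT, ET, OP, AC) from their cell acceptance rates, and runs the standard
battery of association tests: Pearson correlations among traits, parameters
and age; pooled-variance t tests with Cohen's d for the two demographic
splits; Cronbach's alpha per scale; and the Harman single-factor check for
common-method variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import participant_parameters
from .errors import ValidationError, ZeroVarianceError
from .validation import significance_stars

__all__ = [
    "ScaleSpec",
    "FS_SPEC",
    "DDI_SPEC",
    "StatResult",
    "apply_exclusions",
    "score_scale",
    "reverse_code",
    "item_matrix",
    "cronbach_alpha",
    "correlation_matrix",
    "tidy_correlations",
    "group_compare",
    "harman_single_factor",
    "Study2Config",
    "Study2Result",
    "run_study2",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Scoring rules for one Likert scale.

    ``reverse_items`` are stored flipped in the data and are recoded as
    6 - value before summation.  ``scored_subset`` restricts the sum to a
    subset of items (e.g. a psychometrically retained short form); by default
    all items are scored.
    """

    scale_id: str
    item_ids: tuple
    reverse_items: tuple = ()
    response_range: tuple = (1, 5)
    scored_subset: tuple | None = None

    def __post_init__(self):
        if not set(self.reverse_items) <= set(self.item_ids):
            raise ValidationError(
                f"scale {self.scale_id}: reverse_items not a subset of item_ids"
            )
        if self.scored_subset is not None and not (
            set(self.scored_subset) <= set(self.item_ids)
        ):
            raise ValidationError(
                f"scale {self.scale_id}: scored_subset not a subset of item_ids"
            )

    @property
    def scored_items(self) -> tuple:
        return self.scored_subset if self.scored_subset is not None else self.item_ids


def _items(scale_id: str, n: int) -> tuple:
    return tuple(f"{scale_id}_{i}" for i in range(1, n + 1))


#: Social isolation (6 items, 3 reverse-keyed; higher = more isolated).
FS_SPEC = ScaleSpec("fs", _items("fs", 6), reverse_items=("fs_2", "fs_4", "fs_6"))
#: Distress disclosure (12 items, 6 reverse-keyed; higher = more disclosing).
DDI_SPEC = ScaleSpec(
    "ddi", _items("ddi", 12),
    reverse_items=("ddi_2", "ddi_4", "ddi_6", "ddi_8", "ddi_10", "ddi_12"),
)


@dataclass(frozen=True)
class StatResult:
    """One inferential result (correlation or group comparison)."""

    name: str
    estimate: float
    p_value: float
    effect_size: float | None = None
    n: tuple | int | None = None

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


def apply_exclusions(demographics: pd.DataFrame) -> tuple[pd.Index, pd.DataFrame]:
    """Drop attention-check failures, then +/-3 SD completion-latency outliers.

    The latency mean and SD are computed on the sample remaining *after* the
    attention-check exclusion, in a single pass (no iterative re-trimming);
    participants strictly outside mean +/- 3*SD on either side are dropped.
    A participant at exactly the boundary is retained.

    Returns (index of retained participant_ids, exclusion log with columns
    participant_id, reason).
    """
    required = {"participant_id", "imc_pass", "total_latency_s"}
    if not required <= set(demographics.columns):
        raise ValidationError(f"demographics need columns {sorted(required)}")
    df = demographics.set_index("participant_id")
    log = []

    failed = df.index[~df["imc_pass"].astype(bool)]
    log.extend({"participant_id": p, "reason": "imc_failure"} for p in failed)
    df = df.loc[df["imc_pass"].astype(bool)]

    latency = df["total_latency_s"]
    if latency.isna().any():
        missing = list(latency.index[latency.isna()][:5])
        raise ValidationError(f"missing total latency for participants {missing}")
    mean, sd = latency.mean(), latency.std(ddof=1)
    if len(df) > 1 and sd > 0:
        outside = (latency - mean).abs() > 3 * sd
    else:
        outside = pd.Series(False, index=df.index)
    log.extend(
        {"participant_id": p, "reason": "latency_outlier"}
        for p in df.index[outside]
    )
    retained = df.index[~outside]
    return retained, pd.DataFrame(log, columns=["participant_id", "reason"])


def reverse_code(values, low: int = 1, high: int = 5):
    """Recode a reverse-keyed Likert response: x -> (low + high) - x."""
    return (low + high) - np.asarray(values)


def item_matrix(scales: pd.DataFrame, spec: ScaleSpec, recode: bool = True,
                strict: bool = True) -> pd.DataFrame:
    """Participant x item matrix for one scale from the long scales table.

    With ``recode`` the reverse-keyed items are un-flipped so that all
    columns point in the scale's direction (required before reliability).
    With ``strict`` a participant with any missing item raises; otherwise
    incomplete participants are silently dropped.
    """
    required = {"participant_id", "item_id", "value"}
    if not required <= set(scales.columns):
        raise ValidationError(f"scales need columns {sorted(required)}")
    sub = scales[scales["item_id"].isin(spec.item_ids)]
    lo, hi = spec.response_range
    bad = sub[(sub["value"] < lo) | (sub["value"] > hi) | sub["value"].isna()]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(
            f"scale {spec.scale_id}: out-of-range value {r['value']!r} for "
            f"participant {r['participant_id']!r}, item {r['item_id']!r}"
        )
    wide = sub.pivot_table(index="participant_id", columns="item_id",
                           values="value", aggfunc="first")
    missing_cols = [i for i in spec.item_ids if i not in wide.columns]
    if missing_cols and strict:
        raise ValidationError(
            f"scale {spec.scale_id}: items never observed: {missing_cols}"
        )
    wide = wide.reindex(columns=list(spec.item_ids))
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        if strict:
            pid = wide.index[incomplete][0]
            item = wide.columns[wide.loc[pid].isna()][0]
            raise ValidationError(
                f"scale {spec.scale_id}: participant {pid!r} missing item {item!r}"
            )
        wide = wide.loc[~incomplete]
    if recode:
        for item in spec.reverse_items:
            wide[item] = reverse_code(wide[item], lo, hi)
    return wide.astype(float)


def score_scale(scales: pd.DataFrame, spec: ScaleSpec, strict: bool = True
                ) -> pd.Series:
    """Summed scale score per participant (reverse items recoded first)."""
    wide = item_matrix(scales, spec, recode=True, strict=strict)
    return wide[list(spec.scored_items)].sum(axis=1).rename(spec.scale_id)


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha of a participant x item matrix (reverse-coding done).

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    all variances with denominator n-1.
    """
    items = pd.DataFrame(items).dropna()
    k = items.shape[1]
    if k < 2 or len(items) < 3:
        raise ValidationError("alpha needs >= 2 items and >= 3 respondents")
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroVarianceError("total score has zero variance; alpha undefined")
    item_var = items.var(ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValidationError("need >= 3 complete cases per pair")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def correlation_matrix(df: pd.DataFrame):
    """Pairwise-complete Pearson correlations with two-tailed p values.

    Returns (r, p, n) DataFrames indexed by the input columns.  A constant
    column yields NaN entries and a warning (the correlation is undefined).
    """
    cols = list(df.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(df), dtype=int)
    constant = [c for c in cols if df[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s) {constant}: correlations undefined")
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij, nij = _pearson_with_p(
                df[cols[i]].to_numpy(float), df[cols[j]].to_numpy(float)
            )
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    idx = pd.Index(cols)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


def tidy_correlations(r: pd.DataFrame, p: pd.DataFrame, n: pd.DataFrame
                      ) -> pd.DataFrame:
    """Lower-triangle pairs of a correlation matrix as tidy StatResult rows."""
    rows = []
    cols = list(r.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rows.append(
                {
                    "var1": a, "var2": b,
                    "r": r.loc[a, b], "p_value": p.loc[a, b],
                    "n": int(n.loc[a, b]),
                    "stars": significance_stars(p.loc[a, b])
                    if not np.isnan(p.loc[a, b]) else "",
                }
            )
    return pd.DataFrame(rows)


def group_compare(values, labels, group_order: tuple[str, str]) -> StatResult:
    """Student's pooled-variance t test with Cohen's d for two groups.

    The sign convention is first group minus second (per ``group_order``);
    d = mean difference / pooled SD.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    labels = pd.Series(np.asarray(labels, dtype=object))
    g1, g2 = group_order
    a = values[labels.to_numpy() == g1].dropna()
    b = values[labels.to_numpy() == g2].dropna()
    extra = set(labels.unique()) - {g1, g2}
    if extra:
        raise ValidationError(f"unexpected group labels {sorted(map(str, extra))}")
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"both groups need n >= 2 (got {g1}: {len(a)}, {g2}: {len(b)})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    pooled_var = (
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var) if pooled_var > 0 else np.nan
    return StatResult(
        name=f"{g1} vs {g2}",
        estimate=float(t),
        p_value=float(p),
        effect_size=float(d),
        n=(len(a), len(b)),
    )


def harman_single_factor(items: pd.DataFrame) -> tuple[float, int]:
    """Harman common-method check: share of variance of the first component.

    Columns are standardised internally; the statistic is the largest
    eigenvalue of the item correlation matrix divided by the number of items,
    as a percentage.  Also returns the count of eigenvalues exceeding 1.
    Constant columns are dropped (they carry no common variance).
    """
    items = pd.DataFrame(items).dropna()
    keep = items.columns[items.std(ddof=1) > 0]
    if len(keep) < 2:
        raise ValidationError("need >= 2 non-constant columns for the factor check")
    if len(keep) < items.shape[1]:
        warnings.warn(
            f"dropping {items.shape[1] - len(keep)} constant column(s) "
            "from the single-factor check"
        )
    z = (items[keep] - items[keep].mean()) / items[keep].std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals = np.linalg.eigvalsh(corr)[::-1]
    return float(100.0 * evals[0] / len(keep)), int((evals > 1).sum())


@dataclass
class Study2Config:
    """Options for the full individual-differences run."""

    scale_specs: tuple = (FS_SPEC, DDI_SPEC)
    #: variable name used in tables for each scale's summed score
    scale_variable_names: Mapping[str, str] = field(
        default_factory=lambda: {"fs": "si", "ddi": "dd"}
    )
    gender_order: tuple = ("male", "female")
    relationship_order: tuple = ("single", "non_single")
    harman_threshold: float = 40.0


@dataclass
class Study2Result:
    """Everything the individual-differences pipeline produces."""

    participants: pd.DataFrame
    exclusions: pd.DataFrame
    correlations: pd.DataFrame          # tidy pairs
    correlation_r: pd.DataFrame
    correlation_p: pd.DataFrame
    group_tests: pd.DataFrame
    alphas: dict
    harman_percent: float
    harman_n_factors_gt1: int
    harman_threshold: float

    def report(self) -> str:
        """Human-readable markdown summary of the run."""
        inc = self.participants[self.participants["included"]]
        lines = [
            "# Individual-differences analysis",
            "",
            f"Included {len(inc)} of {len(self.participants)} participants "
            f"({len(self.exclusions)} excluded).",
            "",
            "## Reliability",
            "",
        ]
        for scale, alpha in self.alphas.items():
            lines.append(f"- Cronbach's alpha ({scale}): {alpha:.2f}")
        lines += [
            "",
            "## Common-method check",
            "",
            f"First unrotated component explains {self.harman_percent:.2f}% of "
            f"total variance ({self.harman_n_factors_gt1} eigenvalues > 1); "
            f"threshold {self.harman_threshold:.0f}%.",
            "",
            "## Descriptives and correlations",
            "",
        ]
        variables = list(self.correlation_r.columns)
        lines.append("| variable | M +/- SD | " + " | ".join(variables) + " |")
        lines.append("|---" * (len(variables) + 2) + "|")
        for i, v in enumerate(variables):
            cells = []
            for j, w in enumerate(variables):
                if j > i:
                    cells.append("")
                elif j == i:
                    cells.append("1.00")
                else:
                    rv = self.correlation_r.loc[v, w]
                    pv = self.correlation_p.loc[v, w]
                    cells.append(f"{rv:.2f}{significance_stars(pv)}")
            m, s = inc[v].mean(), inc[v].std(ddof=1)
            lines.append(f"| {v} | {m:.2f} +/- {s:.2f} | " + " | ".join(cells) + " |")
        lines += ["", "## Group comparisons", ""]
        lines.append("| grouping | variable | t | p | Cohen's d |")
        lines.append("|---|---|---|---|---|")
        for row in self.group_tests.itertuples():
            lines.append(
                f"| {row.grouping} | {row.variable} | {row.t:.2f}"
                f"{significance_stars(row.p_value)} | {row.p_value:.3f} "
                f"| {row.d:.3f} |"
            )
        return "\n".join(lines)


def run_study2(
    decisions: pd.DataFrame,
    scales: pd.DataFrame,
    demographics: pd.DataFrame,
    config: Study2Config | None = None,
) -> Study2Result:
    """Run the whole individual-differences pipeline on one cohort.

    Steps: exclusions (attention check, then latency trim) -> per-participant
    CAN parameters from decisions -> scale scores -> correlation matrix over
    {si, dd, at, et, op, ac, age} -> gender and relationship-status t tests ->
    per-scale alpha -> Harman single-factor check.  A participant present in
    decisions but lacking complete scale responses is excluded with a logged
    reason.  Deterministic given the inputs.
    """
    config = config or Study2Config()
    retained, exclusion_log = apply_exclusions(demographics)
    logs = [exclusion_log]

    dec = decisions[decisions["participant_id"].isin(retained)]
    params = participant_parameters(dec)

    scale_scores = {}
    complete: pd.Index | None = None
    for spec in config.scale_specs:
        scores = score_scale(
            scales[scales["participant_id"].isin(retained)], spec, strict=False
        )
        name = config.scale_variable_names.get(spec.scale_id, spec.scale_id)
        scale_scores[name] = scores
        complete = scores.index if complete is None else complete.intersection(
            scores.index
        )

    analysable = params.index.intersection(complete if complete is not None
                                           else params.index)
    missing_scales = params.index.difference(analysable)
    if len(missing_scales):
        logs.append(
            pd.DataFrame(
                {"participant_id": missing_scales, "reason": "missing_scales"}
            )
        )
    exclusions = pd.concat(logs, ignore_index=True)

    demo = demographics.set_index("participant_id")
    table = params.loc[analysable, ["p1", "p2", "p3", "p4", "at", "et", "op", "ac",
                                    "n_trials_per_cell"]].copy()
    for name, scores in scale_scores.items():
        table[name] = scores.reindex(analysable)
    for col in ("age", "gender", "relationship_status"):
        table[col] = demo[col].reindex(analysable)

    participants = table.reset_index().rename(columns={"index": "participant_id"})
    participants["included"] = True
    excluded_rows = exclusions.assign(included=False).rename(
        columns={"reason": "exclusion_reason"}
    )
    participants = pd.concat(
        [participants.assign(exclusion_reason=""), excluded_rows],
        ignore_index=True,
    )

    variables = list(scale_scores.keys()) + ["at", "et", "op", "ac", "age"]
    numeric = table[variables].astype(float)
    r, p, n = correlation_matrix(numeric)
    tidy = tidy_correlations(r, p, n)

    test_vars = list(scale_scores.keys()) + ["at", "et", "op", "ac"]
    rows = []
    for grouping, column, order in (
        ("gender", "gender", config.gender_order),
        ("relationship_status", "relationship_status", config.relationship_order),
    ):
        for v in test_vars:
            res = group_compare(table[v], table[column], order)
            rows.append(
                {
                    "grouping": grouping,
                    "variable": v,
                    "group1": order[0],
                    "group2": order[1],
                    "mean1": table.loc[table[column] == order[0], v].mean(),
                    "mean2": table.loc[table[column] == order[1], v].mean(),
                    "t": res.estimate,
                    "p_value": res.p_value,
                    "d": res.effect_size,
                    "n1": res.n[0],
                    "n2": res.n[1],
                }
            )
    group_tests = pd.DataFrame(rows)

    alphas = {
        spec.scale_id: cronbach_alpha(
            item_matrix(
                scales[scales["participant_id"].isin(analysable)], spec,
                recode=True, strict=False,
            )
        )
        for spec in config.scale_specs
    }

    # Common-method check on the raw collected indicators: the 24 binary
    # decisions plus every scale item as stored (no reverse recoding).
    dec_items = dec[dec["participant_id"].isin(analysable)].pivot_table(
        index="participant_id", columns=["framework_id", "cell"], values="accept"
    )
    dec_items.columns = [f"{f}:{c}" for f, c in dec_items.columns]
    scale_items = scales[scales["participant_id"].isin(analysable)].pivot_table(
        index="participant_id", columns="item_id", values="value"
    )
    harman_pct, harman_gt1 = harman_single_factor(
        dec_items.join(scale_items, how="inner")
    )

    return Study2Result(
        participants=participants,
        exclusions=exclusions,
        correlations=tidy,
        correlation_r=r,
        correlation_p=p,
        group_tests=group_tests,
        alphas=alphas,
        harman_percent=harman_pct,
        harman_n_factors_gt1=harman_gt1,
        harman_threshold=config.harman_threshold,
    )
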
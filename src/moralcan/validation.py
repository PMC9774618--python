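"""Material validation for 2x2 everyday-dilemma batteries.

Before a scene framework can be used to dissociate decision tendencies, the
design must be *construally valid*: readers must perceive each of its four
versions as occupying the intended cell (benefits self / benefits others).
Validation asks raters to classify each scenario's outcome as

    A  good for yourself, bad for others      (egoistic, non-altruistic)
    B  good for others, bad for yourself      (non-egoistic, altruistic)
    C  good for both                          (egoistic, altruistic)
    D  bad for both                           (non-egoistic, non-altruistic)

codes agreement with the designed cell as 1/0, tests each scenario's
agreement rate against chance (50%) with a one-df goodness-of-fit chi-square,
and retains a framework only when all four of its versions are judged
consistent above chance at least marginally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from scipy import stats

from .core import CELL_ORDER, DilemmaCell
from .errors import ValidationError

__all__ = [
    "OPTION_FOR_CELL",
    "CELL_FOR_OPTION",
    "code_consistency",
    "chi_square_consistency",
    "CellValidation",
    "RetentionDecision",
    "cell_validations",
    "cell_validations_from_counts",
    "screen_frameworks",
    "summarize_validation",
    "ValidationReport",
    "significance_stars",
]

#: The designed judgment option for each cell.
OPTION_FOR_CELL: Mapping[DilemmaCell, str] = {
    DilemmaCell.EGO_NONALT: "A",     # good for self, bad for others
    DilemmaCell.EGO_ALT: "C",        # good for both
    DilemmaCell.NONEGO_ALT: "B",     # good for others, bad for self
    DilemmaCell.NONEGO_NONALT: "D",  # bad for both
}

CELL_FOR_OPTION: Mapping[str, DilemmaCell] = {v: k for k, v in OPTION_FOR_CELL.items()}

_VALID_OPTIONS = frozenset("ABCD")


def code_consistency(cell: Union[DilemmaCell, str], option: str) -> int:
    """1 if the rater's option matches the cell the scenario was designed for.

    Exactly 4 of the 16 (cell, option) pairs code 1.
    """
    cell = DilemmaCell.coerce(cell)
    option = str(option).strip().upper()
    if option not in _VALID_OPTIONS:
        raise ValidationError(f"judgment option must be one of A-D, got {option!r}")
    return int(OPTION_FOR_CELL[cell] == option)


def chi_square_consistency(n_consistent: int, n_total: int):
    """One-df goodness-of-fit test of a consistency count against 50/50.

    Uses the uncorrected closed form chi2 = (2*n_consistent - n_total)^2 /
    n_total with a two-sided p from the chi-square(1) distribution.

    Returns
    -------
    (chi2, p_value, direction) with direction one of ``above_chance``,
    ``below_chance``, ``at_chance``.
    """
    n_consistent, n_total = int(n_consistent), int(n_total)
    if n_total < 1:
        raise ValidationError("n_total must be at least 1")
    if not 0 <= n_consistent <= n_total:
        raise ValidationError(
            f"n_consistent = {n_consistent} outside [0, {n_total}]"
        )
    chi2 = (2 * n_consistent - n_total) ** 2 / n_total
    p = float(stats.chi2.sf(chi2, df=1))
    if 2 * n_consistent > n_total:
        direction = "above_chance"
    elif 2 * n_consistent < n_total:
        direction = "below_chance"
    else:
        direction = "at_chance"
    return float(chi2), p, direction


def significance_stars(p: float) -> str:
    """Conventional two-tailed star legend: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CellValidation:
    """Chi-square screening result for one scenario (framework x cell)."""

    framework_id: str
    cell: DilemmaCell
    n_consistent: int
    n_total: int
    proportion: float
    chi2: float
    p_value: float
    direction: str


@dataclass(frozen=True)
class RetentionDecision:
    """Whether a framework survives the all-four-cells-above-chance rule."""

    framework_id: str
    retained: bool
    failing_cells: tuple[DilemmaCell, ...]
    reason: str  # "rule" or "exception"


def _validation_from_count(framework_id, cell, n_consistent, n_total) -> CellValidation:
    chi2, p, direction = chi_square_consistency(n_consistent, n_total)
    return CellValidation(
        framework_id=str(framework_id),
        cell=DilemmaCell.coerce(cell),
        n_consistent=int(n_consistent),
        n_total=int(n_total),
        proportion=n_consistent / n_total,
        chi2=chi2,
        p_value=p,
        direction=direction,
    )


def cell_validations(judgments: pd.DataFrame, imc_flags: pd.Series | None = None
                     ) -> list[CellValidation]:
    """Code and test every scenario in a long judgments table.

    Parameters
    ----------
    judgments
        Columns ``participant_id``, ``framework_id``, ``cell``, ``option``.
    imc_flags
        Optional boolean Series indexed by participant_id; participants whose
        flag is False (failed the instructional manipulation check) are
        dropped before coding.
    """
    required = {"participant_id", "framework_id", "cell", "option"}
    if not required <= set(judgments.columns):
        raise ValidationError(f"judgments need columns {sorted(required)}")
    df = judgments
    if imc_flags is not None:
        passed = imc_flags.reindex(df["participant_id"]).fillna(False).to_numpy(bool)
        df = df.loc[passed]
    consistent = [
        code_consistency(c, o) for c, o in zip(df["cell"], df["option"])
    ]
    df = df.assign(consistent=consistent)
    grouped = df.groupby(["framework_id", df["cell"].map(DilemmaCell.coerce)],
                         sort=True, observed=True)["consistent"]
    return [
        _validation_from_count(fw, cell, int(g.sum()), int(g.size))
        for (fw, cell), g in grouped
    ]


def cell_validations_from_counts(counts: pd.DataFrame) -> list[CellValidation]:
    """Screening results from a pre-aggregated count table.

    ``counts`` has columns framework_id, cell, n_consistent, n_total — the
    format of the shipped published-count fixture.
    """
    required = {"framework_id", "cell", "n_consistent", "n_total"}
    if not required <= set(counts.columns):
        raise ValidationError(f"counts need columns {sorted(required)}")
    return [
        _validation_from_count(r.framework_id, r.cell, r.n_consistent, r.n_total)
        for r in counts.itertuples()
    ]


def screen_frameworks(
    validations: Iterable[CellValidation],
    alpha_marginal: float = 0.10,
    exceptions: Sequence[str] = (),
) -> list[RetentionDecision]:
    """Apply the framework-retention rule to per-scenario validations.

    A framework passes the rule iff *every* one of its four cells has
    agreement proportion > 0.5 and two-sided p < ``alpha_marginal`` (default
    0.10, operationalising "at least marginally significant").  Frameworks
    named in ``exceptions`` are retained regardless, flagged with
    reason="exception"; this mirrors battery-size considerations that can
    justify keeping a framework with one near-threshold cell.

    Output is ordered by framework_id and independent of input order.
    """
    by_framework: dict[str, list[CellValidation]] = {}
    for v in validations:
        by_framework.setdefault(v.framework_id, []).append(v)

    exceptions = set(exceptions)
    decisions = []
    for fw in sorted(by_framework):
        cells = by_framework[fw]
        seen = {v.cell for v in cells}
        if len(cells) != 4 or seen != set(CELL_ORDER):
            raise ValidationError(
                f"framework {fw!r} has cells {sorted(c.name for c in seen)}; "
                "expected exactly the four design cells"
            )
        failing = tuple(
            v.cell
            for v in sorted(cells, key=lambda v: v.cell.slot)
            if not (v.proportion > 0.5 and v.p_value < alpha_marginal)
        )
        if not failing:
            decisions.append(RetentionDecision(fw, True, (), "rule"))
        elif fw in exceptions:
            decisions.append(RetentionDecision(fw, True, failing, "exception"))
        else:
            decisions.append(RetentionDecision(fw, False, failing, "rule"))
    return decisions


@dataclass(frozen=True)
class ValidationReport:
    """Per-scenario screening table plus per-framework retention outcomes."""

    cells: pd.DataFrame
    retention: pd.DataFrame
    n_frameworks_retained: int
    n_scenarios_retained: int

    def retained_frameworks(self) -> list[str]:
        return sorted(self.retention.loc[self.retention["retained"], "framework_id"])

    def to_markdown(self) -> str:
        lines = [
            "| framework | cell | n (%) | chi2 | sig |",
            "|---|---|---|---|---|",
        ]
        for r in self.cells.itertuples():
            lines.append(
                f"| {r.framework_id} | {r.cell} | {r.n_consistent} "
                f"({100 * r.proportion:.0f}%) | {r.chi2:.2f} | {r.stars} |"
            )
        lines.append("")
        retained = ", ".join(self.retained_frameworks())
        lines.append(
            f"Retained {self.n_frameworks_retained} frameworks "
            f"({self.n_scenarios_retained} scenarios): {retained}"
        )
        return "\n".join(lines)


def _cells_frame(validations: Sequence[CellValidation]) -> pd.DataFrame:
    rows = [
        {
            "framework_id": v.framework_id,
            "cell": v.cell.name,
            "n_consistent": v.n_consistent,
            "n_total": v.n_total,
            "proportion": v.proportion,
            "chi2": v.chi2,
            "p_value": v.p_value,
            "direction": v.direction,
            "stars": significance_stars(v.p_value),
        }
        for v in validations
    ]
    df = pd.DataFrame(rows)
    slot = {c.name: c.slot for c in CELL_ORDER}
    return (
        df.assign(_slot=df["cell"].map(slot))
        .sort_values(["framework_id", "_slot"])
        .drop(columns="_slot")
        .reset_index(drop=True)
    )


def summarize_validation(
    judgments_or_counts: pd.DataFrame,
    scenario_bank: Sequence[Mapping] | None = None,
    alpha_marginal: float = 0.10,
    exceptions: Sequence[str] = (),
    imc_flags: pd.Series | None = None,
) -> ValidationReport:
    """Run the whole screening stage and assemble a report.

    Accepts either a long judgments table (participant_id/framework_id/cell/
    option) or a pre-aggregated count table (framework_id/cell/n_consistent/
    n_total).  When a scenario bank is supplied, every framework in the bank
    must be covered by at least one judgment.
    """
    if "option" in judgments_or_counts.columns:
        validations = cell_validations(judgments_or_counts, imc_flags=imc_flags)
    else:
        validations = cell_validations_from_counts(judgments_or_counts)

    if scenario_bank is not None:
        covered = {v.framework_id for v in validations}
        missing = [fw["id"] for fw in scenario_bank if fw["id"] not in covered]
        if missing:
            raise ValidationError(
                f"scenario bank frameworks with zero judgments: {missing}"
            )

    decisions = screen_frameworks(validations, alpha_marginal, exceptions)
    retention = pd.DataFrame(
        {
            "framework_id": [d.framework_id for d in decisions],
            "retained": [d.retained for d in decisions],
            "reason": [d.reason for d in decisions],
            "failing_cells": [
                ";".join(c.name for c in d.failing_cells) for d in decisions
            ],
        }
    )
    n_fw = int(retention["retained"].sum())
    return ValidationReport(
        cells=_cells_frame(validations),
        retention=retention,
        n_frameworks_retained=n_fw,
        n_scenarios_retained=4 * n_fw,
    )
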
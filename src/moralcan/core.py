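"""Core types and algebra for the 2x2 everyday-moral-dilemma design.

Each scene framework exists in four parallel versions crossing whether the
proposed act benefits the self (egoistic) and whether it benefits others
(altruistic).  The four acceptance probabilities p1..p4 (one per cell) carry
all the information; the dissociation is a fixed linear map of them:

    AT = (p2 - p1 + p3 - p4) / 2     altruistic tendency, in [-1, 1]
    ET = (p2 - p3 + p1 - p4) / 2     egoistic tendency, in [-1, 1]
    OP = (p1 + p2 + p3 + p4) / 4     overall action/inaction preference, [0, 1]
    AC = p3                          altruistic-choice probability

A fourth orthogonal contrast D = (p2 + p4 - p1 - p3) / 2 (the altruism x
egoism interaction) completes the basis and makes the map invertible, which
is what the synthetic-data generator uses to plant known parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np
import pandas as pd

from .errors import InfeasibleParameterError, MissingCellError, ValidationError

__all__ = [
    "DilemmaCell",
    "CELL_ORDER",
    "ProbabilityProfile",
    "CANParameters",
    "estimate_profile",
    "dissociate",
    "interaction_term",
    "invert",
    "invert_matrix",
    "feasible_mask",
    "participant_parameters",
]


class DilemmaCell(Enum):
    """The four cells of the egoistic x altruistic factorial design.

    The integer value is the probability slot: cell k is summarised by p_k.
    """

    EGO_NONALT = 1      # act benefits self, harms others
    EGO_ALT = 2         # act benefits both
    NONEGO_ALT = 3      # act benefits others at a cost to self
    NONEGO_NONALT = 4   # act harms both

    @property
    def slot(self) -> int:
        return self.value

    def __lt__(self, other):
        if isinstance(other, DilemmaCell):
            return self.value < other.value
        return NotImplemented

    @property
    def egoistic(self) -> bool:
        return self in (DilemmaCell.EGO_NONALT, DilemmaCell.EGO_ALT)

    @property
    def altruistic(self) -> bool:
        return self in (DilemmaCell.EGO_ALT, DilemmaCell.NONEGO_ALT)

    @classmethod
    def coerce(cls, value: Union["DilemmaCell", str]) -> "DilemmaCell":
        """Accept a cell enum or its name (as stored in CSV files)."""
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value)]
        except KeyError:
            raise ValidationError(
                f"unknown dilemma cell {value!r}; expected one of "
                f"{[c.name for c in cls]}"
            ) from None


#: Cells in probability-slot order (p1, p2, p3, p4).
CELL_ORDER: tuple[DilemmaCell, ...] = tuple(sorted(DilemmaCell, key=lambda c: c.slot))

# Rows: (op, at, et, d) as linear functionals of (p1, p2, p3, p4).
_CONTRASTS = np.array(
    [
        [0.25, 0.25, 0.25, 0.25],   # OP
        [-0.5, 0.5, 0.5, -0.5],     # AT
        [0.5, 0.5, -0.5, -0.5],     # ET
        [-0.5, 0.5, -0.5, 0.5],     # D
    ]
)


@dataclass(frozen=True)
class ProbabilityProfile:
    """Acceptance probabilities of one analysis unit in the four cells.

    ``n_trials_per_cell`` records how many binary responses stand behind each
    estimate (p1..p4 order); it is None for exogenous profiles.  With m
    scenarios per cell an individual profile has granularity 1/m, which
    propagates into the sampling variance of the dissociated parameters.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    n_trials_per_cell: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        for slot, p in enumerate(self.as_array(), start=1):
            if not np.isfinite(p) or not 0.0 <= p <= 1.0:
                raise ValidationError(f"p{slot} = {p!r} is not in [0, 1]")
        if self.n_trials_per_cell is not None:
            n = tuple(int(k) for k in self.n_trials_per_cell)
            if len(n) != 4 or any(k < 1 for k in n):
                raise ValidationError(
                    f"n_trials_per_cell must be four positive counts, got {n}"
                )
            object.__setattr__(self, "n_trials_per_cell", n)

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)


@dataclass(frozen=True)
class CANParameters:
    """The dissociated decision parameters of one analysis unit."""

    at: float
    et: float
    op: float
    ac: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.at <= 1.0:
            raise ValidationError(f"at = {self.at!r} outside [-1, 1]")
        if not -1.0 <= self.et <= 1.0:
            raise ValidationError(f"et = {self.et!r} outside [-1, 1]")
        if not 0.0 <= self.op <= 1.0:
            raise ValidationError(f"op = {self.op!r} outside [0, 1]")
        if not 0.0 <= self.ac <= 1.0:
            raise ValidationError(f"ac = {self.ac!r} outside [0, 1]")


def _validate_accept(accept: np.ndarray) -> np.ndarray:
    accept = np.asarray(accept)
    values = pd.unique(accept)
    bad = [v for v in values if v not in (0, 1, 0.0, 1.0, False, True)]
    if bad:
        raise ValidationError(f"accept values must be 0 or 1; found {bad[:5]}")
    return accept.astype(float)


def estimate_profile(records: pd.DataFrame) -> ProbabilityProfile:
    """Estimate the four cell probabilities from binary accept/reject records.

    Parameters
    ----------
    records
        Long table with columns ``cell`` (DilemmaCell or its name) and
        ``accept`` (0/1).  May cover one participant (individual level) or a
        pooled set of participants (group level).

    Returns
    -------
    ProbabilityProfile
        p_k is the exact fraction of accepts in cell k; ``n_trials_per_cell``
        holds the per-cell record counts.

    Raises
    ------
    MissingCellError
        If any of the four cells has no records.
    ValidationError
        If an accept value is not binary.
    """
    if not {"cell", "accept"} <= set(records.columns):
        raise ValidationError("records need 'cell' and 'accept' columns")
    cells = records["cell"].map(DilemmaCell.coerce)
    accept = _validate_accept(records["accept"].to_numpy())

    p, n = [], []
    missing = []
    for cell in CELL_ORDER:
        mask = (cells == cell).to_numpy()
        count = int(mask.sum())
        if count == 0:
            missing.append(cell)
            continue
        p.append(float(accept[mask].mean()))
        n.append(count)
    if missing:
        raise MissingCellError(missing)
    return ProbabilityProfile(*p, n_trials_per_cell=tuple(n))


def dissociate(profile: ProbabilityProfile) -> CANParameters:
    """Dissociate a profile into (AT, ET, OP, AC) via the linear contrasts.

    Pure function of the four probabilities; no rounding or shrinkage.
    """
    op, at, et, _ = _CONTRASTS @ profile.as_array()
    return CANParameters(at=float(at), et=float(et), op=float(op), ac=profile.p3)


def interaction_term(profile: ProbabilityProfile) -> float:
    """The altruism x egoism interaction contrast D = (p2 + p4 - p1 - p3)/2.

    Not a substantive decision parameter; it is the fourth orthogonal
    contrast needed to invert the parameterisation (D = 0 means acceptance
    of benefit-to-others and benefit-to-self combine additively).
    """
    return float(_CONTRASTS[3] @ profile.as_array())


def _unpack_params(params) -> tuple[float, float, float]:
    if isinstance(params, CANParameters):
        return params.at, params.et, params.op
    at, et, op = params
    return float(at), float(et), float(op)


def invert(params, d: float = 0.0) -> ProbabilityProfile:
    """Map (AT, ET, OP) plus the interaction D back to cell probabilities.

    p1 = OP - AT/2 + ET/2 - D/2        p2 = OP + AT/2 + ET/2 + D/2
    p3 = OP + AT/2 - ET/2 - D/2        p4 = OP - AT/2 - ET/2 + D/2

    ``params`` may be a :class:`CANParameters` (its ``ac`` is ignored: AC is
    determined by the other four quantities) or an (at, et, op) triple.

    Raises
    ------
    InfeasibleParameterError
        If any implied probability falls outside [0, 1]; the error names the
        first offending slot and its value.
    """
    at, et, op = _unpack_params(params)
    p = invert_matrix(at, et, op, d)[0]
    # Tolerate floating-point dust at the boundaries only.
    for slot, value in enumerate(p, start=1):
        if value < -1e-12 or value > 1 + 1e-12:
            raise InfeasibleParameterError(slot, float(value))
    p = np.clip(p, 0.0, 1.0)
    return ProbabilityProfile(*map(float, p))


def invert_matrix(at, et, op, d) -> np.ndarray:
    """Vectorised inverse map; returns an (n, 4) array of (p1..p4) rows.

    Does not check feasibility; pair with :func:`feasible_mask`.
    """
    at, et, op, d = np.broadcast_arrays(
        np.atleast_1d(np.asarray(at, dtype=float)),
        np.atleast_1d(np.asarray(et, dtype=float)),
        np.atleast_1d(np.asarray(op, dtype=float)),
        np.atleast_1d(np.asarray(d, dtype=float)),
    )
    theta = np.stack([op, at, et, d], axis=-1)
    return theta @ np.linalg.inv(_CONTRASTS).T


def feasible_mask(at, et, op, d) -> np.ndarray:
    """Boolean mask of parameter rows whose implied p1..p4 all lie in [0, 1]."""
    p = invert_matrix(at, et, op, d)
    return np.all((p >= 0.0) & (p <= 1.0), axis=-1)


def participant_parameters(decisions: pd.DataFrame) -> pd.DataFrame:
    """Individual-level profiles and parameters from a long decisions table.

    Parameters
    ----------
    decisions
        Columns ``participant_id``, ``cell``, ``accept`` (framework ids and
        latencies are ignored here).

    Returns
    -------
    DataFrame indexed by participant_id with columns p1..p4, at, et, op, ac
    and n_trials_per_cell (the per-cell response count, constant across cells
    in a complete battery).

    Raises
    ------
    MissingCellError
        If any participant lacks responses in one of the four cells.
    """
    if not {"participant_id", "cell", "accept"} <= set(decisions.columns):
        raise ValidationError(
            "decisions need 'participant_id', 'cell' and 'accept' columns"
        )
    df = decisions.copy()
    df["cell"] = df["cell"].map(lambda c: DilemmaCell.coerce(c).name)
    _validate_accept(df["accept"].to_numpy())

    counts = df.pivot_table(
        index="participant_id", columns="cell", values="accept", aggfunc="size"
    )
    means = df.pivot_table(
        index="participant_id", columns="cell", values="accept", aggfunc="mean"
    )
    cell_names = [c.name for c in CELL_ORDER]
    missing_cols = [c for c in cell_names if c not in means.columns]
    if missing_cols or means[cell_names].isna().any().any():
        cells = set(missing_cols) | {
            c for c in cell_names if c in means.columns and means[c].isna().any()
        }
        raise MissingCellError([DilemmaCell[c] for c in sorted(cells)])

    p = means[cell_names].to_numpy(dtype=float)
    out = pd.DataFrame(p, index=means.index, columns=["p1", "p2", "p3", "p4"])
    theta = p @ _CONTRASTS.T
    out["op"], out["at"], out["et"] = theta[:, 0], theta[:, 1], theta[:, 2]
    out["ac"] = out["p3"]
    out["n_trials_per_cell"] = counts[cell_names].min(axis=1).astype(int)
    return out[["p1", "p2", "p3", "p4", "at", "et", "op", "ac", "n_trials_per_cell"]]
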
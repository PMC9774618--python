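"""Synthetic survey cohorts with the structure the analysis pipeline assumes.

Real batteries of this kind are collected on survey platforms and rarely
deposited, so every stage of the package is exercised on generated data whose
ground truth is known.  The generative model:

* Each participant carries latent decision parameters (AT, ET, OP, D) and two
  standardised trait latents (si = social isolation, dd = distress
  disclosure), drawn jointly from a multivariate normal with configurable
  means, SDs and correlations, rejection-resampled so that the implied cell
  probabilities are feasible.
* Binary accept/reject decisions are independent Bernoulli draws per scenario
  with the cell probability given by the inverse CAN map.
* Structure-judgment responses (the validation task) match the designed cell
  with a per-cell consistency probability, otherwise land uniformly on one of
  the other three options.
* Likert items load on a trait latent with Gaussian noise and are cut at
  fixed thresholds into 1..5 categories; reverse-keyed items are *stored*
  flipped, so downstream scoring must un-flip them.
* Inattentive responding (IMC failures) and extreme completion latencies are
  planted as labelled rows so exclusion rules can be tested end to end.

Defaults describe a cohort of 747 (post-attention-check) with mean
(AT, ET, OP) = (0.22, 0.31, 0.57), trait-parameter correlations
r(si, at) = 0.27, r(dd, at) = 0.19, r(si, dd) = 0.48, six frameworks of four
scenarios each, and 13 planted latency outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core import CELL_ORDER, DilemmaCell, feasible_mask, invert_matrix
from .errors import ConfigError, MoralcanError
from .validation import OPTION_FOR_CELL

__all__ = [
    "ScaleSimSpec",
    "FS_SIM_SPEC",
    "DDI_SIM_SPEC",
    "PopulationConfig",
    "default_latent_corr",
    "sample_latents",
    "simulate_decisions",
    "simulate_judgments",
    "simulate_scale_items",
    "generate_study1_dataset",
    "generate_study2_dataset",
]

#: Order of latent dimensions in the correlation matrix.
LATENT_ORDER = ("at", "et", "op", "d", "si", "dd")

RngLike = Union[int, np.random.Generator, None]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScaleSimSpec:
    """Measurement model of one Likert scale.

    ``loading`` is the standardised loading of every item on the trait latent
    (scalar, or one value per item); item uniqueness is 1 - loading^2.
    ``thresholds`` are the four cutpoints carving the latent response into the
    1..5 categories.  ``reverse_items`` are stored as 6 - response.
    """

    scale_id: str
    latent: str  # "si" or "dd"
    n_items: int
    loading: Union[float, tuple] = 0.7
    reverse_items: tuple = ()
    thresholds: tuple = (-0.8, -0.3, 0.3, 0.8)

    def __post_init__(self):
        loadings = self.loadings()
        if len(loadings) != self.n_items or np.any((loadings < 0) | (loadings > 1)):
            raise ConfigError(
                f"scale {self.scale_id}: loadings must be {self.n_items} values in [0, 1]"
            )
        thr = np.asarray(self.thresholds, dtype=float)
        if len(thr) != 4 or np.any(np.diff(thr) <= 0):
            raise ConfigError(
                f"scale {self.scale_id}: thresholds must be 4 strictly increasing values"
            )
        unknown = set(self.reverse_items) - set(self.item_ids)
        if unknown:
            raise ConfigError(f"scale {self.scale_id}: unknown reverse items {unknown}")

    @property
    def item_ids(self) -> tuple:
        return tuple(f"{self.scale_id}_{i}" for i in range(1, self.n_items + 1))

    def loadings(self) -> np.ndarray:
        if np.isscalar(self.loading):
            return np.full(self.n_items, float(self.loading))
        return np.asarray(self.loading, dtype=float)


# Reverse-keyed sets follow the published item counts (3 of 6 on the social
# isolation scale, 6 of 12 on the distress disclosure scale); which specific
# items are keyed is a package convention (even-numbered items).
FS_SIM_SPEC = ScaleSimSpec(
    scale_id="fs", latent="si", n_items=6, loading=0.7,
    reverse_items=("fs_2", "fs_4", "fs_6"),
)
DDI_SIM_SPEC = ScaleSimSpec(
    scale_id="ddi", latent="dd", n_items=12, loading=0.7,
    reverse_items=("ddi_2", "ddi_4", "ddi_6", "ddi_8", "ddi_10", "ddi_12"),
)


def default_latent_corr(si_at: float = 0.27, dd_at: float = 0.19,
                        si_dd: float = 0.48) -> np.ndarray:
    """Correlation matrix over (at, et, op, d, si, dd): identity except the
    three planted trait-parameter correlations."""
    corr = np.eye(len(LATENT_ORDER))
    idx = {name: i for i, name in enumerate(LATENT_ORDER)}
    for a, b, r in (("si", "at", si_at), ("dd", "at", dd_at), ("si", "dd", si_dd)):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr


def _default_means() -> dict:
    return {"at": 0.22, "et": 0.31, "op": 0.57, "d": 0.0}


def _default_sds() -> dict:
    # Chosen so that individual-level estimates from 6 trials/cell have SDs
    # near 0.25 / 0.23 / 0.11 once binomial granularity is added on top.
    return {"at": 0.15, "et": 0.11, "op": 0.05, "d": 0.0}


@dataclass
class PopulationConfig:
    """Full description of a synthetic cohort.

    Probabilistic contamination rates (``imc_fail_rate``,
    ``latency_outlier_rate``) are realised as exactly ``round(rate * n)``
    planted rows so that cohorts of a given size are reproducible; the
    default latency-outlier rate 13/747 plants 13 outliers in the default
    cohort.  Completion latency is log-normal (median ~11 min); outlier rows
    are scaled by ``latency_outlier_factor``.
    """

    n_participants: int = 747
    n_frameworks: int = 6
    latent_means: Mapping[str, float] = field(default_factory=_default_means)
    latent_sds: Mapping[str, float] = field(default_factory=_default_sds)
    latent_corr: np.ndarray = field(default_factory=default_latent_corr)
    judgment_consistency: Union[float, Mapping] = 0.85
    scale_specs: tuple = (FS_SIM_SPEC, DDI_SIM_SPEC)
    imc_fail_rate: float = 0.0
    latency_outlier_rate: float = 13 / 747
    latency_log_mean: float = math.log(660.0)
    latency_log_sd: float = 0.25
    latency_outlier_factor: float = 20.0
    decision_latency_log_mean: float = math.log(10.0)
    decision_latency_log_sd: float = 0.4
    prop_male: float = 0.421
    prop_single: float = 0.488
    age_mean: float = 26.66
    age_sd: float = 6.53
    age_range: tuple = (16, 66)
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0 or self.n_frameworks < 1:
            raise ConfigError("n_participants must be >= 0, n_frameworks >= 1")
        for name in ("at", "et", "op", "d"):
            if name not in self.latent_means or name not in self.latent_sds:
                raise ConfigError(f"latent means/sds must include {name!r}")
            if self.latent_sds[name] < 0:
                raise ConfigError(f"latent sd for {name!r} is negative")
        corr = np.asarray(self.latent_corr, dtype=float)
        k = len(LATENT_ORDER)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ConfigError(f"latent_corr must be a symmetric {k}x{k} matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConfigError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ConfigError("latent_corr is not positive semi-definite")
        self.latent_corr = corr
        for name in ("imc_fail_rate", "latency_outlier_rate", "prop_male",
                     "prop_single"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        cons = self.judgment_consistency
        values = cons.values() if isinstance(cons, Mapping) else [cons]
        if any(not 0.0 <= c <= 1.0 for c in values):
            raise ConfigError("judgment_consistency must lie in [0, 1]")


def _mvn_draw(rng, mean, cov, n) -> np.ndarray:
    """MVN sampler tolerating a PSD-singular covariance (zero-SD latents)."""
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ConfigError("latent covariance is not positive semi-definite")
    a = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((n, len(mean)))
    return np.asarray(mean) + z @ a.T


def sample_latents(config: PopulationConfig, rng: RngLike = None) -> pd.DataFrame:
    """Draw a cohort of latent profiles plus demographics.

    Infeasible draws (implied cell probability outside [0, 1], or a parameter
    outside its own range) are rejected and resampled, so the realised latent
    distribution is the configured multivariate normal truncated to the
    feasible region.

    Returns a DataFrame with columns participant_id, at, et, op, d,
    si_latent, dd_latent, gender, age, relationship_status.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.n_participants
    columns = ["participant_id", "at", "et", "op", "d", "si_latent", "dd_latent",
               "gender", "age", "relationship_status"]
    if n == 0:
        return pd.DataFrame(columns=columns)

    sds = np.array([config.latent_sds[k] for k in ("at", "et", "op", "d")] + [1.0, 1.0])
    means = np.array(
        [config.latent_means[k] for k in ("at", "et", "op", "d")] + [0.0, 0.0]
    )
    cov = config.latent_corr * np.outer(sds, sds)

    draws = _mvn_draw(rng, means, cov, n)
    total_drawn = n

    def ok(x: np.ndarray) -> np.ndarray:
        at, et, op, d = x[:, 0], x[:, 1], x[:, 2], x[:, 3]
        in_range = (
            (np.abs(at) <= 1) & (np.abs(et) <= 1) & (op >= 0) & (op <= 1)
            & (np.abs(d) <= 1)
        )
        return in_range & feasible_mask(at, et, op, d)

    bad = ~ok(draws)
    tries = 0
    while bad.any():
        tries += 1
        if tries > config.max_retries:
            accepted = n - int(bad.sum())
            raise MoralcanError(
                "rejection sampling budget exhausted: acceptance rate "
                f"{accepted / total_drawn:.3f} after {total_drawn} draws; "
                "latent means/SDs imply mostly infeasible profiles"
            )
        k = int(bad.sum())
        fresh = _mvn_draw(rng, means, cov, k)
        total_drawn += k
        draws[bad] = fresh
        bad[np.flatnonzero(bad)[ok(fresh)]] = False

    width = max(4, len(str(n)))
    out = pd.DataFrame(draws, columns=["at", "et", "op", "d", "si_latent", "dd_latent"])
    out.insert(0, "participant_id", [f"P{i + 1:0{width}d}" for i in range(n)])
    out["gender"] = np.where(rng.random(n) < config.prop_male, "male", "female")
    age = np.rint(rng.normal(config.age_mean, config.age_sd, n))
    out["age"] = np.clip(age, *config.age_range).astype(int)
    out["relationship_status"] = np.where(
        rng.random(n) < config.prop_single, "single", "non_single"
    )
    return out


def simulate_decisions(
    latents: pd.DataFrame,
    n_frameworks: int = 6,
    rng: RngLike = None,
    latency_log_mean: float = math.log(10.0),
    latency_log_sd: float = 0.4,
) -> pd.DataFrame:
    """Bernoulli accept/reject decisions for every participant x framework x cell.

    Returns exactly ``len(latents) * n_frameworks * 4`` rows with columns
    participant_id, framework_id, cell, accept, latency_s (per-decision
    reading + response time, log-normal).
    """
    rng = _as_rng(rng)
    n = len(latents)
    cols = ["participant_id", "framework_id", "cell", "accept", "latency_s"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    p = invert_matrix(
        latents["at"].to_numpy(), latents["et"].to_numpy(),
        latents["op"].to_numpy(), latents["d"].to_numpy(),
    )
    if np.any((p < 0) | (p > 1)):
        bad = latents.loc[np.any((p < 0) | (p > 1), axis=1), "participant_id"]
        raise MoralcanError(
            f"infeasible latent profiles for participants {list(bad[:5])}"
        )
    nf = int(n_frameworks)
    accept = (rng.random((n, nf, 4)) < p[:, None, :]).astype(int)
    latency = rng.lognormal(latency_log_mean, latency_log_sd, size=(n, nf, 4))

    frameworks = [f"F{j + 1}" for j in range(nf)]
    cells = [c.name for c in CELL_ORDER]
    return pd.DataFrame(
        {
            "participant_id": np.repeat(latents["participant_id"].to_numpy(), nf * 4),
            "framework_id": np.tile(np.repeat(frameworks, 4), n),
            "cell": np.tile(cells, n * nf),
            "accept": accept.reshape(-1),
            "latency_s": np.round(latency.reshape(-1), 3),
        }
    )


def _consistency_by_cell(consistency) -> dict:
    if isinstance(consistency, Mapping):
        return {DilemmaCell.coerce(k): float(v) for k, v in consistency.items()}
    return {c: float(consistency) for c in CELL_ORDER}


def simulate_judgments(
    n_participants: int,
    scenario_bank: Sequence[Mapping],
    consistency: Union[float, Mapping] = 0.85,
    rng: RngLike = None,
) -> pd.DataFrame:
    """Structure-judgment (A-D) responses for the validation task.

    With probability ``consistency`` (scalar or per-cell mapping) a response
    is the option matching the designed cell; otherwise it is uniform over
    the other three options.
    """
    rng = _as_rng(rng)
    cons = _consistency_by_cell(consistency)
    if any(not 0 <= c <= 1 for c in cons.values()):
        raise ConfigError("consistency probabilities must lie in [0, 1]")

    scenarios = [
        (fw["id"], DilemmaCell.coerce(cell["cell"]))
        for fw in scenario_bank
        for cell in fw["cells"]
    ]
    width = max(4, len(str(n_participants)))
    pids = [f"P{i + 1:0{width}d}" for i in range(n_participants)]

    options = np.array(list("ABCD"))
    rows = {"participant_id": [], "framework_id": [], "cell": [], "option": []}
    for fw_id, cell in scenarios:
        designed = OPTION_FOR_CELL[cell]
        others = [o for o in "ABCD" if o != designed]
        hit = rng.random(n_participants) < cons[cell]
        alt = rng.integers(0, 3, n_participants)
        chosen = np.where(hit, designed, np.array(others)[alt])
        rows["participant_id"].extend(pids)
        rows["framework_id"].extend([fw_id] * n_participants)
        rows["cell"].extend([cell.name] * n_participants)
        rows["option"].extend(chosen.tolist())
    return pd.DataFrame(rows)


def simulate_scale_items(
    latents: pd.DataFrame, spec: ScaleSimSpec, rng: RngLike = None
) -> pd.DataFrame:
    """Likert item responses (long format) for one scale.

    latent_item = loading * trait + sqrt(1 - loading^2) * noise, cut at the
    spec thresholds into categories 1..5; reverse-keyed items are stored as
    6 - response.
    """
    rng = _as_rng(rng)
    trait_col = f"{spec.latent}_latent"
    if trait_col not in latents.columns:
        raise ConfigError(f"latents table lacks column {trait_col!r}")
    trait = latents[trait_col].to_numpy()
    n = len(trait)
    lam = spec.loadings()
    noise = rng.standard_normal((n, spec.n_items))
    latent_item = trait[:, None] * lam + noise * np.sqrt(1.0 - lam**2)
    thr = np.asarray(spec.thresholds)
    response = 1 + (latent_item[:, :, None] > thr).sum(axis=-1)

    reverse = np.array([item in spec.reverse_items for item in spec.item_ids])
    response = np.where(reverse, 6 - response, response)

    return pd.DataFrame(
        {
            "participant_id": np.repeat(latents["participant_id"].to_numpy(),
                                        spec.n_items),
            "scale_id": spec.scale_id,
            "item_id": np.tile(spec.item_ids, n),
            "value": response.reshape(-1),
        }
    )


def _plant_flags(rng, pids: np.ndarray, rate: float, eligible: np.ndarray
                 ) -> np.ndarray:
    """Choose round(rate * n) rows among ``eligible`` (boolean mask)."""
    n = len(pids)
    k = int(round(rate * n))
    flags = np.zeros(n, dtype=bool)
    if k > 0:
        candidates = np.flatnonzero(eligible)
        if k > len(candidates):
            raise ConfigError("not enough eligible rows to plant contamination")
        flags[rng.choice(candidates, size=k, replace=False)] = True
    return flags


def generate_study2_dataset(config: PopulationConfig) -> dict:
    """Full synthetic decision-survey dataset (the individual-differences study).

    Returns a dict of DataFrames: ``latents`` (ground truth), ``decisions``,
    ``scales`` (all scales stacked), ``demographics`` (with imc_pass,
    total_latency_s and the planted latency_outlier label).  Deterministic
    given ``config.seed``.
    """
    rng = _as_rng(config.seed)
    latents = sample_latents(config, rng)
    decisions = simulate_decisions(
        latents, config.n_frameworks, rng,
        config.decision_latency_log_mean, config.decision_latency_log_sd,
    )
    scales = (
        pd.concat(
            [simulate_scale_items(latents, spec, rng) for spec in config.scale_specs],
            ignore_index=True,
        )
        if len(latents)
        else pd.DataFrame(columns=["participant_id", "scale_id", "item_id", "value"])
    )

    n = len(latents)
    pids = latents["participant_id"].to_numpy() if n else np.array([], dtype=object)
    imc_fail = _plant_flags(rng, pids, config.imc_fail_rate, np.ones(n, dtype=bool))
    total_latency = rng.lognormal(config.latency_log_mean, config.latency_log_sd, n)
    outlier = _plant_flags(rng, pids, config.latency_outlier_rate, ~imc_fail)
    total_latency = np.where(
        outlier, total_latency * config.latency_outlier_factor, total_latency
    )

    demographics = pd.DataFrame(
        {
            "participant_id": pids,
            "gender": latents["gender"] if n else pd.Series(dtype=object),
            "age": latents["age"] if n else pd.Series(dtype=int),
            "relationship_status": (
                latents["relationship_status"] if n else pd.Series(dtype=object)
            ),
            "imc_pass": ~imc_fail,
            "total_latency_s": np.round(total_latency, 3),
            "latency_outlier": outlier,
        }
    )
    return {
        "latents": latents,
        "decisions": decisions,
        "scales": scales,
        "demographics": demographics,
    }


def generate_study1_dataset(
    n_participants: int = 209,
    scenario_bank: Sequence[Mapping] | None = None,
    consistency: Union[float, Mapping] = 0.85,
    imc_fail_rate: float = 0.0,
    seed: int = 0,
) -> dict:
    """Synthetic validation-study dataset: judgments plus IMC flags.

    Judgments are generated for all participants; ``imc_pass`` marks the
    planted failures so the screening stage can drop them first.
    """
    if scenario_bank is None:
        from .io import load_scenario_bank

        scenario_bank = load_scenario_bank()["frameworks"]
    rng = _as_rng(seed)
    judgments = simulate_judgments(n_participants, scenario_bank, consistency, rng)
    pids = judgments["participant_id"].unique()
    fail = _plant_flags(rng, pids, imc_fail_rate, np.ones(len(pids), dtype=bool))
    imc_pass = pd.Series(~fail, index=pids, name="imc_pass")
    return {"judgments": judgments, "imc_pass": imc_pass}
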
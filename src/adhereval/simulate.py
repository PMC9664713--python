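"""Synthetic cohort generator with a latent-adherence measurement-error model.

The generator emulates the data structure of an ART-adherence study in which a
single inter-visit window (the final, week-48 window) is observed per
participant through three imperfect channels:

* **self-report (SR)** — the participant states how many pills they missed;
  social-desirability and recall bias shrink the reported missed-pill count
  (``sr_underreport_factor``) and a fraction of participants report zero
  missed pills regardless of the truth (``sr_zero_report_prob``);
* **pharmacy refill (PR)** — a pill ledger (dispensed + previously returned −
  currently returned); leftover pills may be unknown
  (``pr_unknown_leftover_prob``, in which case downstream scoring assumes
  full adherence) and surplus supply carried in from earlier visits may be
  kept at home uncounted (``pr_surplus_prob``), inflating apparent intake;
* **electronic monitoring (RTMM)** — a smart pill box counts box openings;
  connectivity/battery outages drop intake events
  (``rtmm_outage_day_prob``) and "pocket dosing" consolidates several doses
  into one opening (``rtmm_pocket_dose_prob``), deflating the count.

All three channels observe one underlying intake stream: per dosing moment a
Bernoulli draw with the participant's latent adherence propensity.  The
recorded ``true_adherence`` is the realized fraction of dosing moments at
which pills were actually taken, so with every error mechanism disabled each
channel reproduces ``100 * true_adherence`` exactly.

The binary outcome (detectable viral load at the end of follow-up) is drawn
from a logistic model on realized adherence with an additive regimen effect
for the tenofovir--lamivudine--efavirenz (TLE) class.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

__all__ = [
    "REGIMEN_CLASSES",
    "SimulationConfig",
    "ParticipantRecord",
    "simulate_cohort",
    "simulate_outcome",
    "write_cohort",
    "read_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "expected_detectable_fraction",
]

REGIMEN_CLASSES = ("TLE", "other_first_line", "PI_based", "DTG_based")


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if value <= 0:
        raise ConfigError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one synthetic cohort.

    Latent adherence propensity is a two-component Beta mixture
    (an adherent and a struggling subpopulation), each component
    parameterized by mean and concentration (a = mean*conc,
    b = (1-mean)*conc).  Defaults describe a cohort of 233 participants,
    ~70% female, with an over-reporting self-report channel and mildly
    lossy electronic monitoring, producing ~31% detectable viral load.
    """

    n_participants: int = 233
    prop_female: float = 0.704
    regimen_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "TLE": 0.32,
            "other_first_line": 0.32,
            "PI_based": 0.20,
            "DTG_based": 0.16,
        }
    )
    # latent adherence mixture
    adherence_high_mean: float = 0.95
    adherence_high_concentration: float = 40.0
    adherence_low_mean: float = 0.60
    adherence_low_concentration: float = 8.0
    adherence_high_weight: float = 0.70
    # visit window / prescription
    days_in_window: int = 56
    pills_per_day: int = 1
    dosing_moments_per_day: int = 1
    # outcome model (log-odds of detectable viral load)
    outcome_intercept: float = 2.7
    outcome_slope: float = -4.0
    outcome_tle_effect: float = -0.7
    # self-report error mechanisms
    sr_zero_report_prob: float = 0.5
    sr_underreport_factor: float = 0.5
    # pharmacy refill error mechanisms
    pr_unknown_leftover_prob: float = 0.15
    pr_surplus_prob: float = 0.10
    # electronic monitoring error mechanisms
    rtmm_outage_day_prob: float = 0.02
    rtmm_pocket_dose_prob: float = 0.10
    rtmm_arm_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError(
                f"n_participants must be positive, got {self.n_participants!r}"
            )
        for name in (
            "prop_female",
            "adherence_high_weight",
            "sr_zero_report_prob",
            "sr_underreport_factor",
            "pr_unknown_leftover_prob",
            "pr_surplus_prob",
            "rtmm_outage_day_prob",
            "rtmm_pocket_dose_prob",
            "rtmm_arm_prob",
        ):
            _check_prob(name, getattr(self, name))
        for name in (
            "adherence_high_concentration",
            "adherence_low_concentration",
        ):
            _check_positive(name, getattr(self, name))
        for name in ("adherence_high_mean", "adherence_low_mean"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ConfigError(f"{name} must be in (0, 1), got {value!r}")
        for name in ("days_in_window", "pills_per_day", "dosing_moments_per_day"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.pills_per_day % self.dosing_moments_per_day != 0:
            raise ConfigError(
                "pills_per_day must be divisible by dosing_moments_per_day "
                f"(got {self.pills_per_day} / {self.dosing_moments_per_day})"
            )
        probs = self.regimen_class_probs
        unknown = set(probs) - set(REGIMEN_CLASSES)
        if unknown:
            raise ConfigError(
                f"regimen_class_probs has unknown classes {sorted(unknown)}; "
                f"allowed: {list(REGIMEN_CLASSES)}"
            )
        for cls, p in probs.items():
            _check_prob(f"regimen_class_probs[{cls!r}]", p)
        total = sum(probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"regimen_class_probs must sum to 1, got {total!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    # -- convenience -------------------------------------------------------

    @property
    def dosing_moments_per_window(self) -> int:
        return self.days_in_window * self.dosing_moments_per_day

    @property
    def pills_per_window(self) -> int:
        return self.days_in_window * self.pills_per_day

    def adherence_mixture(self) -> tuple[stats.rv_continuous, stats.rv_continuous, float]:
        """Return (high component, low component, weight of high component)."""
        hm, hc = self.adherence_high_mean, self.adherence_high_concentration
        lm, lc = self.adherence_low_mean, self.adherence_low_concentration
        high = stats.beta(hm * hc, (1.0 - hm) * hc)
        low = stats.beta(lm * lc, (1.0 - lm) * lc)
        return high, low, self.adherence_high_weight

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown SimulationConfig fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class ParticipantRecord:
    """Raw observables for one participant's final visit window.

    ``pr_returned_current`` is ``None`` when leftover pills are unknown;
    ``rtmm_openings`` is ``None`` for participants outside the electronic
    monitoring arm.  ``true_adherence`` (realized fraction of dosing moments
    taken) exists only for simulated cohorts.
    """

    participant_id: str
    sex: str
    regimen_class: str
    true_adherence: float | None
    pills_per_day: int
    days_in_window: int
    sr_missed_pills: int
    pr_dispensed_prev: int
    pr_returned_prev: int
    pr_returned_current: int | None
    rtmm_openings: int | None
    rtmm_expected_openings: int
    vl_detectable: bool

    def validate(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(
                f"{self.participant_id}: sex must be 'female' or 'male', "
                f"got {self.sex!r}"
            )
        if self.regimen_class not in REGIMEN_CLASSES:
            raise ValueError(
                f"{self.participant_id}: unknown regimen_class "
                f"{self.regimen_class!r}"
            )
        if self.true_adherence is not None and not (0.0 <= self.true_adherence <= 1.0):
            raise ValueError(
                f"{self.participant_id}: true_adherence outside [0, 1]: "
                f"{self.true_adherence!r}"
            )
        if self.days_in_window <= 0 or self.pills_per_day <= 0:
            raise ValueError(
                f"{self.participant_id}: days_in_window and pills_per_day "
                "must be positive"
            )
        prescribed = self.days_in_window * self.pills_per_day
        if not (0 <= self.sr_missed_pills <= prescribed):
            raise ValueError(
                f"{self.participant_id}: sr_missed_pills={self.sr_missed_pills} "
                f"outside [0, {prescribed}]"
            )
        for name in ("pr_dispensed_prev", "pr_returned_prev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.participant_id}: {name} is negative")
        if self.pr_returned_current is not None and self.pr_returned_current < 0:
            raise ValueError(f"{self.participant_id}: pr_returned_current is negative")
        if self.rtmm_openings is not None and self.rtmm_openings < 0:
            raise ValueError(f"{self.participant_id}: rtmm_openings is negative")
        if self.rtmm_expected_openings <= 0:
            raise ValueError(
                f"{self.participant_id}: rtmm_expected_openings must be positive"
            )


def simulate_outcome(
    true_adherence: float,
    is_tle: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> bool:
    """Draw a detectable-viral-load indicator for one participant.

    Bernoulli with log-odds ``intercept + slope*adherence + tle_effect*1[TLE]``.
    """
    if not (0.0 <= true_adherence <= 1.0):
        raise ValueError(f"true_adherence outside [0, 1]: {true_adherence!r}")
    eta = (
        config.outcome_intercept
        + config.outcome_slope * true_adherence
        + (config.outcome_tle_effect if is_tle else 0.0)
    )
    return bool(rng.random() < expit(eta))


def simulate_cohort(config: SimulationConfig) -> list[ParticipantRecord]:
    """Generate a cohort of participants under ``config``.

    Deterministic for a fixed config (including seed): the same call produces
    an identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    high, low, w_high = config.adherence_mixture()
    classes = list(config.regimen_class_probs)
    class_p = np.array([config.regimen_class_probs[c] for c in classes])

    moments = config.dosing_moments_per_window
    pills_per_moment = config.pills_per_day // config.dosing_moments_per_day
    pills_total = config.pills_per_window

    records: list[ParticipantRecord] = []
    width = len(str(config.n_participants))
    for i in range(config.n_participants):
        pid = f"P{i + 1:0{width}d}"
        sex = "female" if rng.random() < config.prop_female else "male"
        regimen = classes[rng.choice(len(classes), p=class_p)]

        # latent adherence propensity, then the realized intake stream
        if rng.random() < w_high:
            propensity = float(high.rvs(random_state=rng))
        else:
            propensity = float(low.rvs(random_state=rng))
        taken_moments = int(rng.binomial(moments, propensity))
        true_adherence = taken_moments / moments
        taken_pills = taken_moments * pills_per_moment
        missed_pills = pills_total - taken_pills

        # self-report: shrink the missed count, sometimes report zero outright
        if rng.random() < config.sr_zero_report_prob:
            sr_missed = 0
        else:
            sr_missed = int(round(missed_pills * config.sr_underreport_factor))

        # pharmacy ledger: supply = dispensed + returned at previous visit;
        # surplus kept at home is never counted back, inflating apparent intake
        if rng.random() < config.pr_surplus_prob:
            extra = int(rng.integers(1, 15))
        else:
            extra = 0
        carried_in = int(rng.integers(0, extra + 1))
        dispensed_prev = pills_total + extra - carried_in
        returned_prev = carried_in
        supply = dispensed_prev + returned_prev
        kept_back = min(extra, supply - taken_pills)
        returned_current: int | None = supply - taken_pills - kept_back
        if rng.random() < config.pr_unknown_leftover_prob:
            returned_current = None

        # electronic monitoring: outages drop openings, pocket dosing
        # consolidates several intakes into one opening
        openings: int | None = None
        if rng.random() < config.rtmm_arm_prob:
            lost = int(rng.binomial(taken_moments, config.rtmm_outage_day_prob))
            openings = taken_moments - lost
            if openings >= 2 and rng.random() < config.rtmm_pocket_dose_prob:
                openings -= int(rng.integers(1, min(openings, 7)))

        vl = simulate_outcome(true_adherence, regimen == "TLE", config, rng)

        rec = ParticipantRecord(
            participant_id=pid,
            sex=sex,
            regimen_class=regimen,
            true_adherence=true_adherence,
            pills_per_day=config.pills_per_day,
            days_in_window=config.days_in_window,
            sr_missed_pills=sr_missed,
            pr_dispensed_prev=dispensed_prev,
            pr_returned_prev=returned_prev,
            pr_returned_current=returned_current,
            rtmm_openings=openings,
            rtmm_expected_openings=moments,
            vl_detectable=vl,
        )
        rec.validate()
        records.append(rec)
    return records


def expected_detectable_fraction(config: SimulationConfig, grid: int = 2001) -> float:
    """Analytic detectable-viral-load prevalence implied by ``config``.

    Integrates the outcome model over the latent adherence mixture and the
    binomial realization of intake (exact sum over intake counts), averaged
    over the regimen mix.  Serves as the closed-form check that the
    Monte-Carlo prevalence converges to the model's expectation.
    """
    high, low, w_high = config.adherence_mixture()
    m = config.dosing_moments_per_window
    a_grid = np.linspace(0.0, 1.0, grid)[1:-1]
    density = w_high * high.pdf(a_grid) + (1.0 - w_high) * low.pdf(a_grid)

    k = np.arange(m + 1)
    p_tle = config.regimen_class_probs.get("TLE", 0.0)
    total = 0.0
    for tle, weight in ((True, p_tle), (False, 1.0 - p_tle)):
        if weight == 0.0:
            continue
        eta = (
            config.outcome_intercept
            + config.outcome_slope * (k / m)
            + (config.outcome_tle_effect if tle else 0.0)
        )
        p_detect_given_k = expit(eta)
        # E_K[p | a] for each grid point a; binomial pmf over k
        pmf = stats.binom.pmf(k[None, :], m, a_grid[:, None])
        p_given_a = pmf @ p_detect_given_k
        total += weight * np.trapezoid(p_given_a * density, a_grid)
    norm = np.trapezoid(density, a_grid)
    return float(total / norm)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_COLUMNS = [
    "participant_id",
    "sex",
    "regimen_class",
    "true_adherence",
    "pills_per_day",
    "days_in_window",
    "sr_missed_pills",
    "pr_dispensed_prev",
    "pr_returned_prev",
    "pr_returned_current",
    "rtmm_openings",
    "rtmm_expected_openings",
    "vl_detectable",
]


def cohort_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Tabulate a cohort; optional fields become nullable columns."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    for col in ("pr_returned_current", "rtmm_openings"):
        df[col] = df[col].astype("Int64")
    return df


def frame_to_cohort(df: pd.DataFrame, validate: bool = True) -> list[ParticipantRecord]:
    records = []
    for idx, row in df.iterrows():
        rec = ParticipantRecord(
            participant_id=str(row["participant_id"]),
            sex=str(row["sex"]),
            regimen_class=str(row["regimen_class"]),
            true_adherence=(
                None if pd.isna(row.get("true_adherence")) else float(row["true_adherence"])
            ),
            pills_per_day=int(row["pills_per_day"]),
            days_in_window=int(row["days_in_window"]),
            sr_missed_pills=int(row["sr_missed_pills"]),
            pr_dispensed_prev=int(row["pr_dispensed_prev"]),
            pr_returned_prev=int(row["pr_returned_prev"]),
            pr_returned_current=(
                None if pd.isna(row["pr_returned_current"]) else int(row["pr_returned_current"])
            ),
            rtmm_openings=(
                None if pd.isna(row["rtmm_openings"]) else int(row["rtmm_openings"])
            ),
            rtmm_expected_openings=int(row["rtmm_expected_openings"]),
            vl_detectable=_parse_bool(row["vl_detectable"]),
        )
        if validate:
            try:
                rec.validate()
            except ValueError as exc:
                raise ValueError(f"row {idx}: {exc}") from exc
        records.append(rec)
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, str):
        if value.lower() in ("true", "1"):
            return True
        if value.lower() in ("false", "0"):
            return False
        raise ValueError(f"cannot parse boolean from {value!r}")
    return bool(int(value))


def write_cohort(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write a cohort CSV (unknown leftover / absent RTMM as empty fields)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.sex,
                    r.regimen_class,
                    "" if r.true_adherence is None else repr(r.true_adherence),
                    r.pills_per_day,
                    r.days_in_window,
                    r.sr_missed_pills,
                    r.pr_dispensed_prev,
                    r.pr_returned_prev,
                    "" if r.pr_returned_current is None else r.pr_returned_current,
                    "" if r.rtmm_openings is None else r.rtmm_openings,
                    r.rtmm_expected_openings,
                    r.vl_detectable,
                ]
            )


def read_cohort(path: str | Path) -> list[ParticipantRecord]:
    """Read a cohort CSV, validating per-record invariants.

    Raises ``ValueError`` with the offending row number on malformed rows or
    invariant violations; blank optional fields become ``None``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, dtype={"participant_id": str}, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse cohort CSV {path}: {exc}") from exc
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV {path} missing columns: {sorted(missing)}")
    try:
        return frame_to_cohort(df)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
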
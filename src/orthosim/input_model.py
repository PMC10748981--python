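"""Stochastic input parameters for the orthopaedic ward model.

The unit treats five elective procedures: primary total hip (p-THR), primary
total knee (p-TKR) and unicompartmental knee (p-UKR) replacement, plus hip and
knee revisions (r-THR, r-TKR).  Each procedure carries a length-of-stay (LOS)
distribution specified by its mean and standard deviation in days and sampled
as a lognormal via moment matching.  A fraction of patients experience a
delayed discharge: their whole stay is drawn from a separate, much longer
lognormal fitted to delayed spells.

This module owns:

* the moment-matching conversion from (mean, sd) to lognormal (mu, sigma);
* the baseline parameter set of the study unit (packaged as YAML);
* fitting parameters from EHR-like spell records;
* a synthetic EHR generator used for fixtures and parameter-recovery checks.

All stochastic operations take an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PROCEDURES",
    "PRIMARY_PROCEDURES",
    "REVISION_PROCEDURES",
    "LosSpec",
    "LognormalParams",
    "CaseMix",
    "ModelParams",
    "EhrRecord",
    "lognormal_from_moments",
    "sample_los",
    "sample_procedure",
    "fit_los_parameters",
    "generate_synthetic_ehr",
    "generate_reference_cohort",
    "REFERENCE_COHORT_COUNTS",
    "REFERENCE_COHORT_DELAYED",
    "baseline_params",
    "load_params",
    "save_params",
    "load_ehr_csv",
    "save_ehr_csv",
]

PRIMARY_PROCEDURES: tuple[str, ...] = ("p-THR", "p-TKR", "p-UKR")
REVISION_PROCEDURES: tuple[str, ...] = ("r-THR", "r-TKR")
PROCEDURES: tuple[str, ...] = PRIMARY_PROCEDURES + REVISION_PROCEDURES

#: Spell counts of the study cohort used for the exactly-representable fixture:
#: 6,912 elective spells of which 529 had a recorded discharge delay (7.6%).
REFERENCE_COHORT_COUNTS: dict[str, int] = {
    "p-THR": 3057,
    "p-TKR": 2302,
    "p-UKR": 679,
    "r-THR": 482,
    "r-TKR": 392,
}
REFERENCE_COHORT_DELAYED: int = 529


class InvalidParameterError(ValueError):
    """A distribution or probability parameter is outside its domain."""


class FittingError(ValueError):
    """Raised when EHR records are insufficient to fit the model parameters."""


def surgical_class_of(procedure: str) -> str:
    """Return ``"primary"`` or ``"revision"`` for a procedure label."""
    if procedure in PRIMARY_PROCEDURES:
        return "primary"
    if procedure in REVISION_PROCEDURES:
        return "revision"
    raise InvalidParameterError(f"unknown procedure label: {procedure!r}")


@dataclass(frozen=True)
class LosSpec:
    """Length-of-stay specification in natural units: mean and SD in days."""

    mean_days: float
    sd_days: float

    def __post_init__(self) -> None:
        if not self.mean_days > 0:
            raise InvalidParameterError(
                f"mean_days must be positive, got {self.mean_days}"
            )
        if self.sd_days < 0:
            raise InvalidParameterError(
                f"sd_days must be non-negative, got {self.sd_days}"
            )

    def scaled(self, factor: float) -> "LosSpec":
        """Scale mean and SD together (coefficient of variation preserved)."""
        if not factor > 0:
            raise InvalidParameterError(f"scale factor must be positive: {factor}")
        return LosSpec(self.mean_days * factor, self.sd_days * factor)


@dataclass(frozen=True)
class LognormalParams:
    """Lognormal parameters on the log scale (mu, sigma in log-days)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be non-negative: {self.sigma}")

    @property
    def mean(self) -> float:
        """Arithmetic mean of the distribution, in days."""
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def sd(self) -> float:
        """Arithmetic standard deviation of the distribution, in days."""
        # expm1 keeps precision for tiny sigma (near-degenerate distributions)
        return math.sqrt(
            math.expm1(self.sigma**2) * math.exp(2 * self.mu + self.sigma**2)
        )


def lognormal_from_moments(mean_days: float, sd_days: float) -> LognormalParams:
    """Convert a (mean, SD) in days to lognormal (mu, sigma) by moment matching.

    With ``cv = sd/mean``: ``sigma^2 = ln(1 + cv^2)`` and
    ``mu = ln(mean) - sigma^2 / 2``, so the lognormal reproduces the stated
    arithmetic moments exactly.  ``sd = 0`` degenerates to a point mass.
    """
    if not mean_days > 0:
        raise InvalidParameterError(f"mean_days must be positive, got {mean_days}")
    if sd_days < 0:
        raise InvalidParameterError(f"sd_days must be non-negative, got {sd_days}")
    sigma2 = math.log1p((sd_days / mean_days) ** 2)
    mu = math.log(mean_days) - sigma2 / 2
    return LognormalParams(mu=mu, sigma=math.sqrt(sigma2))


def sample_los(
    params: LognormalParams,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw length(s) of stay in days from a lognormal; strictly positive."""
    if params.sigma == 0.0:
        value = math.exp(params.mu)
        return value if size is None else np.full(size, value)
    return rng.lognormal(mean=params.mu, sigma=params.sigma, size=size)


@dataclass(frozen=True)
class CaseMix:
    """Two-level case mix: surgical class split, then within-class shares.

    The study cohort was 87% primary (p-THR 51%, p-TKR 38%, p-UKR 11%) and
    13% revision (r-THR 55%, r-TKR 45%).
    """

    primary_share: float
    within_primary: Mapping[str, float]
    within_revision: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.primary_share <= 1.0:
            raise InvalidParameterError(
                f"primary_share must lie in [0,1]: {self.primary_share}"
            )
        for name, shares, labels in (
            ("within_primary", self.within_primary, PRIMARY_PROCEDURES),
            ("within_revision", self.within_revision, REVISION_PROCEDURES),
        ):
            if set(shares) != set(labels):
                raise InvalidParameterError(
                    f"{name} must give shares for exactly {labels}, got {set(shares)}"
                )
            if any(not 0.0 <= s <= 1.0 for s in shares.values()):
                raise InvalidParameterError(f"{name} shares must lie in [0,1]")
            if not math.isclose(sum(shares.values()), 1.0, abs_tol=1e-9):
                raise InvalidParameterError(f"{name} shares must sum to 1")

    @property
    def revision_share(self) -> float:
        return 1.0 - self.primary_share

    def procedure_share(self, procedure: str) -> float:
        """Marginal probability of a given procedure label."""
        if procedure in PRIMARY_PROCEDURES:
            return self.primary_share * self.within_primary[procedure]
        if procedure in REVISION_PROCEDURES:
            return self.revision_share * self.within_revision[procedure]
        raise InvalidParameterError(f"unknown procedure label: {procedure!r}")


def sample_procedure(
    case_mix: CaseMix, surgical_class: str, rng: np.random.Generator
) -> str:
    """Draw a procedure label from the within-class categorical distribution."""
    if surgical_class == "primary":
        labels, shares = PRIMARY_PROCEDURES, case_mix.within_primary
    elif surgical_class == "revision":
        labels, shares = REVISION_PROCEDURES, case_mix.within_revision
    else:
        raise InvalidParameterError(
            f"surgical_class must be 'primary' or 'revision': {surgical_class!r}"
        )
    u = rng.random()
    cumulative = 0.0
    for label in labels:
        cumulative += shares[label]
        if u < cumulative:
            return label
    return labels[-1]


@dataclass(frozen=True)
class ModelParams:
    """All stochastic inputs: per-procedure LOS, delayed-stay LOS, routing, mix."""

    los_specs: Mapping[str, LosSpec]
    delayed_los: LosSpec
    prop_delayed: float
    case_mix: CaseMix

    def __post_init__(self) -> None:
        missing = set(PROCEDURES) - set(self.los_specs)
        if missing:
            raise InvalidParameterError(
                f"los_specs missing procedure(s): {sorted(missing)}"
            )
        if not 0.0 <= self.prop_delayed <= 1.0:
            raise InvalidParameterError(
                f"prop_delayed must lie in [0,1]: {self.prop_delayed}"
            )

    def lognormal(self, procedure: str) -> LognormalParams:
        spec = self.los_specs[procedure]
        return lognormal_from_moments(spec.mean_days, spec.sd_days)

    def delayed_lognormal(self) -> LognormalParams:
        return lognormal_from_moments(
            self.delayed_los.mean_days, self.delayed_los.sd_days
        )


@dataclass(frozen=True)
class EhrRecord:
    """One hospital spell: procedure performed, stay length, delayed flag."""

    patient_id: str
    procedure: str
    los_days: float
    delayed: bool

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise InvalidParameterError(
                f"unknown procedure label: {self.procedure!r}"
            )
        if not self.los_days > 0:
            raise InvalidParameterError(f"los_days must be positive: {self.los_days}")


# ---------------------------------------------------------------------------
# Baseline parameters
# ---------------------------------------------------------------------------

_YAML_KEYS = {  # YAML-safe keys <-> procedure labels
    "p_thr": "p-THR",
    "p_tkr": "p-TKR",
    "p_ukr": "p-UKR",
    "r_thr": "r-THR",
    "r_tkr": "r-TKR",
}
_LABEL_TO_KEY = {v: k for k, v in _YAML_KEYS.items()}


def _params_from_dict(doc: Mapping) -> ModelParams:
    try:
        los_specs = {
            _YAML_KEYS[key]: LosSpec(float(v["mean"]), float(v["sd"]))
            for key, v in doc["los_specs"].items()
        }
        delayed = LosSpec(
            float(doc["delayed_los"]["mean"]), float(doc["delayed_los"]["sd"])
        )
        cm = doc["case_mix"]
        case_mix = CaseMix(
            primary_share=float(cm["primary"]),
            within_primary={
                _YAML_KEYS[k]: float(v) for k, v in cm["within_primary"].items()
            },
            within_revision={
                _YAML_KEYS[k]: float(v) for k, v in cm["within_revision"].items()
            },
        )
        return ModelParams(
            los_specs=los_specs,
            delayed_los=delayed,
            prop_delayed=float(doc["prop_delayed"]),
            case_mix=case_mix,
        )
    except KeyError as exc:
        raise InvalidParameterError(f"parameter file missing key: {exc}") from exc


def _params_to_dict(params: ModelParams) -> dict:
    return {
        "los_specs": {
            _LABEL_TO_KEY[label]: {"mean": spec.mean_days, "sd": spec.sd_days}
            for label, spec in params.los_specs.items()
        },
        "delayed_los": {
            "mean": params.delayed_los.mean_days,
            "sd": params.delayed_los.sd_days,
        },
        "prop_delayed": params.prop_delayed,
        "case_mix": {
            "primary": params.case_mix.primary_share,
            "revision": params.case_mix.revision_share,
            "within_primary": {
                _LABEL_TO_KEY[k]: v for k, v in params.case_mix.within_primary.items()
            },
            "within_revision": {
                _LABEL_TO_KEY[k]: v for k, v in params.case_mix.within_revision.items()
            },
        },
    }


def load_params(path: str | Path) -> ModelParams:
    """Load model parameters from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise InvalidParameterError(f"parameter file {path} is not a mapping")
    return _params_from_dict(doc)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write model parameters to a YAML file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)


def baseline_params() -> ModelParams:
    """Baseline parameters of the study unit, read from the packaged YAML.

    Means/SDs in days: p-THR 4.4/2.9, p-TKR 4.7/2.8, p-UKR 2.9/2.1,
    r-THR 6.9/7.0, r-TKR 7.2/7.6; delayed stays 16.5/15.1; 7.6% of patients
    delayed; case mix 87/13 primary/revision.
    """
    text = resources.files("orthosim").joinpath("data/baseline_params.yaml").read_text()
    return _params_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Fitting and synthetic EHR generation
# ---------------------------------------------------------------------------

def fit_los_parameters(
    records: Sequence[EhrRecord],
    delayed_fallback: LosSpec | None = None,
) -> ModelParams:
    """Fit model parameters from spell records by sample moments.

    Per-procedure mean/SD are computed over *non-delayed* spells; the delayed
    distribution over delayed spells; ``prop_delayed`` is the delayed fraction
    of all records.  The case mix is the empirical two-level label frequency.

    Raises :class:`FittingError` if any procedure has no non-delayed record.
    With zero delayed records, ``prop_delayed`` is 0 and ``delayed_los`` falls
    back to ``delayed_fallback`` (default: the baseline delayed spec) with a
    warning.
    """
    if not records:
        raise FittingError("no records supplied")

    frame = ehr_to_frame(records)
    non_delayed = frame[~frame["delayed"].astype(bool)]
    delayed = frame[frame["delayed"].astype(bool)]

    los_specs: dict[str, LosSpec] = {}
    for label in PROCEDURES:
        los = non_delayed.loc[non_delayed["procedure"] == label, "los_days"]
        if los.empty:
            raise FittingError(f"no non-delayed records for procedure {label!r}")
        sd = float(los.std(ddof=1)) if len(los) > 1 else 0.0
        los_specs[label] = LosSpec(float(los.mean()), sd)

    if delayed.empty:
        fallback = delayed_fallback or baseline_params().delayed_los
        warnings.warn(
            "no delayed records: prop_delayed set to 0 and delayed_los falls "
            "back to the configured default",
            stacklevel=2,
        )
        delayed_spec = fallback
    else:
        sd = float(delayed["los_days"].std(ddof=1)) if len(delayed) > 1 else 0.0
        delayed_spec = LosSpec(float(delayed["los_days"].mean()), sd)

    counts = frame["procedure"].value_counts()
    n_primary = int(sum(counts.get(lab, 0) for lab in PRIMARY_PROCEDURES))
    n_revision = int(sum(counts.get(lab, 0) for lab in REVISION_PROCEDURES))
    # Degenerate classes keep the baseline within-class split so CaseMix stays valid.
    base_mix = baseline_params().case_mix
    within_primary = (
        {lab: counts.get(lab, 0) / n_primary for lab in PRIMARY_PROCEDURES}
        if n_primary
        else dict(base_mix.within_primary)
    )
    within_revision = (
        {lab: counts.get(lab, 0) / n_revision for lab in REVISION_PROCEDURES}
        if n_revision
        else dict(base_mix.within_revision)
    )
    case_mix = CaseMix(
        primary_share=n_primary / len(frame),
        within_primary=within_primary,
        within_revision=within_revision,
    )
    return ModelParams(
        los_specs=los_specs,
        delayed_los=delayed_spec,
        prop_delayed=len(delayed) / len(frame),
        case_mix=case_mix,
    )


def generate_synthetic_ehr(
    params: ModelParams,
    n: int,
    seed: int | np.random.Generator,
) -> list[EhrRecord]:
    """Generate ``n`` synthetic spell records from the model parameters.

    Each record draws its surgical class and procedure from the case mix, a
    Bernoulli(``prop_delayed``) delayed flag, and a stay from the matching
    lognormal (delayed spells from the delayed distribution).  Deterministic
    for a fixed integer seed.
    """
    if n < 0:
        raise InvalidParameterError(f"n must be non-negative, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    labels = list(PROCEDURES)
    marginal = np.array([params.case_mix.procedure_share(lab) for lab in labels])
    marginal = marginal / marginal.sum()
    proc_idx = rng.choice(len(labels), size=n, p=marginal)
    delayed_flags = rng.random(n) < params.prop_delayed

    lognormals = {lab: params.lognormal(lab) for lab in labels}
    delayed_ln = params.delayed_lognormal()
    records = []
    for i in range(n):
        label = labels[proc_idx[i]]
        ln = delayed_ln if delayed_flags[i] else lognormals[label]
        los = float(sample_los(ln, rng))
        records.append(
            EhrRecord(
                patient_id=f"synth-{i:06d}",
                procedure=label,
                los_days=los,
                delayed=bool(delayed_flags[i]),
            )
        )
    return records


def generate_reference_cohort(seed: int | np.random.Generator = 0) -> list[EhrRecord]:
    """Synthetic stand-in for the study cohort with its exact marginal counts.

    Produces 6,912 records with per-procedure counts 3057/2302/679/482/392 and
    exactly 529 delayed spells, so the fitted delayed proportion is exactly
    529/6912 (7.65%).  Stay lengths are synthetic draws from the baseline
    distributions; only the counts mirror the cohort.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = baseline_params()
    total = sum(REFERENCE_COHORT_COUNTS.values())

    labels = np.repeat(
        list(REFERENCE_COHORT_COUNTS),
        list(REFERENCE_COHORT_COUNTS.values()),
    )
    delayed = np.zeros(total, dtype=bool)
    delayed[:REFERENCE_COHORT_DELAYED] = True
    rng.shuffle(labels)
    rng.shuffle(delayed)

    lognormals = {lab: params.lognormal(lab) for lab in PROCEDURES}
    delayed_ln = params.delayed_lognormal()
    records = []
    for i in range(total):
        ln = delayed_ln if delayed[i] else lognormals[labels[i]]
        records.append(
            EhrRecord(
                patient_id=f"cohort-{i:06d}",
                procedure=str(labels[i]),
                los_days=float(sample_los(ln, rng)),
                delayed=bool(delayed[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# EHR CSV round-trip
# ---------------------------------------------------------------------------

def ehr_to_frame(records: Iterable[EhrRecord]) -> pd.DataFrame:
    """Tabulate records with columns patient_id, procedure, los_days, delayed."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "procedure": r.procedure,
                "los_days": r.los_days,
                "delayed": int(r.delayed),
            }
            for r in records
        ],
        columns=["patient_id", "procedure", "los_days", "delayed"],
    )


def frame_to_records(frame: pd.DataFrame) -> list[EhrRecord]:
    return [
        EhrRecord(
            patient_id=str(row.patient_id),
            procedure=str(row.procedure),
            los_days=float(row.los_days),
            delayed=bool(int(row.delayed)),
        )
        for row in frame.itertuples(index=False)
    ]


def save_ehr_csv(records: Iterable[EhrRecord], path: str | Path) -> None:
    ehr_to_frame(records).to_csv(path, index=False)


def load_ehr_csv(path: str | Path) -> list[EhrRecord]:
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))
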
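"""Data model for randomized two-arm trials and a synthetic trial generator.

A trial holds, per subject: an arm label (``"T"`` or ``"C"``, the assignment
vector Z), an integer enrollment stratum (the enrollment period relative to a
potential adaptation; a single stratum means the blind was complete
throughout), and one or more outcome columns (the outcome data Y).  Missing
outcome values are ``NaN`` in memory and a configurable token (default: empty
string) on disk.

The generator draws outcomes from a Gaussian copula with configurable margins
per endpoint: continuous (arm-specific mean, common SD), binary (arm-specific
event probability), or a "drug level" endpoint that is positive for every
treated subject and exactly zero for every control — the construct that
completely unblinds anyone who looks at it.  Missingness can differ by arm,
which is exactly the mechanism that can invalidate blinded adaptation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

ARM_TREATMENT = "T"
ARM_CONTROL = "C"

#: Token written for missing cells in CSV files (and accepted when reading).
DEFAULT_MISSING_TOKEN = ""


class ValidationError(ValueError):
    """Raised when trial data violates its invariants."""


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


# ---------------------------------------------------------------------------
# TrialData
# ---------------------------------------------------------------------------


@dataclass
class TrialData:
    """Per-subject data of a randomized two-arm trial.

    Parameters
    ----------
    subject_id
        Unique subject identifiers.
    arm
        Assignment labels, ``"T"`` or ``"C"`` (the vector Z).
    stratum
        Integer enrollment-stratum labels; contiguous from 1.  A single
        stratum means arm totals were unknown until the end (fully blinded).
    outcomes
        Mapping endpoint name -> float array; ``NaN`` marks missing (Y).
    binary_endpoints
        Names of endpoints restricted to {0, 1, missing}.
    """

    subject_id: np.ndarray
    arm: np.ndarray
    stratum: np.ndarray
    outcomes: dict[str, np.ndarray]
    binary_endpoints: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.arm = np.asarray(self.arm, dtype=object)
        self.stratum = np.asarray(self.stratum, dtype=int)
        self.outcomes = {k: np.asarray(v, dtype=float) for k, v in self.outcomes.items()}
        self.binary_endpoints = tuple(self.binary_endpoints)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = len(self.subject_id)
        if n < 2:
            raise ValidationError(f"need at least 2 subjects, got {n}")
        if len(set(self.subject_id.tolist())) != n:
            raise ValidationError("duplicate subject_id")
        for name, col in [("arm", self.arm), ("stratum", self.stratum)]:
            if len(col) != n:
                raise ValidationError(f"length of {name} ({len(col)}) != n ({n})")
        bad = [i for i, a in enumerate(self.arm) if a not in (ARM_TREATMENT, ARM_CONTROL)]
        if bad:
            raise ValidationError(
                f"unknown arm label {self.arm[bad[0]]!r} in row {bad[0]}"
            )
        strata = np.unique(self.stratum)
        if not np.array_equal(strata, np.arange(1, len(strata) + 1)):
            raise ValidationError(
                f"strata must be contiguous integers starting at 1, got {strata.tolist()}"
            )
        for name, col in self.outcomes.items():
            if len(col) != n:
                raise ValidationError(f"endpoint {name!r} has length {len(col)} != n ({n})")
        for name in self.binary_endpoints:
            if name not in self.outcomes:
                raise ValidationError(f"binary endpoint {name!r} not among outcomes")
            col = self.outcomes[name]
            ok = np.isnan(col) | (col == 0.0) | (col == 1.0)
            if not ok.all():
                raise ValidationError(f"binary endpoint {name!r} has values outside {{0,1,NaN}}")

    # -- convenience accessors ------------------------------------------

    @property
    def n(self) -> int:
        return len(self.subject_id)

    @property
    def endpoint_names(self) -> tuple[str, ...]:
        return tuple(self.outcomes)

    @property
    def arm_mask(self) -> np.ndarray:
        """Boolean mask, True where the subject is in the treatment arm."""
        return self.arm == ARM_TREATMENT

    @property
    def n_T(self) -> int:
        return int(self.arm_mask.sum())

    @property
    def n_C(self) -> int:
        return self.n - self.n_T

    @property
    def n_strata(self) -> int:
        return int(self.stratum.max())

    def per_stratum_counts(self) -> tuple[tuple[int, int], ...]:
        """(n_T, n_C) within each stratum, in stratum order."""
        out = []
        for s in range(1, self.n_strata + 1):
            in_s = self.stratum == s
            n_t = int((self.arm_mask & in_s).sum())
            out.append((n_t, int(in_s.sum()) - n_t))
        return tuple(out)

    def relabeled(self) -> "TrialData":
        """Copy with T and C labels swapped (for blinding-contract checks)."""
        swapped = np.where(self.arm == ARM_TREATMENT, ARM_CONTROL, ARM_TREATMENT)
        return TrialData(
            subject_id=self.subject_id.copy(),
            arm=swapped.astype(object),
            stratum=self.stratum.copy(),
            outcomes={k: v.copy() for k, v in self.outcomes.items()},
            binary_endpoints=self.binary_endpoints,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "subject_id": self.subject_id,
            "arm": self.arm,
            "stratum": self.stratum,
        }
        data.update(self.outcomes)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# CSV I/O (RFC-4180 dialect via pandas, UTF-8, header required)
# ---------------------------------------------------------------------------


def read_trial(
    path,
    *,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    binary_endpoints: Sequence[str] = (),
) -> TrialData:
    """Read a trial from CSV.

    The file must have a header row with ``subject_id``, ``arm`` and
    ``stratum`` columns; every remaining column is an endpoint.  Cells equal
    to ``missing_token`` are read as missing.
    """
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=[missing_token],
        encoding="utf-8",
    )
    required = ["subject_id", "arm", "stratum"]
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    endpoints = [c for c in df.columns if c not in required]
    arm = df["arm"].to_numpy(dtype=object)
    bad = [i for i, a in enumerate(arm) if a not in (ARM_TREATMENT, ARM_CONTROL)]
    if bad:
        raise ValidationError(f"unknown arm label {arm[bad[0]]!r} in data row {bad[0]}")
    try:
        stratum = df["stratum"].astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer stratum label: {exc}") from exc
    outcomes = {}
    for name in endpoints:
        try:
            outcomes[name] = df[name].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric value in endpoint {name!r}: {exc}") from exc
    return TrialData(
        subject_id=df["subject_id"].to_numpy(dtype=object),
        arm=arm,
        stratum=stratum,
        outcomes=outcomes,
        binary_endpoints=tuple(binary_endpoints),
    )


def write_trial(trial: TrialData, path, *, missing_token: str = DEFAULT_MISSING_TOKEN) -> None:
    """Write a trial to CSV; round-trips cell-for-cell through `read_trial`."""
    df = trial.to_frame()
    for name in trial.binary_endpoints:
        # keep binary cells as integers on disk so the table round-trips cleanly
        col = df[name]
        df[name] = col.map(lambda v: "" if pd.isna(v) else str(int(v)))
        df[name] = df[name].replace("", np.nan)
    df.to_csv(path, index=False, na_rep=missing_token, encoding="utf-8")


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

CONTINUOUS = "continuous"
BINARY = "binary"
DRUG_LEVEL = "drug_level"


@dataclass(frozen=True)
class EndpointSpec:
    """Marginal distribution of one endpoint, by arm.

    kind ``"continuous"``: Gaussian with ``mean_T``/``mean_C`` and common
    ``sd``.  kind ``"binary"``: Bernoulli with ``p_T``/``p_C``.  kind
    ``"drug_level"``: log-normal (positive) for treated subjects, exactly 0
    for controls — values, not labels, betray the assignment.
    """

    kind: str = CONTINUOUS
    mean_T: float = 0.0
    mean_C: float = 0.0
    sd: float = 1.0
    p_T: float = 0.5
    p_C: float = 0.5
    missing_T: float = 0.0
    missing_C: float = 0.0

    def validate(self, name: str) -> None:
        if self.kind not in (CONTINUOUS, BINARY, DRUG_LEVEL):
            raise ConfigError(f"endpoint {name!r}: unknown kind {self.kind!r}")
        if self.kind == CONTINUOUS and self.sd < 0:
            raise ConfigError(f"endpoint {name!r}: sd must be >= 0")
        for p, label in [
            (self.p_T, "p_T"),
            (self.p_C, "p_C"),
            (self.missing_T, "missing_T"),
            (self.missing_C, "missing_C"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"endpoint {name!r}: {label}={p} outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-trial recipe: per-stratum arm sizes, endpoint margins,
    a cross-endpoint latent correlation matrix, and a seed."""

    strata: tuple[tuple[int, int], ...] = ((3, 3),)
    endpoints: Mapping[str, EndpointSpec] = field(default_factory=dict)
    correlation: Sequence[Sequence[float]] | None = None
    seed: int | None = None

    def validate(self) -> None:
        if not self.endpoints:
            raise ConfigError("at least one endpoint required")
        total = 0
        for s, (n_t, n_c) in enumerate(self.strata, start=1):
            if n_t < 0 or n_c < 0:
                raise ConfigError(f"stratum {s}: negative arm size")
            if n_t + n_c < 1:
                raise ConfigError(f"stratum {s}: empty stratum")
            total += n_t + n_c
        if total < 2:
            raise ConfigError("total sample size must be >= 2")
        for name, spec in self.endpoints.items():
            spec.validate(name)
        if self.correlation is not None:
            k = len(self.endpoints)
            R = np.asarray(self.correlation, dtype=float)
            if R.shape != (k, k):
                raise ConfigError(f"correlation matrix must be {k}x{k}, got {R.shape}")
            if not np.allclose(R, R.T):
                raise ConfigError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0):
                raise ConfigError("correlation matrix diagonal must be 1")
            if np.linalg.eigvalsh(R).min() < -1e-9:
                raise ConfigError("correlation matrix not positive semi-definite")

    def _corr_root(self) -> np.ndarray:
        k = len(self.endpoints)
        if self.correlation is None:
            return np.eye(k)
        R = np.asarray(self.correlation, dtype=float)
        # eigen square root tolerates the semi-definite boundary
        vals, vecs = np.linalg.eigh(R)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def config_from_dict(d: Mapping) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain (JSON-loaded) mapping."""
    endpoints = {
        name: EndpointSpec(**spec) for name, spec in d.get("endpoints", {}).items()
    }
    strata = tuple(tuple(int(x) for x in pair) for pair in d.get("strata", [[3, 3]]))
    return GeneratorConfig(
        strata=strata,
        endpoints=endpoints,
        correlation=d.get("correlation"),
        seed=d.get("seed"),
    )


def config_from_json(path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_trial(
    config: GeneratorConfig,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> TrialData:
    """Draw one synthetic trial.

    Reproducible: a given ``seed`` (or ``config.seed`` when ``seed`` is None)
    yields a bit-identical trial.  Within each stratum the enrollment order of
    arms is shuffled so position carries no assignment information.  Under a
    strong-null configuration (identical margins per arm, no arm-dependent
    missingness) the joint outcome distribution does not depend on the arm.
    """
    config.validate()
    if rng is None:
        if seed is None:
            seed = config.seed
        rng = np.random.default_rng(seed)

    names = list(config.endpoints)
    L = config._corr_root()
    ids: list[str] = []
    arms: list[str] = []
    strat: list[int] = []
    cols: dict[str, list[np.ndarray]] = {name: [] for name in names}
    counter = 0
    for s, (n_t, n_c) in enumerate(config.strata, start=1):
        n = n_t + n_c
        arm = np.array([ARM_TREATMENT] * n_t + [ARM_CONTROL] * n_c, dtype=object)
        arm = arm[rng.permutation(n)]
        treated = arm == ARM_TREATMENT
        latent = rng.standard_normal((n, len(names))) @ L.T
        for j, name in enumerate(names):
            spec = config.endpoints[name]
            u = latent[:, j]
            if spec.kind == CONTINUOUS:
                mu = np.where(treated, spec.mean_T, spec.mean_C)
                y = mu + spec.sd * u
            elif spec.kind == BINARY:
                cut = np.where(treated, ndtri(spec.p_T), ndtri(spec.p_C))
                y = (u < cut).astype(float)
            else:  # drug level: positive iff treated
                y = np.where(treated, np.exp(u), 0.0)
            miss_rate = np.where(treated, spec.missing_T, spec.missing_C)
            miss = rng.random(n) < miss_rate
            y = np.where(miss, np.nan, y)
            cols[name].append(y)
        ids.extend(f"S{counter + i + 1:05d}" for i in range(n))
        counter += n
        arms.extend(arm.tolist())
        strat.extend([s] * n)

    binary = tuple(n for n in names if config.endpoints[n].kind == BINARY)
    return TrialData(
        subject_id=np.array(ids, dtype=object),
        arm=np.array(arms, dtype=object),
        stratum=np.array(strat, dtype=int),
        outcomes={name: np.concatenate(cols[name]) for name in names},
        binary_endpoints=binary,
    )
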
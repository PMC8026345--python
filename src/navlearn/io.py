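"""Canonical data model, trial-table I/O, posterior stores, run configuration.

The canonical on-disk format for behavioral data is a UTF-8 CSV with one
row per scheduled pointing trial (timeouts included as rows with
``missing=True``, because the state-space model needs their block/trial
position).  Angles are stored in degrees throughout; signed errors live
in (-180, 180] with positive values meaning a clockwise overshoot past
the target direction.  Absent numeric values are encoded as empty cells.

Posterior stores are language-neutral: a tidy long CSV of draws
(columns ``chain, draw, parameter, value``) plus a JSON sidecar with
sampler metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("navlearn")

AGE_GROUPS = ("young", "old")
INTERSECTIONS = ("I1", "I2", "I3", "I4")
DIRECTIONS = ("D1", "D2", "D3", "D4")
TARGETS = ("T1", "T2")
TRIAL_KINDS = ("retrieval", "control")

#: Canonical column order of the trial-table CSV.
TRIAL_COLUMNS = [
    "subject_id",
    "age_group",
    "block",
    "trial_in_block",
    "intersection",
    "direction",
    "target",
    "trial_kind",
    "abs_error",
    "signed_error",
    "response_time",
    "missing",
]

_ANGLE_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or has the wrong shape."""


class ValidationError(ValueError):
    """A row violates the trial-record invariants."""


class ConfigError(ValueError):
    """Invalid run configuration."""


class StoreError(RuntimeError):
    """A posterior store is corrupted or incomplete."""


@dataclass(frozen=True)
class TrialRecord:
    """One pointing trial.

    ``abs_error`` is the unsigned angular deviation of the response from
    the true target direction (degrees, [0, 180]); ``signed_error`` the
    signed deviation in (-180, 180].  Both are ``None`` exactly when the
    trial timed out (``missing=True``).
    """

    subject_id: str
    age_group: str
    block: int
    trial_in_block: int
    intersection: str
    direction: str
    target: str
    trial_kind: str = "retrieval"
    abs_error: float | None = None
    signed_error: float | None = None
    response_time: float | None = None
    missing: bool = False

    def validate(self, n_blocks: int | None = None, timeout: float | None = None) -> None:
        """Raise :class:`ValidationError` if any invariant is violated."""
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age_group {self.age_group!r}")
        if self.intersection not in INTERSECTIONS:
            raise ValidationError(f"unknown intersection {self.intersection!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.target not in TARGETS:
            raise ValidationError(f"unknown target {self.target!r}")
        if self.trial_kind not in TRIAL_KINDS:
            raise ValidationError(f"unknown trial_kind {self.trial_kind!r}")
        if self.block < 1:
            raise ValidationError(f"block must be >= 1, got {self.block}")
        if n_blocks is not None and self.block > n_blocks:
            raise ValidationError(
                f"block {self.block} outside schedule with {n_blocks} blocks"
            )
        if self.trial_in_block < 1:
            raise ValidationError(
                f"trial_in_block must be >= 1, got {self.trial_in_block}"
            )
        if self.missing:
            if self.abs_error is not None or self.signed_error is not None:
                raise ValidationError("missing trial must not carry an error value")
        else:
            if self.abs_error is None:
                raise ValidationError("observed trial lacks abs_error")
            if not 0.0 <= self.abs_error <= 180.0:
                raise ValidationError(
                    f"abs_error {self.abs_error} outside [0, 180]"
                )
            if self.signed_error is not None:
                if not -180.0 < self.signed_error <= 180.0 + _ANGLE_TOL:
                    raise ValidationError(
                        f"signed_error {self.signed_error} outside (-180, 180]"
                    )
                if abs(abs(self.signed_error) - self.abs_error) > _ANGLE_TOL:
                    raise ValidationError(
                        "abs_error must equal |signed_error| "
                        f"({self.abs_error} vs {self.signed_error})"
                    )
            if self.response_time is not None:
                if self.response_time <= 0:
                    raise ValidationError(
                        f"response_time {self.response_time} must be positive"
                    )
                if timeout is not None and self.response_time > timeout + 1e-9:
                    raise ValidationError(
                        f"response_time {self.response_time} exceeds timeout {timeout}"
                    )


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC sampler settings (shared by both state-space models)."""

    chains: int = 4
    iterations: int = 1000
    warmup: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.chains < 2:
            raise ConfigError(f"need >= 2 chains, got {self.chains}")
        if not 0 < self.warmup < self.iterations:
            raise ConfigError(
                f"warmup ({self.warmup}) must be in (0, iterations={self.iterations})"
            )

    @property
    def draws_per_chain(self) -> int:
        return self.iterations - self.warmup

    @property
    def total_draws(self) -> int:
        """Post-warmup draws pooled over chains."""
        return self.chains * self.draws_per_chain


#: Sampler settings of the original published analyses: four chains of 4000
#: iterations with 2000 warmup, i.e. 8000 post-warmup draws.
PUBLISHED_SAMPLER = SamplerConfig(chains=4, iterations=4000, warmup=2000, seed=0)

#: Lighter desk-scale default for tests and examples.
TEST_SAMPLER = SamplerConfig(chains=4, iterations=1000, warmup=500, seed=0)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    preset: str = "behavioral"
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    k_range: tuple[int, int] = (3, 7)
    cv_folds: int = 10
    chance_level: float = 90.0
    n_young: int = 25
    n_old: int = 32

    def validate(self) -> None:
        if self.preset not in ("behavioral", "fmri"):
            raise ConfigError(f"unknown schedule preset {self.preset!r}")
        self.sampler.validate()
        k_lo, k_hi = self.k_range
        n = self.n_young + self.n_old
        if not 2 <= k_lo <= k_hi <= n - 1:
            raise ConfigError(f"k_range {self.k_range} outside [2, {n - 1}]")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.chance_level <= 0:
            raise ConfigError("chance_level must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sampler" in d and isinstance(d["sampler"], dict):
            d["sampler"] = SamplerConfig(**d["sampler"])
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a JSON or YAML document."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@contextmanager
def log_stage(stage: str, **context):
    """Log entry/exit of a pipeline stage with wall-clock timing."""
    t0 = time.perf_counter()
    logger.info("stage=%s start %s", stage, context or "")
    try:
        yield
    finally:
        logger.info("stage=%s done in %.2fs", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to a canonical-column DataFrame."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    """Convert a canonical DataFrame back to :class:`TrialRecord` objects."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                age_group=str(row.age_group),
                block=int(row.block),
                trial_in_block=int(row.trial_in_block),
                intersection=str(row.intersection),
                direction=str(row.direction),
                target=str(row.target),
                trial_kind=str(row.trial_kind),
                abs_error=None if pd.isna(row.abs_error) else float(row.abs_error),
                signed_error=None
                if pd.isna(row.signed_error)
                else float(row.signed_error),
                response_time=None
                if pd.isna(row.response_time)
                else float(row.response_time),
                missing=bool(row.missing),
            )
        )
    return records


def validate_frame(
    df: pd.DataFrame,
    n_blocks: int | None = None,
    timeout: float | None = None,
) -> None:
    """Validate every row of a canonical trial table.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (naming the offending row index) for rows
    violating the record invariants.
    """
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trial table lacks required column {col!r}")
    for idx, rec in zip(df.index, frame_to_records(df)):
        try:
            rec.validate(n_blocks=n_blocks, timeout=timeout)
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None


def read_trial_table(
    path: str | Path,
    n_blocks: int | None = None,
    timeout: float | None = None,
) -> pd.DataFrame:
    """Read and validate a canonical trial-table CSV.

    Returns a DataFrame sorted by (subject_id, block, trial_in_block);
    use :func:`frame_to_records` for record-level access.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    validate_frame(df, n_blocks=n_blocks, timeout=timeout)
    df = df.sort_values(
        ["subject_id", "block", "trial_in_block"], kind="stable"
    ).reset_index(drop=True)
    return df[TRIAL_COLUMNS]


def write_trial_table(
    trials: pd.DataFrame | Iterable[TrialRecord], path: str | Path
) -> Path:
    """Write a trial table as canonical CSV (empty cells for absent values)."""
    if not isinstance(trials, pd.DataFrame):
        trials = records_to_frame(trials)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees binary round-trip of float64 cells
    trials[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    return path


def block_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-block observed-trial means and missingness counts.

    ``block_mean_error`` is computed over observed retrieval trials only;
    it is the location anchor for the prior imputation of missing trials.
    """
    retrieval = trials[trials["trial_kind"] == "retrieval"]
    rows = []
    for (subject, block), grp in retrieval.groupby(["subject_id", "block"], sort=True):
        observed = grp[~grp["missing"].astype(bool)]
        rows.append(
            {
                "subject_id": subject,
                "block": int(block),
                "block_mean_error": float(observed["abs_error"].mean())
                if len(observed)
                else math.nan,
                "n_observed": int(len(observed)),
                "n_missing": int(grp["missing"].astype(bool).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior stores
# ---------------------------------------------------------------------------


def persist_posterior(posterior, path: str | Path) -> Path:
    """Write a posterior to ``path`` (a directory) as tidy CSV + JSON sidecar.

    The long CSV has columns ``chain, draw, parameter, value`` with
    parameter names like ``mu[1]`` or ``sigma_y``; the sidecar records the
    model variant and sampler metadata.  The store round-trips losslessly
    (floats are written with shortest round-trip repr).
    """
    params = posterior.param_dict()
    n_chains, n_draws = posterior.sigma_y.shape
    if n_chains * n_draws == 0:
        raise ValueError("refusing to persist an empty posterior")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    names: list[str] = []
    cols: list[np.ndarray] = []
    for base, arr in params.items():
        if arr is None:
            continue
        if arr.ndim == 2:
            names.append(base)
            cols.append(arr.reshape(n_chains * n_draws, 1))
        else:
            names.extend(f"{base}[{i + 1}]" for i in range(arr.shape[2]))
            cols.append(arr.reshape(n_chains * n_draws, arr.shape[2]))
    values = np.concatenate(cols, axis=1)  # (chain*draw, n_params)
    chain_idx = np.repeat(np.arange(n_chains), n_draws * len(names))
    draw_idx = np.tile(np.repeat(np.arange(n_draws), len(names)), n_chains)
    long = pd.DataFrame(
        {
            "chain": chain_idx,
            "draw": draw_idx,
            "parameter": np.tile(np.asarray(names, dtype=object), n_chains * n_draws),
            "value": values.reshape(-1),
        }
    )
    long.to_csv(path / "draws.csv", index=False, float_format="%.17g")
    meta = dict(posterior.meta)
    meta.update(
        model=posterior.model,
        chains=n_chains,
        draws_per_chain=n_draws,
        total_draws=n_chains * n_draws,
        parameters=names,
    )
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_posterior(path: str | Path):
    """Read a posterior store written by :func:`persist_posterior`.

    Raises :class:`StoreError` on truncated or inconsistent stores; no
    partial object is returned.
    """
    from navlearn.statespace import StateSpacePosterior

    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
        long = pd.read_csv(path / "draws.csv", float_precision="round_trip")
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise StoreError(f"cannot read posterior store at {path}: {exc}") from exc
    names = meta.pop("parameters")
    n_chains = meta.pop("chains")
    n_draws = meta.pop("draws_per_chain")
    meta.pop("total_draws", None)
    model = meta.pop("model")
    expected = n_chains * n_draws * len(names)
    if len(long) != expected:
        raise StoreError(
            f"posterior store at {path} is truncated: "
            f"{len(long)} rows, expected {expected}"
        )
    try:
        values = long["value"].to_numpy(float).reshape(n_chains, n_draws, len(names))
    except ValueError as exc:
        raise StoreError(f"malformed draws at {path}: {exc}") from exc

    def gather(base: str) -> np.ndarray | None:
        idx = [i for i, n in enumerate(names) if n == base or n.startswith(base + "[")]
        if not idx:
            return None
        arr = values[:, :, idx]
        return arr[:, :, 0] if names[idx[0]] == base else arr

    return StateSpacePosterior(
        model=model,
        mu=gather("mu"),
        eta=gather("eta"),
        sigma_mu=gather("sigma_mu"),
        sigma_eta=gather("sigma_eta"),
        sigma_y=gather("sigma_y"),
        meta=meta,
    )
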
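"""Synthetic herd generator calibrated to the reference population.

Each biotype x sex cell is drawn from a multivariate Gaussian over the
17 measurements with mean vector = biotype trait means (times an
optional per-trait male multiplier) and covariance ``D R D`` where
``D = diag(CV%/100 * mean)`` and ``R`` is the target correlation matrix.
Draws with any non-positive coordinate are rejected and redrawn —
negligible truncation at the calibrated CVs (<= 11.32%), which is why a
truncated Gaussian was preferred over a log-normal: first and second
moments stay directly interpretable as the configured means and CVs.

The qualitative correlation pattern (sign/strength classes) need not be
positive definite, so the assembled target matrix is repaired with
Higham's alternating-projections nearest-correlation algorithm before
use.

Determinism: a fixed ``(config, seed)`` reproduces the identical herd
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import calibration
from .io import write_records
from .schema import AnimalRecord, Biotype, Sex


class CorrelationError(ValueError):
    """Input matrix violates the correlation-matrix contract."""


def assemble_correlation(
    spec: Mapping[tuple[str, str], float] | None = None,
    traits: Sequence[str] = calibration.MEASUREMENTS,
) -> np.ndarray:
    """Dense symmetric target matrix from a sparse pair specification."""
    spec = calibration.REFERENCE_CORRELATION_SPEC if spec is None else spec
    index = {t: i for i, t in enumerate(traits)}
    matrix = np.eye(len(traits))
    for (a, b), value in spec.items():
        if a not in index or b not in index:
            raise KeyError(f"unknown trait in correlation pair ({a}, {b})")
        if a == b:
            raise CorrelationError(f"self-pair ({a}, {a}) not allowed")
        if not -1.0 <= value <= 1.0:
            raise CorrelationError(f"correlation {value} outside [-1, 1]")
        matrix[index[a], index[b]] = matrix[index[b], index[a]] = value
    return matrix


def nearest_correlation(
    matrix: np.ndarray,
    *,
    tol: float = 1e-12,
    max_iter: int = 500,
    min_eig: float = 1e-8,
) -> np.ndarray:
    """Nearest correlation matrix by Higham alternating projections.

    Alternates projection onto the positive-semidefinite cone
    (eigenvalue clipping, with a Dykstra correction so the iteration
    converges to the *nearest* point, not just *a* point) and onto the
    unit-diagonal affine set.  The result has minimum eigenvalue
    >= ``min_eig`` and is (numerically) idempotent on already-PD
    inputs.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise CorrelationError("matrix must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise CorrelationError("matrix must be symmetric")
    if not np.allclose(np.diag(A), 1.0, atol=1e-12):
        raise CorrelationError("matrix must have a unit diagonal")
    if np.any(np.abs(A) > 1.0 + 1e-12):
        raise CorrelationError("entries must lie in [-1, 1]")

    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(max_iter):
        R = Y - dS
        eigval, eigvec = np.linalg.eigh((R + R.T) / 2.0)
        X = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
        dS = X - R
        Y_next = X.copy()
        np.fill_diagonal(Y_next, 1.0)
        if np.linalg.norm(Y_next - Y, ord="fro") <= tol * max(
            1.0, np.linalg.norm(Y, ord="fro")
        ):
            Y = Y_next
            break
        Y = Y_next

    # enforce the eigenvalue floor, then restore the unit diagonal
    eigval, eigvec = np.linalg.eigh((Y + Y.T) / 2.0)
    if eigval.min() < min_eig:
        eigval = np.clip(eigval, min_eig, None)
        Y = (eigvec * eigval) @ eigvec.T
        d = np.sqrt(np.diag(Y))
        Y = Y / np.outer(d, d)
    Y = (Y + Y.T) / 2.0
    np.fill_diagonal(Y, 1.0)
    return Y


@dataclass(frozen=True)
class HerdConfig:
    """Full parameterization of a synthetic population.

    Defaults reproduce the reference population: 95 animals in six
    biotype x sex cells (females 53/16/14, males 4/4/4), per-biotype
    trait means, one pooled CV% per trait applied within biotype, the
    qualitative correlation pattern (repaired to positive definite),
    and no sex effect (per-sex trait means are not published for the
    calibration population; the multiplier exists for sensitivity
    studies).
    """

    cell_sizes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(calibration.REFERENCE_GROUP_SIZES)
    )
    trait_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            b: dict(m) for b, m in calibration.REFERENCE_TRAIT_MEANS.items()
        }
    )
    trait_cv: Mapping[str, float] = field(
        default_factory=lambda: dict(calibration.REFERENCE_TRAIT_CV)
    )
    correlation: np.ndarray | None = None
    male_multiplier: float | Mapping[str, float] = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for key, size in self.cell_sizes.items():
            if size < 0:
                raise ValueError(f"negative cell size for {key}")
        for biotype, means in self.trait_means.items():
            for trait, mean in means.items():
                if mean <= 0:
                    raise ValueError(
                        f"non-positive mean {trait}={mean} for {biotype}"
                    )
        for trait, cv in self.trait_cv.items():
            if cv <= 0:
                raise ValueError(f"non-positive CV for {trait}")
        if self.correlation is None:
            repaired = nearest_correlation(assemble_correlation())
        else:
            repaired = nearest_correlation(np.asarray(self.correlation))
        object.__setattr__(self, "correlation", repaired)

    def scaled_to(self, total: int) -> "HerdConfig":
        """Config with cell sizes scaled proportionally to ~``total``."""
        current = sum(self.cell_sizes.values())
        if current == 0:
            raise ValueError("cannot scale an empty design")
        factor = total / current
        sizes = {
            key: max(1, round(size * factor)) if size else 0
            for key, size in self.cell_sizes.items()
        }
        return dataclasses.replace(self, cell_sizes=sizes)

    def multiplier_vector(self, traits: Sequence[str]) -> np.ndarray:
        if isinstance(self.male_multiplier, Mapping):
            return np.array(
                [self.male_multiplier.get(t, 1.0) for t in traits]
            )
        return np.full(len(traits), float(self.male_multiplier))


def build_default_config(seed: int | None = None) -> HerdConfig:
    """The reference-population configuration (95 animals)."""
    return HerdConfig(seed=seed)


_PREFIX = {"NEGRO": "N", "CALLEJON": "C", "ATIGRADO": "A"}


def simulate_herd(
    config: HerdConfig | None = None, seed: int | None = None
) -> list[AnimalRecord]:
    """Draw a herd; identical (config, seed) gives identical records."""
    config = config or build_default_config()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    traits = list(calibration.MEASUREMENTS)
    p = len(traits)
    chol = np.linalg.cholesky(config.correlation)
    records: list[AnimalRecord] = []
    rejected = 0
    total = 0
    for (biotype, sex) in sorted(config.cell_sizes):
        size = config.cell_sizes[(biotype, sex)]
        if size == 0:
            continue
        mean = np.array([config.trait_means[biotype][t] for t in traits])
        if sex == "MALE":
            mean = mean * config.multiplier_vector(traits)
        sd = np.array([config.trait_cv[t] for t in traits]) / 100.0 * mean
        samples = np.empty((size, p))
        filled = 0
        while filled < size:
            need = size - filled
            z = rng.standard_normal((need, p))
            values = mean + (z @ chol.T) * sd
            keep = (values > 0).all(axis=1)
            kept = int(keep.sum())
            samples[filled:filled + kept] = values[keep]
            total += need
            rejected += need - kept
            filled += kept
        prefix = _PREFIX.get(biotype, biotype[:1])
        for i in range(size):
            records.append(
                AnimalRecord(
                    animal_id=f"{prefix}{sex[:1]}{i + 1:05d}",
                    biotype=Biotype(biotype),
                    sex=Sex(sex),
                    measurements=dict(zip(traits, samples[i].tolist())),
                )
            )
    if total and rejected / total > 0.01:
        warnings.warn(
            f"rejection rate {rejected / total:.1%} exceeds 1%: trait "
            "means are small relative to their CVs",
            stacklevel=2,
        )
    return records


def config_to_dict(config: HerdConfig) -> dict:
    """JSON-serializable form of a config (for the run manifest)."""
    return {
        "cell_sizes": {
            f"{b}:{s}": n for (b, s), n in sorted(config.cell_sizes.items())
        },
        "trait_means": {b: dict(m) for b, m in config.trait_means.items()},
        "trait_cv": dict(config.trait_cv),
        "correlation": np.asarray(config.correlation).tolist(),
        "male_multiplier": (
            dict(config.male_multiplier)
            if isinstance(config.male_multiplier, Mapping)
            else float(config.male_multiplier)
        ),
        "seed": config.seed,
    }


def config_from_dict(payload: Mapping) -> HerdConfig:
    cell_sizes = {
        tuple(key.split(":")): int(n)
        for key, n in payload["cell_sizes"].items()
    }
    return HerdConfig(
        cell_sizes=cell_sizes,
        trait_means=payload["trait_means"],
        trait_cv=payload["trait_cv"],
        correlation=np.asarray(payload["correlation"]),
        male_multiplier=payload["male_multiplier"],
        seed=payload["seed"],
    )


def herd_to_files(
    records: Sequence[AnimalRecord],
    directory: str | Path,
    *,
    config: HerdConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the herd CSV plus a manifest recording config and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records_path = directory / "herd.csv"
    write_records(records, records_path)
    manifest_path = directory / "manifest.json"
    manifest = {
        "n_records": len(records),
        "seed": seed,
        "config": config_to_dict(config) if config is not None else None,
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"records": records_path, "manifest": manifest_path}
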
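"""Delimited-text readers/writers and JSON result serialization.

Delimiters are autodetected from the file extension (``.csv`` -> comma,
anything else -> whitespace/tab) and can be overridden.  All numeric
output is written at full double precision so round trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .alm import ALMResult
from .grid import SupportSet
from .types import (
    InputError,
    MixingDistribution,
    MixtureData,
    ParseError,
    ValidationError,
)

__all__ = [
    "read_table",
    "read_observations",
    "read_grid_file",
    "write_mixing_distribution",
    "read_mixing_distribution",
    "write_denoised",
    "write_result",
    "read_result_mixing",
]


def _delimiter_for(path: Path, override: Optional[str]) -> Optional[str]:
    if override is not None:
        return override
    return "," if path.suffix.lower() == ".csv" else None  # None = whitespace


def read_table(path, delimiter: Optional[str] = None) -> np.ndarray:
    """Read a delimited numeric table as a 2-D array."""
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    try:
        arr = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return arr


def read_observations(
    path,
    cov_path=None,
    cov_mode: str = "shared",
    delimiter: Optional[str] = None,
) -> MixtureData:
    """Read observations and (optionally) covariances into a MixtureData.

    With no covariance file the noise defaults to the shared identity.
    Covariance layouts: ``shared`` — d x d; ``diag`` — n x d positive
    variances; ``full`` — (n*d) x d, one d x d block per observation.
    """
    Y = read_table(path, delimiter)
    n, d = Y.shape
    if cov_path is None:
        return MixtureData(Y=Y, covs=np.eye(d), cov_mode="shared")
    C = read_table(cov_path, delimiter)
    if cov_mode == "shared":
        if C.shape != (d, d):
            raise InputError(
                f"{cov_path}: expected {d} rows x {d} cols for a shared "
                f"covariance, found {C.shape[0]} rows"
            )
        covs = C
    elif cov_mode == "diag":
        if C.shape != (n, d):
            raise InputError(
                f"{cov_path}: expected {n} rows of per-observation variances, "
                f"found {C.shape[0]} rows"
            )
        covs = C
    elif cov_mode == "full":
        if C.shape != (n * d, d):
            raise InputError(
                f"{cov_path}: expected {n * d} rows ({n} stacked {d}x{d} "
                f"blocks), found {C.shape[0]} rows"
            )
        covs = C.reshape(n, d, d)
    else:
        raise InputError(f"unknown cov_mode {cov_mode!r}")
    return MixtureData(Y=Y, covs=covs, cov_mode=cov_mode)


def read_grid_file(path, kind: str = "location", delimiter=None) -> SupportSet:
    return SupportSet(read_table(path, delimiter), kind=kind)


def write_mixing_distribution(G: MixingDistribution, path) -> None:
    """Serialize a mixing distribution to JSON at full double precision."""
    if G.has_duplicate_atoms():
        raise ValidationError("duplicate support atoms; merge before writing")
    G.check_normalized()
    doc = {
        "support": G.support.tolist(),
        "weights": G.weights.tolist(),
        "m": G.m,
        "d": G.d,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_mixing_distribution(path) -> MixingDistribution:
    doc = json.loads(Path(path).read_text())
    return MixingDistribution.from_arrays(
        np.array(doc["support"], dtype=float),
        np.array(doc["weights"], dtype=float),
        merge_duplicates=False,
    )


def write_denoised(
    estimates: np.ndarray,
    method_tag: str,
    path,
    delimiter: Optional[str] = None,
) -> None:
    """Write denoised estimates with a header line naming the method."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    if estimates.shape[0] == 0:
        raise InputError("no estimates to write")
    if not np.all(np.isfinite(estimates)):
        raise ValidationError("non-finite denoised estimates")
    path = Path(path)
    delim = _delimiter_for(path, delimiter) or "\t"
    d = estimates.shape[1]
    header = method_tag if d == 1 else delim.join(
        f"{method_tag}_{j + 1}" for j in range(d)
    )
    np.savetxt(path, estimates, delimiter=delim, header=header, comments="",
               fmt="%.17g")


def write_result(result: ALMResult, path, solver: str = "alm") -> None:
    """Full solver result document: mixing distribution, KKT report, log."""
    doc = {
        "solver": solver,
        "mixing": {
            "support": result.mixing.support.tolist(),
            "weights": result.mixing.weights.tolist(),
            "m": result.mixing.m,
            "d": result.mixing.d,
        },
        "kkt": result.report.as_dict(),
        "objective": result.report.objective,
        "converged": result.converged,
        "weight_sum_raw": result.weight_sum_raw,
        "log": result.log,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_result_mixing(path) -> MixingDistribution:
    doc = json.loads(Path(path).read_text())
    mix = doc["mixing"] if "mixing" in doc else doc
    return MixingDistribution.from_arrays(
        np.array(mix["support"], dtype=float),
        np.array(mix["weights"], dtype=float),
        merge_duplicates=False,
    )
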
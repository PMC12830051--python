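"""Domain types, validation and tabular I/O for provider summary statistics.

Every provider (cluster) is represented by its public summary record: the
observed outcome total ``O``, the expected total ``E`` under the national
risk model, the effective size ``n_tilde`` (the information-scale
denominator of the score statistic; equals ``E`` for Poisson outcomes), an
optional third-cumulant sum used by the general-family approximations, and
a vector of cluster-level covariates ``W`` (e.g. the DSA donation rate).
No patient-level data appear anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .families import FamilySpec

__all__ = [
    "ProviderSummary",
    "ProviderTable",
    "ZScore",
    "NullMoments",
    "ResultRow",
    "read_provider_table",
    "write_results",
    "read_results",
    "stack_providers",
]

#: relative tolerance for the Poisson identity n_tilde == E
_POISSON_RTOL = 1e-8

RESULT_COLUMNS = [
    "id",
    "z_naive",
    "z_corrected",
    "flag_freq",
    "post_median",
    "ci_lo",
    "ci_hi",
    "flag_bayes",
    "in_null_set",
]

_FLAGS = ("low", "null", "high")


@dataclass
class ProviderSummary:
    """One cluster's public summary record."""

    id: str
    O: float
    E: float
    n_tilde: float
    W: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sum_b3: float | None = None

    def __post_init__(self) -> None:
        self.W = np.atleast_1d(np.asarray(self.W, dtype=float))
        if not np.isfinite(self.O) or self.O < 0:
            raise ValueError(f"provider {self.id!r}: O must be finite and >= 0")
        if not (np.isfinite(self.E) and self.E > 0):
            raise ValueError(f"provider {self.id!r}: E must be positive")
        if not (np.isfinite(self.n_tilde) and self.n_tilde > 0):
            raise ValueError(f"provider {self.id!r}: n_tilde must be positive")
        if not np.all(np.isfinite(self.W)):
            raise ValueError(f"provider {self.id!r}: covariates must be finite")


class ProviderTable(list):
    """A list of :class:`ProviderSummary` with ingestion metadata attached.

    ``covariate_names`` are the source column names and
    ``centering_offsets`` the per-column means subtracted at ingestion
    (zeros when centering was disabled), so fitted coefficients can be
    reported on the original covariate scale.
    """

    def __init__(
        self,
        providers: Iterable[ProviderSummary] = (),
        covariate_names: Sequence[str] = (),
        centering_offsets: Sequence[float] = (),
    ) -> None:
        super().__init__(providers)
        self.covariate_names = list(covariate_names)
        self.centering_offsets = np.asarray(centering_offsets, dtype=float)


@dataclass(frozen=True)
class ZScore:
    """Naive fixed-effects score statistic for one provider."""

    id: str
    z: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.z):
            raise ValueError(f"provider {self.id!r}: z-score must be finite")


@dataclass(frozen=True)
class NullMoments:
    """Conditional null mean and variance of the naive Z-score."""

    id: str
    mean: float
    var: float

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValueError(f"provider {self.id!r}: null variance must be > 0")


@dataclass
class ResultRow:
    """One provider's evaluation: naive/corrected scores, flags, interval."""

    id: str
    z_naive: float
    z_corrected: float
    flag_freq: str
    post_median: float
    ci_lo: float
    ci_hi: float
    flag_bayes: str
    in_null_set: bool

    def __post_init__(self) -> None:
        if self.flag_freq not in _FLAGS or self.flag_bayes not in _FLAGS:
            raise ValueError(f"provider {self.id!r}: flags must be in {_FLAGS}")
        if not self.ci_lo < self.ci_hi:
            raise ValueError(f"provider {self.id!r}: ci_lo must be < ci_hi")


DEFAULT_SCHEMA: Mapping[str, str] = {
    "id": "id",
    "observed": "observed",
    "expected": "expected",
    "effective_size": "effective_size",
}


def read_provider_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    family: FamilySpec | None = None,
    covariate_columns: Sequence[str] | None = None,
    center: bool = True,
) -> ProviderTable:
    """Read a provider summary CSV into validated records.

    Parameters
    ----------
    path
        CSV file with a header row; comma separated, UTF-8.
    schema
        Maps the roles ``id``, ``observed``, ``expected`` and (optionally)
        ``effective_size`` and ``sum_b3`` to column names in the file.
        Roles missing from the mapping use their role name as the column
        name.
    family
        When Poisson and the effective-size column is absent, ``n_tilde``
        is set to ``E`` (both equal the sum of exponentiated null linear
        predictors).
    covariate_columns
        Cluster-level covariate columns.  Defaults to every numeric column
        not claimed by the schema.
    center
        Subtract each covariate column's mean (the moment formulas assume
        mean-zero covariates); the offsets are recorded on the returned
        table.
    """
    resolved = dict(DEFAULT_SCHEMA)
    if schema:
        resolved.update(schema)
    df = pd.read_csv(path)

    for role in ("id", "observed", "expected"):
        if resolved[role] not in df.columns:
            raise KeyError(
                f"required column {resolved[role]!r} (role {role!r}) "
                f"missing from {path}"
            )

    id_col = resolved["id"]
    obs_col = resolved["observed"]
    exp_col = resolved["expected"]
    eff_col = resolved.get("effective_size")
    b3_col = resolved.get("sum_b3")

    claimed = {id_col, obs_col, exp_col}
    if eff_col in df.columns:
        claimed.add(eff_col)
    if b3_col and b3_col in df.columns:
        claimed.add(b3_col)

    if covariate_columns is None:
        covariate_columns = [
            c
            for c in df.columns
            if c not in claimed and pd.api.types.is_numeric_dtype(df[c])
        ]
    else:
        missing = [c for c in covariate_columns if c not in df.columns]
        if missing:
            raise KeyError(f"covariate columns {missing} missing from {path}")

    Wraw = df[list(covariate_columns)].to_numpy(dtype=float)
    if np.isnan(Wraw).any():
        bad = df[list(covariate_columns)].isna().any(axis=1)
        raise ValueError(
            f"missing covariate values in rows {list(df.index[bad])}; "
            "no imputation is performed"
        )
    offsets = Wraw.mean(axis=0) if (center and Wraw.size) else np.zeros(Wraw.shape[1])
    W = Wraw - offsets

    E = df[exp_col].to_numpy(dtype=float)
    O = df[obs_col].to_numpy(dtype=float)
    if eff_col is not None and eff_col in df.columns:
        n_tilde = df[eff_col].to_numpy(dtype=float)
    elif family is not None and family.family == "poisson":
        n_tilde = E.copy()
    else:
        raise KeyError(
            f"effective-size column {eff_col!r} missing and family is not "
            "Poisson; cannot default n_tilde"
        )
    sum_b3 = (
        df[b3_col].to_numpy(dtype=float) if (b3_col and b3_col in df.columns) else None
    )

    providers = []
    for k in range(len(df)):
        try:
            providers.append(
                ProviderSummary(
                    id=str(df[id_col].iloc[k]),
                    O=float(O[k]),
                    E=float(E[k]),
                    n_tilde=float(n_tilde[k]),
                    W=W[k],
                    sum_b3=None if sum_b3 is None else float(sum_b3[k]),
                )
            )
        except ValueError as err:
            raise ValueError(f"row {k}: {err}") from err

    table = ProviderTable(providers, covariate_columns, offsets)
    validate_providers(table, family)
    return table


def validate_providers(
    providers: Sequence[ProviderSummary], family: FamilySpec | None = None
) -> None:
    """Cross-record validation: equal covariate lengths, Poisson identity."""
    if not providers:
        raise ValueError("provider table is empty")
    P = providers[0].W.size
    for p in providers:
        if p.W.size != P:
            raise ValueError(
                f"provider {p.id!r}: covariate length {p.W.size} differs "
                f"from {P} (ragged covariates)"
            )
    if family is not None and family.family == "poisson":
        for p in providers:
            if abs(p.n_tilde - p.E) > _POISSON_RTOL * p.E:
                raise ValueError(
                    f"provider {p.id!r}: Poisson family requires n_tilde == E "
                    f"(got n_tilde={p.n_tilde}, E={p.E})"
                )


def stack_providers(
    providers: Sequence[ProviderSummary],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Column-stack provider records into arrays ``(ids, O, E, n_tilde, W, sum_b3)``."""
    ids = [p.id for p in providers]
    O = np.array([p.O for p in providers], dtype=float)
    E = np.array([p.E for p in providers], dtype=float)
    n_tilde = np.array([p.n_tilde for p in providers], dtype=float)
    W = np.vstack([p.W for p in providers]) if providers[0].W.size else np.zeros((len(providers), 0))
    if all(p.sum_b3 is not None for p in providers):
        sum_b3 = np.array([p.sum_b3 for p in providers], dtype=float)
    else:
        sum_b3 = None
    return ids, O, E, n_tilde, W, sum_b3


def write_results(rows: Sequence[ResultRow], path: str | Path) -> None:
    """Write evaluation results as CSV (fixed column order, round-trip safe)."""
    if not rows:
        raise ValueError("no result rows to write")
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "z_naive": r.z_naive,
                "z_corrected": r.z_corrected,
                "flag_freq": r.flag_freq,
                "post_median": r.post_median,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "flag_bayes": r.flag_bayes,
                "in_null_set": r.in_null_set,
            }
            for r in rows
        ],
        columns=RESULT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> list[ResultRow]:
    """Read back a results CSV written by :func:`write_results`."""
    # keep_default_na: the flag level "null" must not be parsed as NaN
    df = pd.read_csv(path, keep_default_na=False)
    df["in_null_set"] = df["in_null_set"].astype(str) == "True"
    return [
        ResultRow(
            id=str(rec.id),
            z_naive=float(rec.z_naive),
            z_corrected=float(rec.z_corrected),
            flag_freq=str(rec.flag_freq),
            post_median=float(rec.post_median),
            ci_lo=float(rec.ci_lo),
            ci_hi=float(rec.ci_hi),
            flag_bayes=str(rec.flag_bayes),
            in_null_set=bool(rec.in_null_set),
        )
        for rec in df.itertuples(index=False)
    ]
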
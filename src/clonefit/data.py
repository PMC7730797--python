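"""Input data containers, TSV parsing, validation and pre-processing filters.

The unit of input is one observation of a somatic SNV in one bulk tumour
sample: variant/reference read counts plus the local context needed to map
variant allele frequency (VAF) onto cancer cell fraction (CCF) — allele
specific copy number (major/minor in the tumour, total in contaminating
normal cells), the tumour content of the sample and a per-base sequencing
error rate.  A :class:`Dataset` is the rectangular collection of these
observations over N mutations x M samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MutationObservation",
    "Dataset",
    "GenotypeState",
    "CCFGrid",
    "InputFormatError",
    "load_input_table",
    "write_input_table",
    "filter_mutations",
    "build_genotype_states",
    "build_ccf_grid",
]

#: tokens accepted as "missing" in input tables
MISSING_TOKENS = (".", "NA", "")

DEFAULT_NORMAL_CN = 2
DEFAULT_ERROR_RATE = 1e-3

REQUIRED_COLUMNS = (
    "mutation_id",
    "sample_id",
    "ref_counts",
    "alt_counts",
    "major_cn",
    "minor_cn",
    "tumour_content",
)
OPTIONAL_COLUMNS = ("normal_cn", "error_rate")


class InputFormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class MutationObservation:
    """One mutation measured in one sample, with its local context.

    ``major_cn``/``minor_cn`` are allele-specific copy numbers of the locus
    in the malignant cells, ``normal_cn`` the total copy number in
    contaminating normal cells (2 for autosomes), ``tumour_content`` the
    fraction of malignant cells in the sample and ``error_rate`` the
    per-base sequencing error rate.  ``float('nan')`` copy numbers mark
    missing copy-number calls; such mutations must be filtered out before
    model fitting.
    """

    mutation_id: str
    sample_id: str
    alt_count: int
    ref_count: int
    major_cn: float
    minor_cn: float
    normal_cn: int = DEFAULT_NORMAL_CN
    tumour_content: float = 1.0
    error_rate: float = DEFAULT_ERROR_RATE

    def __post_init__(self) -> None:
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError(
                f"negative read count for ({self.mutation_id}, {self.sample_id})"
            )
        if not np.isnan(self.major_cn):
            if self.major_cn < 0 or self.minor_cn < 0:
                raise ValueError("copy numbers must be non-negative")
            if self.minor_cn > self.major_cn:
                raise ValueError(
                    f"minor_cn > major_cn for ({self.mutation_id}, {self.sample_id})"
                )
        if self.normal_cn < 1:
            raise ValueError("normal_cn must be a positive integer")
        if not 0.0 <= self.tumour_content <= 1.0:
            raise ValueError("tumour_content must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count

    @property
    def total_cn(self) -> float:
        """Total tumour copy number (major + minor)."""
        return self.major_cn + self.minor_cn


@dataclass
class Dataset:
    """Rectangular N mutations x M samples collection of observations.

    All per-observation quantities are stored as dense ``(N, M)`` arrays in
    first-appearance order of mutation and sample ids.  Copy-number arrays
    are floats so that missing calls can be carried as NaN until
    :func:`filter_mutations` removes them.
    """

    mutation_ids: list[str]
    sample_ids: list[str]
    alt: np.ndarray
    ref: np.ndarray
    major_cn: np.ndarray
    minor_cn: np.ndarray
    normal_cn: np.ndarray
    tumour_content: np.ndarray
    error_rate: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.mutation_ids), len(self.sample_ids)
        if n < 1 or m < 1:
            raise ValueError("a Dataset needs at least one mutation and one sample")
        if len(set(self.mutation_ids)) != n:
            raise ValueError("mutation ids must be unique")
        if len(set(self.sample_ids)) != m:
            raise ValueError("sample ids must be unique")
        for name in ("alt", "ref", "major_cn", "minor_cn", "normal_cn",
                     "tumour_content", "error_rate"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n, m):
                raise ValueError(f"{name} must have shape ({n}, {m}), got {arr.shape}")
            setattr(self, name, arr)
        if np.any(self.alt < 0) or np.any(self.ref < 0):
            raise ValueError("read counts must be non-negative")
        with np.errstate(invalid="ignore"):
            if np.any(self.minor_cn > self.major_cn):
                raise ValueError("minor_cn may not exceed major_cn")
        if np.any((self.tumour_content < 0) | (self.tumour_content > 1)):
            raise ValueError("tumour_content must lie in [0, 1]")
        if np.any((self.error_rate < 0) | (self.error_rate >= 1)):
            raise ValueError("error_rate must lie in [0, 1)")

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def depth(self) -> np.ndarray:
        return self.alt + self.ref

    @property
    def total_cn(self) -> np.ndarray:
        return self.major_cn + self.minor_cn

    def observation(self, i: int, j: int) -> MutationObservation:
        return MutationObservation(
            mutation_id=self.mutation_ids[i],
            sample_id=self.sample_ids[j],
            alt_count=int(self.alt[i, j]),
            ref_count=int(self.ref[i, j]),
            major_cn=float(self.major_cn[i, j]),
            minor_cn=float(self.minor_cn[i, j]),
            normal_cn=int(self.normal_cn[i, j]),
            tumour_content=float(self.tumour_content[i, j]),
            error_rate=float(self.error_rate[i, j]),
        )

    def subset_mutations(self, keep: np.ndarray) -> "Dataset":
        """Return a new Dataset restricted to mutations where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        if keep.sum() == 0:
            raise ValueError("cannot subset to an empty Dataset")
        ids = [mid for mid, k in zip(self.mutation_ids, keep) if k]
        return Dataset(
            mutation_ids=ids,
            sample_ids=list(self.sample_ids),
            alt=self.alt[keep],
            ref=self.ref[keep],
            major_cn=self.major_cn[keep],
            minor_cn=self.minor_cn[keep],
            normal_cn=self.normal_cn[keep],
            tumour_content=self.tumour_content[keep],
            error_rate=self.error_rate[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table in the input TSV dialect (row per observation)."""
        n, m = self.n_mutations, self.n_samples
        rows = {
            "mutation_id": np.repeat(self.mutation_ids, m),
            "sample_id": np.tile(self.sample_ids, n),
            "ref_counts": self.ref.reshape(-1),
            "alt_counts": self.alt.reshape(-1),
            "major_cn": self.major_cn.reshape(-1),
            "minor_cn": self.minor_cn.reshape(-1),
            "normal_cn": self.normal_cn.reshape(-1),
            "tumour_content": self.tumour_content.reshape(-1),
            "error_rate": self.error_rate.reshape(-1),
        }
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        if self.mutation_ids != other.mutation_ids or self.sample_ids != other.sample_ids:
            return False
        for name in ("alt", "ref", "major_cn", "minor_cn", "normal_cn",
                     "tumour_content", "error_rate"):
            a, b = getattr(self, name), getattr(other, name)
            if not np.array_equal(a, b, equal_nan=True):
                return False
        return True


@dataclass(frozen=True)
class GenotypeState:
    """One candidate genotype configuration for a mutation.

    ``multiplicity`` is the number of tumour chromosome copies carrying the
    variant allele; ``prior_weight`` is the prior probability of this state
    among the candidates of the same observation.
    """

    normal_cn: int
    tumour_cn: int
    multiplicity: int
    prior_weight: float


@dataclass(frozen=True)
class CCFGrid:
    """Uniform grid of admissible CCF values {0, 1/F, ..., 1}."""

    F: int
    values: np.ndarray = field(compare=False)

    @property
    def size(self) -> int:
        return self.F + 1

    @property
    def spacing(self) -> float:
        return 1.0 / self.F


def build_ccf_grid(F: int) -> CCFGrid:
    """Return the uniform CCF grid with resolution ``F`` (F + 1 points).

    Any CCF in [0, 1] is then within ``1 / (2 F)`` of a grid point.
    """
    if F < 1:
        raise ValueError(f"grid resolution F must be >= 1, got {F}")
    values = np.linspace(0.0, 1.0, F + 1)
    values.setflags(write=False)
    return CCFGrid(F=int(F), values=values)


def build_genotype_states(
    major_cn: int, minor_cn: int, normal_cn: int = DEFAULT_NORMAL_CN
) -> list[GenotypeState]:
    """Enumerate candidate genotype states for one locus.

    The "major copy number" elicitation rule distinguishes when the
    mutation arose relative to the copy-number change at the locus: an
    early mutation may sit on 1..major_cn chromosome copies (one pre-change
    state per multiplicity), while a late mutation arose after the change
    and sits on a single copy.  All major_cn + 1 hypotheses get equal prior
    mass; under the shared expected-VAF model the late hypothesis coincides
    with the multiplicity-1 early one, so it is folded in by doubling that
    state's weight.  Down-weighting high multiplicities this way matters:
    a uniform prior over multiplicities alone leaves a degeneracy where
    single-copy mutations at amplified loci are re-explained at higher
    multiplicity and proportionally lower CCF.

    Mutations with ``major_cn == 0`` carry no admissible state and must be
    removed by :func:`filter_mutations` before fitting.
    """
    major_cn = int(major_cn)
    minor_cn = int(minor_cn)
    if major_cn < 1:
        raise ValueError("major_cn must be >= 1; filter such mutations first")
    if minor_cn < 0 or minor_cn > major_cn:
        raise ValueError("need 0 <= minor_cn <= major_cn")
    total = major_cn + minor_cn
    norm = float(major_cn + 1)
    return [
        GenotypeState(
            normal_cn=int(normal_cn), tumour_cn=total, multiplicity=m,
            prior_weight=(2.0 if m == 1 else 1.0) / norm,
        )
        for m in range(1, major_cn + 1)
    ]


def _parse_numeric(
    frame: pd.DataFrame, column: str, *, integer: bool, allow_missing: bool
) -> np.ndarray:
    """Parse one column to floats, mapping missing tokens to NaN."""
    raw = frame[column].astype(str).str.strip()
    missing = raw.isin(MISSING_TOKENS) | frame[column].isna()
    values = pd.to_numeric(raw.where(~missing), errors="coerce")
    bad = values.isna() & ~missing
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise InputFormatError(
            f"column '{column}': non-numeric value {raw[bad.idxmax()]!r} at line {line}"
        )
    if not allow_missing and missing.any():
        line = int(missing.idxmax()) + 2
        raise InputFormatError(f"column '{column}': missing value at line {line}")
    if integer:
        finite = values.dropna()
        off = finite[finite != finite.round()]
        if len(off):
            line = int(off.index[0]) + 2
            raise InputFormatError(
                f"column '{column}': non-integer value {off.iloc[0]!r} at line {line}"
            )
    return values.to_numpy(dtype=float)


def load_input_table(path) -> Dataset:
    """Read a tab-separated input table into a validated :class:`Dataset`.

    Required columns: mutation_id, sample_id, ref_counts, alt_counts,
    major_cn, minor_cn, tumour_content.  Optional: normal_cn (default 2),
    error_rate (default 1e-3).  ".", "NA" and the empty field denote a
    missing value; missing copy numbers are tolerated here and removed by
    :func:`filter_mutations`.  Mutation/sample order is order of first
    appearance in the file, so shuffling rows does not change the result.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise InputFormatError(
            f"input table is missing required column(s): {', '.join(missing_cols)}"
        )
    if len(frame) == 0:
        raise InputFormatError("input table contains no observations")

    frame = frame.reset_index(drop=True)
    mutation_ids = list(dict.fromkeys(frame["mutation_id"]))
    sample_ids = list(dict.fromkeys(frame["sample_id"]))
    n, m = len(mutation_ids), len(sample_ids)

    pairs = list(zip(frame["mutation_id"], frame["sample_id"]))
    if len(set(pairs)) != len(pairs):
        seen: set[tuple[str, str]] = set()
        for p in pairs:
            if p in seen:
                raise InputFormatError(f"duplicate observation for {p}")
            seen.add(p)
    absent = [
        (mid, sid)
        for mid in mutation_ids
        for sid in sample_ids
        if (mid, sid) not in set(pairs)
    ]
    if absent:
        listing = "; ".join(f"({mid}, {sid})" for mid, sid in absent[:20])
        raise InputFormatError(
            f"incomplete design: missing observation(s) for {listing}"
        )

    columns = {
        "alt": _parse_numeric(frame, "alt_counts", integer=True, allow_missing=False),
        "ref": _parse_numeric(frame, "ref_counts", integer=True, allow_missing=False),
        "major_cn": _parse_numeric(frame, "major_cn", integer=True, allow_missing=True),
        "minor_cn": _parse_numeric(frame, "minor_cn", integer=True, allow_missing=True),
        "tumour_content": _parse_numeric(
            frame, "tumour_content", integer=False, allow_missing=False
        ),
    }
    if "normal_cn" in frame.columns:
        normal = _parse_numeric(frame, "normal_cn", integer=True, allow_missing=True)
        normal = np.where(np.isnan(normal), DEFAULT_NORMAL_CN, normal)
    else:
        normal = np.full(len(frame), float(DEFAULT_NORMAL_CN))
    columns["normal_cn"] = normal
    if "error_rate" in frame.columns:
        err = _parse_numeric(frame, "error_rate", integer=False, allow_missing=True)
        err = np.where(np.isnan(err), DEFAULT_ERROR_RATE, err)
    else:
        err = np.full(len(frame), DEFAULT_ERROR_RATE)
    columns["error_rate"] = err

    row_index = {mid: i for i, mid in enumerate(mutation_ids)}
    col_index = {sid: j for j, sid in enumerate(sample_ids)}
    ii = frame["mutation_id"].map(row_index).to_numpy()
    jj = frame["sample_id"].map(col_index).to_numpy()

    grids = {}
    for name, flat in columns.items():
        grid = np.full((n, m), np.nan)
        grid[ii, jj] = flat
        grids[name] = grid
    for name in ("alt", "ref", "normal_cn"):
        grids[name] = grids[name].astype(np.int64)

    return Dataset(mutation_ids=mutation_ids, sample_ids=sample_ids, **grids)


def write_input_table(dataset: Dataset, path) -> None:
    """Write a Dataset in the input TSV dialect (NaN rendered as "NA")."""
    frame = dataset.to_dataframe()
    for col in ("major_cn", "minor_cn"):
        vals = frame[col]
        frame[col] = vals.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def filter_mutations(dataset: Dataset) -> tuple[Dataset | None, pd.DataFrame]:
    """Drop mutations that cannot be placed on the CCF grid.

    A mutation is removed from *all* samples if, in any sample, its copy
    number call is missing, its major copy number is zero, or its total
    tumour copy number is zero.  Returns the filtered dataset (None if
    nothing survives) and a report with columns ``mutation_id``/``reason``.
    The operation is idempotent.
    """
    missing = np.isnan(dataset.major_cn) | np.isnan(dataset.minor_cn)
    with np.errstate(invalid="ignore"):
        major_zero = dataset.major_cn == 0
        total_zero = dataset.total_cn == 0

    reasons = []
    keep = np.ones(dataset.n_mutations, dtype=bool)
    for i, mid in enumerate(dataset.mutation_ids):
        why = []
        if missing[i].any():
            why.append("missing_copy_number")
        if major_zero[i].any():
            why.append("major_cn_zero")
        if total_zero[i].any():
            why.append("total_cn_zero")
        if why:
            keep[i] = False
            reasons.append({"mutation_id": mid, "reason": ";".join(why)})

    report = pd.DataFrame(reasons, columns=["mutation_id", "reason"])
    if keep.all():
        return dataset, report
    if not keep.any():
        return None, report
    return dataset.subset_mutations(keep), report
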
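"""Shared domain types for methylation panels, clocks, and genomic region sets.

Conventions used throughout the package:

* CpG positions are 1-based single-base coordinates (array-manifest style);
  a CpG at position ``p`` occupies the 0-based half-open interval ``[p-1, p)``.
* BED intervals are 0-based half-open.
* Beta values are methylation fractions in ``[0, 1]``; missing probe values
  are represented as NaN and handled downstream (clock: mean-impute from
  training means; EWAS: pairwise-complete).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VALID_TISSUES = ("blood", "skin")
VALID_SEXES = ("F", "M", "unknown")


class FormatError(ValueError):
    """A file did not conform to its documented dialect."""


class ValidationError(ValueError):
    """Parsed content violated a domain invariant."""


def _canon_label(x: object) -> str:
    return str(x).strip().casefold()


@dataclass
class SamplePanel:
    """Per-sample metadata aligned (by ``sample_id``) to a beta matrix.

    ``meta`` carries any extra sample-sheet columns as opaque metadata.
    """

    sample_id: list[str]
    species: list[str]
    tissue: list[str]
    age_years: np.ndarray
    sex: list[str]
    age_known: list[bool]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_id)
        if n < 1:
            raise ValidationError("sample panel must contain at least one sample")
        if len(set(self.sample_id)) != n:
            dups = sorted({s for s in self.sample_id if self.sample_id.count(s) > 1})
            raise ValidationError(f"duplicate sample_ids: {dups}")
        self.species = [_canon_label(s) for s in self.species]
        self.tissue = [_canon_label(t) for t in self.tissue]
        bad_tissue = sorted({t for t in self.tissue if t not in VALID_TISSUES})
        if bad_tissue:
            raise ValidationError(
                f"tissue must be one of {VALID_TISSUES}, got {bad_tissue}"
            )
        self.age_years = np.asarray(self.age_years, dtype=float)
        if self.age_years.shape != (n,):
            raise ValidationError("age_years length does not match sample_ids")
        neg = [sid for sid, a in zip(self.sample_id, self.age_years) if a < 0]
        if neg:
            raise ValidationError(f"negative age_years for samples: {neg}")
        self.sex = [s if s in VALID_SEXES else _norm_sex(s) for s in self.sex]

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "species": self.species,
                "tissue": self.tissue,
                "age_years": self.age_years,
                "sex": self.sex,
                "age_known": self.age_known,
            }
        )
        return df

    def subset(self, mask: np.ndarray) -> "SamplePanel":
        """Row-subset by boolean mask or integer index array."""
        idx = np.arange(len(self))[mask] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return SamplePanel(
            sample_id=[self.sample_id[i] for i in idx],
            species=[self.species[i] for i in idx],
            tissue=[self.tissue[i] for i in idx],
            age_years=self.age_years[idx],
            sex=[self.sex[i] for i in idx],
            age_known=[self.age_known[i] for i in idx],
            meta=self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None,
        )

    def strata(self) -> list[tuple[str, str]]:
        """Distinct (species, tissue) strata in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for sp, ti in zip(self.species, self.tissue):
            seen.setdefault((sp, ti), None)
        return list(seen)


def _norm_sex(s: object) -> str:
    c = str(s).strip().upper()
    if c in ("F", "FEMALE"):
        return "F"
    if c in ("M", "MALE"):
        return "M"
    return "unknown"


@dataclass
class BetaMatrix:
    """Samples x CpGs methylation fractions, row-aligned to a SamplePanel."""

    sample_ids: list[str]
    cpg_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError("cpg_ids are not unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            bad = finite[(finite < -1e-9) | (finite > 1 + 1e-9)]
            raise ValidationError(
                f"beta values outside [0,1] beyond tolerance, e.g. {bad[:3]}"
            )
        # values within 1e-9 of the boundary are clamped, not rejected
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cpg_ids)}

    def subset_samples(self, mask: np.ndarray) -> "BetaMatrix":
        idx = np.arange(len(self.sample_ids))[mask] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return BetaMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            cpg_ids=self.cpg_ids,
            values=self.values[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)


@dataclass
class CpGMap:
    """CpG id -> (chromosome, 1-based position) lookup."""

    table: pd.DataFrame  # columns: cpg_id, chromosome, position

    def __post_init__(self) -> None:
        req = {"cpg_id", "chromosome", "position"}
        missing = req - set(self.table.columns)
        if missing:
            raise FormatError(f"CpG map missing columns: {sorted(missing)}")
        if self.table["cpg_id"].duplicated().any():
            dups = self.table.loc[self.table["cpg_id"].duplicated(), "cpg_id"].tolist()
            raise ValidationError(f"duplicate cpg_ids in map: {dups[:5]}")
        if (self.table["position"] < 1).any():
            raise ValidationError("CpG positions must be >= 1 (1-based)")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cpg_ids(self) -> list[str]:
        return self.table["cpg_id"].tolist()

    def positions(self) -> dict[str, tuple[str, int]]:
        return {
            r.cpg_id: (r.chromosome, int(r.position))
            for r in self.table.itertuples(index=False)
        }


@dataclass
class RegionSet:
    """A named collection of 0-based half-open genomic intervals.

    Intervals are canonicalized (sorted per chromosome) on construction;
    overlapping intervals are retained unless explicitly merged.
    """

    set_name: str
    intervals: list[tuple[str, int, int]]
    source_label: str | None = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValidationError(
                    f"degenerate interval {chrom}:{start}-{end} in set {self.set_name}"
                )
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "RegionSet":
        """Union of intervals: overlapping/adjacent intervals coalesced."""
        out: list[tuple[str, int, int]] = []
        for chrom, start, end in self.intervals:
            if out and out[-1][0] == chrom and start <= out[-1][2]:
                prev = out[-1]
                out[-1] = (chrom, prev[1], max(prev[2], end))
            else:
                out.append((chrom, start, end))
        return RegionSet(self.set_name, out, self.source_label)

    def by_chromosome(self) -> dict[str, np.ndarray]:
        """Merged intervals as per-chromosome (k, 2) arrays of [start, end)."""
        merged = self.merged()
        groups: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in merged.intervals:
            groups.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in groups.items()}


@dataclass
class ClockModel:
    """A fitted penalized age clock: intercept + sparse CpG weights.

    The linear score ``intercept + sum_j w_j * beta_j`` lives on the
    transformed-age scale; :func:`cetclock.clock.predict_age` maps it back to
    years through the inverse age transform. ``training_means`` stores the
    training-set mean beta of each model CpG for missing-value imputation at
    prediction time.
    """

    intercept: float
    weights: Mapping[str, float]
    transform_spec: "TransformSpec"  # noqa: F821 - forward ref to transform module
    training_means: Mapping[str, float] = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = {k: float(v) for k, v in self.weights.items() if v != 0.0}
        self.training_means = {k: float(v) for k, v in self.training_means.items()}

    @property
    def n_cpgs(self) -> int:
        return len(self.weights)
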
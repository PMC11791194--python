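"""Readers and writers for the tabular and genomic formats the pipeline touches.

CSV is the canonical tabular dialect (comma or tab sniffed); BED files are
3+ column, 0-based half-open; clock models serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .transform import TransformSpec
from .types import (
    BetaMatrix,
    CpGMap,
    FormatError,
    RegionSet,
    SamplePanel,
    ValidationError,
)

_PANEL_REQUIRED = ("sample_id", "species", "tissue", "age_years", "sex")


def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing comma vs tab from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_sample_panel(path) -> SamplePanel:
    """Load and validate a sample sheet.

    Required columns: sample_id, species, tissue, age_years, sex. An
    optional ``age_known`` boolean column flags estimated ages; extra
    columns are preserved as opaque metadata.
    """
    df = _read_table(path)
    missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing required column(s): {missing}")
    ages = pd.to_numeric(df["age_years"], errors="coerce")
    if ages.isna().any():
        bad = df.loc[ages.isna(), "sample_id"].tolist()
        raise FormatError(f"non-numeric age_years for samples: {bad}")
    age_known = (
        df["age_known"].astype(bool).tolist()
        if "age_known" in df.columns
        else [True] * len(df)
    )
    extra = df.drop(columns=[c for c in df.columns if c in _PANEL_REQUIRED + ("age_known",)])
    return SamplePanel(
        sample_id=[str(s).strip() for s in df["sample_id"]],
        species=df["species"].tolist(),
        tissue=df["tissue"].tolist(),
        age_years=ages.to_numpy(dtype=float),
        sex=df["sex"].tolist(),
        age_known=age_known,
        meta=extra if len(extra.columns) else None,
    )


def write_sample_panel(panel: SamplePanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def read_beta_matrix(path, panel: SamplePanel) -> BetaMatrix:
    """Load a samples x CpGs beta matrix and align its rows to ``panel``.

    The first column holds sample ids; remaining headers are CpG ids. Rows
    may appear in any order; they are permuted to panel order. Values more
    than 1e-9 outside [0,1] raise; values within tolerance are clamped.
    """
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str).str.strip()
    missing = [s for s in panel.sample_id if s not in df.index]
    if missing:
        raise FormatError(f"samples in panel missing from beta matrix: {missing}")
    df = df.loc[panel.sample_id]
    return BetaMatrix(
        sample_ids=list(panel.sample_id),
        cpg_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_beta_matrix(betas: BetaMatrix, path) -> None:
    betas.to_frame().rename_axis("sample_id").to_csv(path)


def read_cpg_map(path) -> CpGMap:
    """Load a CpG position table (cpg_id, chromosome, 1-based position)."""
    df = _read_table(path)
    missing = [c for c in ("cpg_id", "chromosome", "position") if c not in df.columns]
    if missing:
        raise FormatError(f"CpG map missing column(s): {missing}")
    df["position"] = pd.to_numeric(df["position"]).astype(np.int64)
    return CpGMap(df[["cpg_id", "chromosome", "position"]].copy())


def write_cpg_map(cpg_map: CpGMap, path) -> None:
    cpg_map.table.to_csv(path, index=False)


def read_bed(path, set_name: str | None = None, merge: bool = False) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open) into a RegionSet."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path.name}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path.name}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((fields[0], start, end))
    rs = RegionSet(set_name or path.stem, intervals)
    return rs.merged() if merge else rs


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_clock_model(model, path) -> None:
    """Serialize a ClockModel to JSON; read(write(m)) == m field-for-field."""
    doc = {
        "format": "cetclock-model",
        "version": 1,
        "intercept": model.intercept,
        "weights": dict(model.weights),
        "transform_spec": model.transform_spec.to_dict(),
        "training_means": dict(model.training_means),
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_clock_model(path):
    from .types import ClockModel

    with open(path) as fh:
        doc = json.load(fh)
    try:
        spec = TransformSpec.from_dict(doc["transform_spec"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"invalid transform spec in clock model: {exc}") from exc
    try:
        return ClockModel(
            intercept=float(doc["intercept"]),
            weights=doc["weights"],
            transform_spec=spec,
            training_means=doc.get("training_means", {}),
            training_meta=doc.get("training_meta", {}),
        )
    except (KeyError, TypeError, ValidationError) as exc:
        raise FormatError(f"invalid clock model document: {exc}") from exc
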
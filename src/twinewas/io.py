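"""Readers/writers for the on-disk formats and run configuration.

Formats: phenotype TSV (one row per sample), methylation matrix TSV
(probes x samples, probe id in the first column), manifest as either a
BED-like TSV (0-based half-open; chrom, start, end, probe_id, gene,
feature, island, flags) or a 1-based position TSV.  Positions are 1-based
inclusive internally; all BED output converts to 0-based half-open.  Gzip
is handled transparently by extension.  All writes are atomic
(temp + rename).  Scientific-notation p-values are serialized with 6
significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dmr import DmrConfig
from .ewas import EwasConfig
from .preprocess import MethylationMatrix, ProbeManifest
from .simulate import CohortConfig, MethylomeConfig, TwinCohort

ASSOCIATION_COLUMNS = [
    "probe_id",
    "a_score",
    "p_gcc",
    "coef_lin",
    "p_kin",
    "p_lme",
    "gene",
    "chrom",
    "pos",
    "feature",
    "island",
    "p_combined",
    "q_value",
    "direction",
    "winner",
]


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_tsv(df: pd.DataFrame, path, float_format="%.6g", index=False) -> None:
    # infer compression from the *target* name (the temp file has none)
    comp = "gzip" if str(path).endswith(".gz") else None
    _atomic_write(
        Path(path),
        lambda tmp: df.to_csv(
            tmp, sep="\t", index=index, float_format=float_format, compression=comp
        ),
    )


# ---------------------------------------------------------------------------
# cohort / phenotype tables


def write_cohort(cohort: TwinCohort, path) -> None:
    _write_tsv(cohort.samples, path, float_format="%.10g")


def read_cohort(path) -> TwinCohort:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    cohort = TwinCohort(df)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# methylation matrix + manifest


def write_methylation(matrix: MethylationMatrix, path) -> None:
    _write_tsv(matrix.values, path, float_format="%.8g", index=True)


def write_manifest(manifest: ProbeManifest, path, dialect: str = "bed") -> None:
    t = manifest.table
    if dialect == "bed":
        out = pd.DataFrame(
            {
                "chrom": t["chrom"],
                "start": t["pos"] - 1,  # 1-based inclusive -> 0-based half-open
                "end": t["pos"],
                "probe_id": t["probe_id"],
                "gene": t.get("gene", ""),
                "feature": t.get("feature", ""),
                "island": t.get("island", ""),
                "flags": t.get("flags", ""),
            }
        )
    elif dialect == "pos":
        out = t
    else:
        raise ValueError(f"unknown manifest dialect {dialect!r}")
    _write_tsv(out, path)


def read_manifest(path, dialect: str = "bed") -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    if dialect == "bed":
        if not {"chrom", "start", "end", "probe_id"} <= set(df.columns):
            raise ValueError("BED-like manifest needs chrom, start, end, probe_id")
        df = df.assign(pos=df["start"] + 1).drop(columns=["start", "end"])
    elif dialect != "pos":
        raise ValueError(f"unknown manifest dialect {dialect!r}")
    for col in ("gene", "feature", "island", "flags"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    if not df[["chrom", "pos"]].equals(df[["chrom", "pos"]].sort_values(["chrom", "pos"])):
        import warnings

        warnings.warn("manifest positions were unsorted; sorted on load")
    return ProbeManifest(df)


def read_methylation(path, manifest_path, dialect: str = "bed", phenotype_path=None):
    """Load a methylation matrix and its manifest, aligned; optionally
    check samples against a phenotype table."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    logging.getLogger(__name__).info(
        "loaded %d probes x %d samples from %s", *values.shape, path
    )
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicated probe id {dup!r} in matrix")
    manifest = read_manifest(manifest_path, dialect)
    matrix = MethylationMatrix(values, scale="beta")
    manifest.aligned_to(matrix)
    # order matrix rows by manifest (position-sorted)
    matrix = MethylationMatrix(values.loc[manifest.probe_ids], scale="beta")
    if phenotype_path is not None:
        cohort = read_cohort(phenotype_path)
        missing = set(matrix.sample_ids) - set(cohort.sample_ids)
        if missing:
            raise ValueError(
                f"samples in matrix missing from phenotype table: {sorted(missing)[:5]}"
            )
    return matrix, manifest


# ---------------------------------------------------------------------------
# results


def write_outputs(records: pd.DataFrame, regions, summary, out_dir) -> dict:
    """Write association TSV, region BED + TSV, QQ table and summary JSON.

    Missing per-model entries become empty cells, not dropped rows.
    Returns the mapping of logical name to path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cols = [c for c in ASSOCIATION_COLUMNS if c in records.columns]
    assoc = records[cols].copy()
    paths["association"] = out_dir / "association.tsv"
    _write_tsv(assoc, paths["association"])

    if regions is not None:
        paths["regions"] = out_dir / "regions.tsv"
        _write_tsv(regions, paths["regions"])
        bed = pd.DataFrame(
            {
                "chrom": regions["chrom"],
                "start": regions["start"],
                "end": regions["end"],
                "name": [f"dmr{i:03d}" for i in range(len(regions))],
                "score": -np.log10(np.maximum(regions["q_value"], 1e-300)),
                "direction": regions["direction"],
            }
        )
        paths["regions_bed"] = out_dir / "regions.bed"
        _write_tsv(bed, paths["regions_bed"])

    if summary is not None:
        paths["qq"] = out_dir / "qq.tsv"
        _write_tsv(summary.qq_table, paths["qq"])
        payload = {
            "lambda_gc": summary.lambda_gc,
            "counts": {f"p<{t:g}": c for t, c in summary.counts.items()},
            "n_probes": summary.n_probes,
            "n_overlap_top": summary.n_overlap_top,
        }
        paths["summary"] = out_dir / "summary.json"
        _atomic_write(
            paths["summary"],
            lambda tmp: Path(tmp).write_text(json.dumps(payload, indent=2) + "\n"),
        )
    return paths


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run."""

    seed: int = 0
    max_missing: float = 0.05
    epsilon: float = 1e-6
    cohort: CohortConfig = field(default_factory=CohortConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    ewas: EwasConfig = field(default_factory=EwasConfig)
    dmr: DmrConfig = field(default_factory=DmrConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, value in raw.items():
            ftype = fields[name].default_factory if fields[name].default_factory is not dataclasses.MISSING else None
            if ftype is not None and isinstance(value, dict):
                sub_cls = ftype
                sub_fields = {f.name for f in dataclasses.fields(sub_cls)}
                bad = set(value) - sub_fields
                if bad:
                    raise ValueError(f"unknown config keys under {name!r}: {sorted(bad)}")
                value = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[name] = sub_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        _atomic_write(
            Path(path),
            lambda tmp: Path(tmp).write_text(yaml.safe_dump(clean(payload), sort_keys=False)),
        )
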
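"""Readers and writers for the pipeline's TSV/JSON artifacts.

All tables are tab-separated UTF-8 with '.' decimals and no quoting; the
first column is the row key (``gene_id`` or ``sample_id``), which makes
round trips bit-exact for integer tables. A study directory holds
``counts.tsv``, ``samples.tsv``, ``mapping_stats.tsv``, ``coverage.tsv``
and, for synthetic studies, ``truth.json``.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    MAPPING_CATEGORIES,
    SAMPLE_SHEET_COLUMNS,
    CountMatrix,
    SimConfig,
    StudyBundle,
    Truth,
    validate_gene_model,
)


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def write_counts(counts: CountMatrix, path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path, library_sizes: pd.Series | None = None) -> CountMatrix:
    """Read a gene x sample count table.

    Duplicate gene ids, ragged rows and non-integer entries raise
    :class:`ParseError` naming the line. Without explicit
    ``library_sizes`` column sums are used (a lower bound on true totals).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ParseError(
            f"{path}, line {row + 2}: duplicate gene id {df['gene_id'].iloc[row]!r}"
        )
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0])
        raise ParseError(f"{path}, line {row + 2}: ragged or missing fields")
    body = df.set_index("gene_id")
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | (numeric != numeric.round()).any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(f"{path}, line {row + 2}: non-integer count")
    counts = numeric.astype(np.int64)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return CountMatrix(counts=counts, library_sizes=library_sizes)


# ---------------------------------------------------------------------------
# sample sheet / mapping stats / coverage / gene model
# ---------------------------------------------------------------------------

def write_sample_sheet(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(Path(path), sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(meta.columns) - {"library_size"}
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    design = meta[["tumor_id", "tissue", "protocol", "input_ng"]]
    if design.duplicated().any():
        raise ParseError(f"{path}: duplicate (tumor, tissue, protocol, input) combination")
    return meta


def write_mapping_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index_label="sample_id")


def read_mapping_stats(path) -> pd.DataFrame:
    stats = pd.read_csv(Path(path), sep="\t", index_col="sample_id")
    missing = set(MAPPING_CATEGORIES) - set(stats.columns)
    if missing:
        raise ParseError(f"{path}: mapping stats missing categories {sorted(missing)}")
    sums = stats[list(MAPPING_CATEGORIES)].sum(axis=1)
    bad = (sums - 1.0).abs() > 1e-6
    if bad.any():
        raise ParseError(
            f"{path}: mapping fractions for {sums.index[bad][0]!r} sum to {sums[bad].iloc[0]!r}"
        )
    return stats


def write_coverage(coverage: pd.DataFrame, path) -> None:
    coverage.to_csv(path, sep="\t", index_label="sample_id")


def read_coverage(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col="sample_id")


def write_gene_model(gene_model: pd.DataFrame, path) -> None:
    gene_model.to_csv(path, sep="\t", index=False)


def read_gene_model(path) -> pd.DataFrame:
    return validate_gene_model(pd.read_csv(Path(path), sep="\t"))


def read_transcript_coverage(path) -> dict[str, np.ndarray]:
    """Ragged TSV of per-transcript positional coverage: id, v1, v2, ..."""
    out: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}, line {lineno}: expected id + coverage values")
            tid = fields[0]
            if tid in out:
                raise ParseError(f"{path}, line {lineno}: duplicate transcript id {tid!r}")
            try:
                out[tid] = np.array([float(x) for x in fields[1:]])
            except ValueError:
                raise ParseError(f"{path}, line {lineno}: non-numeric coverage value")
    return out


def write_transcript_coverage(vectors: dict[str, np.ndarray], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, vec in vectors.items():
            fh.write(tid + "\t" + "\t".join(f"{v:g}" for v in np.asarray(vec)) + "\n")


# ---------------------------------------------------------------------------
# truth / config
# ---------------------------------------------------------------------------

def write_truth(truth: Truth, path) -> None:
    payload = {
        "gene_ids": truth.expr.index.tolist(),
        "expr": {t: truth.expr[t].tolist() for t in truth.expr.columns},
        "de_registry": {
            t: df.to_dict(orient="list") for t, df in truth.de_registry.items()
        },
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_truth(path) -> Truth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    expr = pd.DataFrame(
        payload["expr"], index=pd.Index(payload["gene_ids"], name="gene_id")
    )
    registry = {t: pd.DataFrame(d) for t, d in payload["de_registry"].items()}
    return Truth(expr=expr, de_registry=registry)


def read_config(path) -> SimConfig:
    """Parse and validate a run-configuration JSON (pydantic error paths)."""
    return SimConfig.model_validate_json(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# bundle directory
# ---------------------------------------------------------------------------

def write_bundle(bundle: StudyBundle, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(bundle.counts, outdir / "counts.tsv")
    write_sample_sheet(bundle.meta, outdir / "samples.tsv")
    write_mapping_stats(bundle.mapping_stats, outdir / "mapping_stats.tsv")
    write_coverage(bundle.coverage, outdir / "coverage.tsv")
    write_gene_model(bundle.gene_model, outdir / "gene_model.tsv")
    if bundle.truth is not None:
        write_truth(bundle.truth, outdir / "truth.json")
    return outdir


def read_bundle(indir) -> StudyBundle:
    indir = Path(indir)
    meta = read_sample_sheet(indir / "samples.tsv")
    library_sizes = (
        pd.Series(meta["library_size"].to_numpy(), index=meta["sample_id"].to_numpy())
        if "library_size" in meta.columns
        else None
    )
    counts = read_counts(indir / "counts.tsv", library_sizes=library_sizes)
    truth_path = indir / "truth.json"
    return StudyBundle(
        gene_model=read_gene_model(indir / "gene_model.tsv"),
        counts=counts,
        meta=meta,
        mapping_stats=read_mapping_stats(indir / "mapping_stats.tsv"),
        coverage=read_coverage(indir / "coverage.tsv"),
        truth=read_truth(truth_path) if truth_path.exists() else None,
    )


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def _fmt_pct(x: float) -> str:
    s = f"{x * 100:.1f}"
    return s[:-2] if s.endswith(".0") else s


def summarize_mapping(
    mapping_stats: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: tuple[str, ...] = ("tissue", "protocol"),
) -> pd.DataFrame:
    """Per-group mapping-category summary formatted as "mean (min–max)" percent.

    Groups the sample sheet by ``grouping`` columns; every sample in
    ``mapping_stats`` must appear in the sheet. Empty groups are dropped
    with a warning.
    """
    missing = set(mapping_stats.index) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
    joined = meta.set_index("sample_id").join(mapping_stats, how="inner")
    rows = []
    for key, grp in joined.groupby(list(grouping), observed=True):
        if grp.empty:  # pragma: no cover - groupby omits empty groups
            warnings.warn(f"empty group {key}")
            continue
        key = key if isinstance(key, tuple) else (key,)
        row = {col: val for col, val in zip(grouping, key)}
        row["n"] = len(grp)
        for cat in MAPPING_CATEGORIES:
            vals = grp[cat]
            row[cat] = f"{_fmt_pct(vals.mean())} ({_fmt_pct(vals.min())}–{_fmt_pct(vals.max())})"
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_mapping_numeric(
    mapping_stats: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: tuple[str, ...] = ("tissue", "protocol"),
) -> pd.DataFrame:
    """Full-precision per-group mean/min/max fractions (for JSON serialization)."""
    joined = meta.set_index("sample_id").join(mapping_stats, how="inner")
    agg = joined.groupby(list(grouping), observed=True)[list(MAPPING_CATEGORIES)].agg(
        ["mean", "min", "max"]
    )
    agg.columns = [f"{cat}_{stat}" for cat, stat in agg.columns]
    return agg.reset_index()
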
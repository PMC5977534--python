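"""Core data containers and the simulation configuration.

Counts, sample metadata, mapping statistics and gene annotation travel as
pandas objects; small value types (saturation curves, depth requirements,
fold-change agreement records) are dataclasses. The simulation
configuration is a pydantic model so that JSON run configs are validated
with explicit error paths.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

#: Read-mapping categories, in canonical column order.
MAPPING_CATEGORIES = ("exon", "intron_intergenic", "rRNA", "multi", "unmapped")

TISSUES = ("FF", "FFPE")
PROTOCOLS = ("polyA", "ribo")

# Default per-protocol mean mapping fractions for the tissue x protocol
# design. The FF ribosomal-depletion vector is renormalized: its raw
# one-decimal means sum to 99.8%.
_FF_RIBO_RAW = np.array([0.214, 0.444, 0.247, 0.063, 0.030])
DEFAULT_MAPPING_FRACTIONS: dict[str, dict[str, dict[str, float]]] = {
    "FF": {
        "polyA": dict(zip(MAPPING_CATEGORIES, (0.580, 0.250, 0.013, 0.119, 0.038))),
        "ribo": dict(zip(MAPPING_CATEGORIES, (_FF_RIBO_RAW / _FF_RIBO_RAW.sum()).tolist())),
    },
    "FFPE": {
        "polyA": dict(zip(MAPPING_CATEGORIES, (0.292, 0.282, 0.127, 0.059, 0.240))),
        "ribo": dict(zip(MAPPING_CATEGORIES, (0.084, 0.702, 0.053, 0.065, 0.096))),
    },
}

GENE_MODEL_COLUMNS = ("gene_id", "length_bp", "gene_class", "has_polyA")
SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "tumor_id",
    "tissue",
    "protocol",
    "input_ng",
    "archive_years",
    "library_size",
)


class SimConfig(BaseModel):
    """Study-design parameters for the matched FF/FFPE simulator.

    Expression is parameterized on the log2 scale; noise SDs are per gene
    per library. ``mapping_fractions[tissue][protocol]`` gives the five
    read-category fractions (must sum to 1).
    """

    n_genes: int = Field(default=23_000, ge=10)
    mu_logexpr: float = 4.0
    sigma_logexpr: float = Field(default=2.0, gt=0)
    n_tumors: int = Field(default=3, ge=1)
    frac_de_genes: float = Field(default=0.35, ge=0.0, le=1.0)
    de_effect_sd: float = Field(default=2.0, ge=0.0)
    sigma_tissue: float = Field(default=0.98, ge=0.0)
    sigma_protocol: float = Field(default=0.30, ge=0.0)
    sigma_input_100ng: float = Field(default=0.0, ge=0.0)
    frag_mean_bp: float = Field(default=500.0, gt=0)
    ff_polyA_tilt: float = Field(default=1.2, ge=1.0)
    mapping_fractions: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=lambda: {
            t: {p: dict(v) for p, v in d.items()}
            for t, d in DEFAULT_MAPPING_FRACTIONS.items()
        }
    )
    depth_total_reads: int = Field(default=30_000_000, gt=0)
    input_ng_levels: tuple[float, ...] = (100.0, 500.0)
    frac_rrna_genes: float = Field(default=0.005, ge=0.0, lt=1.0)
    frac_other_genes: float = Field(default=0.02, ge=0.0, lt=1.0)
    coverage_reads: int = Field(default=100_000, gt=0)
    coverage_n_transcripts: int = Field(default=200, gt=0)
    seed: int = 0

    @field_validator("mapping_fractions")
    @classmethod
    def _check_fractions(cls, mf):
        for tissue, per_protocol in mf.items():
            if tissue not in TISSUES:
                raise ValueError(f"unknown tissue {tissue!r}")
            for protocol, fr in per_protocol.items():
                if protocol not in PROTOCOLS:
                    raise ValueError(f"unknown protocol {protocol!r}")
                missing = set(MAPPING_CATEGORIES) - set(fr)
                if missing:
                    raise ValueError(
                        f"mapping_fractions[{tissue}][{protocol}] missing {sorted(missing)}"
                    )
                vec = np.array([fr[c] for c in MAPPING_CATEGORIES], dtype=float)
                if (vec < 0).any():
                    raise ValueError(
                        f"mapping_fractions[{tissue}][{protocol}] has negative entries"
                    )
                if abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"mapping_fractions[{tissue}][{protocol}] sums to {vec.sum()!r}, not 1"
                    )
        return mf

    @model_validator(mode="after")
    def _check_gene_classes(self):
        if self.frac_rrna_genes + self.frac_other_genes >= 1.0:
            raise ValueError("rRNA + other gene fractions must be < 1")
        return self

    def fractions_vector(self, tissue: str, protocol: str) -> np.ndarray:
        try:
            fr = self.mapping_fractions[tissue][protocol]
        except KeyError:
            raise KeyError(f"no mapping fractions for tissue={tissue!r}, protocol={protocol!r}")
        return np.array([fr[c] for c in MAPPING_CATEGORIES], dtype=float)


def validate_gene_model(gene_model: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (gene_id, length_bp, gene_class, has_polyA)."""
    missing = set(GENE_MODEL_COLUMNS) - set(gene_model.columns)
    if missing:
        raise ValueError(f"gene model missing columns {sorted(missing)}")
    if gene_model["gene_id"].duplicated().any():
        dup = gene_model.loc[gene_model["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    if (gene_model["length_bp"] < 100).any():
        raise ValueError("gene lengths must be >= 100 bp")
    bad = ~gene_model["gene_class"].isin(["mRNA", "rRNA", "other"])
    if bad.any():
        raise ValueError(f"unknown gene_class values: {gene_model.loc[bad, 'gene_class'].unique()}")
    rrna_polya = (gene_model["gene_class"] == "rRNA") & gene_model["has_polyA"]
    if rrna_polya.any():
        raise ValueError("rRNA genes must have has_polyA = False")
    return gene_model


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus total library sizes.

    ``library_sizes`` is the total number of sequenced fragments per
    sample (exonic and non-exonic), so column sums are <= library sizes.
    """

    counts: pd.DataFrame  # index gene_id, columns sample_id
    library_sizes: pd.Series  # index sample_id

    def __post_init__(self):
        if not np.issubdtype(np.asarray(self.counts).dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
            raise ValueError(f"library sizes missing for samples {missing}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        short = self.counts.sum(axis=0) > self.library_sizes
        if short.any():
            raise ValueError(
                f"library_sizes smaller than column sums for {list(short.index[short])}"
            )
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def column(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]


@dataclass
class ExpressionMatrix:
    """Floored log2-scale normalized expression (same shape as its source counts)."""

    values: pd.DataFrame
    floor: float = 5.0

    def __post_init__(self):
        if (self.values.to_numpy() < self.floor - 1e-12).any():
            raise ValueError("expression values below floor")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def column(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


@dataclass
class CoverageProfile:
    """Mean relative coverage along the transcript body, 5' (bin 1) to 3' (bin n)."""

    sample_id: str
    bins: np.ndarray  # normalized to mean 1

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if (self.bins < 0).any():
            raise ValueError("coverage bins must be non-negative")
        if abs(self.bins.mean() - 1.0) > 1e-9:
            raise ValueError("coverage bins must be normalized to mean 1")


@dataclass
class Truth:
    """Ground truth of a simulated study.

    ``expr`` holds true log2 expression per tumor (genes x tumors);
    ``de_registry`` maps tumor_id to a table of (gene_id, effect) for the
    genes that received a tumor-specific additive log2 effect.
    """

    expr: pd.DataFrame
    de_registry: dict[str, pd.DataFrame]

    def true_fc(self, tumor_a: str, tumor_b: str) -> pd.Series:
        return self.expr[tumor_a] - self.expr[tumor_b]

    def de_genes_between(self, tumor_a: str, tumor_b: str) -> pd.Index:
        """Genes whose true log2 FC between two tumors is nonzero."""
        fc = self.true_fc(tumor_a, tumor_b)
        return fc.index[fc != 0]


@dataclass
class StudyBundle:
    """A complete simulated (or loaded) study: annotation, counts, design, QC."""

    gene_model: pd.DataFrame
    counts: CountMatrix
    meta: pd.DataFrame  # sample sheet
    mapping_stats: pd.DataFrame  # index sample_id, columns MAPPING_CATEGORIES
    coverage: pd.DataFrame  # index sample_id, columns bin_1..bin_n
    truth: Optional[Truth] = None

    def __post_init__(self):
        if list(self.counts.sample_ids) != list(self.meta["sample_id"]):
            raise ValueError("counts columns and sample sheet rows must match 1:1")

    def samples_where(self, **conditions) -> pd.DataFrame:
        """Rows of the sample sheet matching all equality conditions."""
        mask = pd.Series(True, index=self.meta.index)
        for key, value in conditions.items():
            mask &= self.meta[key] == value
        return self.meta[mask]


@dataclass
class SaturationCurve:
    """Monotone detected-genes vs exonic-reads relationship.

    ``form`` is 'hyperbola' (G(r) = G_max * r / (r + K), closed-form
    inverse) or 'monotone_interpolant' (shape-preserving cubic through
    depth-averaged points).
    """

    form: Literal["hyperbola", "monotone_interpolant"]
    g_max: Optional[float] = None
    k: Optional[float] = None
    interpolant: object = None
    rmse: float = float("nan")
    points: Optional[pd.DataFrame] = None
    max_observed_reads: float = 0.0

    def predict(self, exonic_reads):
        r = np.asarray(exonic_reads, dtype=float)
        if self.form == "hyperbola":
            return self.g_max * r / (r + self.k)
        return np.clip(self.interpolant(r), 0.0, None)

    def invert(self, target_genes: float) -> float:
        """Exonic reads needed to detect ``target_genes`` genes."""
        from scipy.optimize import brentq

        if target_genes <= 0:
            raise ValueError("target_genes must be positive")
        if self.form == "hyperbola":
            if target_genes >= self.g_max:
                raise ValueError(
                    f"unreachable target: {target_genes} genes >= curve plateau {self.g_max:.1f}"
                )
            return self.k * target_genes / (self.g_max - target_genes)
        hi = self.max_observed_reads
        if target_genes > self.predict(hi):
            raise ValueError(
                f"unreachable target: {target_genes} genes beyond interpolant range"
            )
        return brentq(lambda r: float(self.predict(r)) - target_genes, 0.0, hi)


@dataclass
class DepthRequirement:
    """Total sequencing depth required to reach a detected-gene target."""

    group: str
    target_genes: int
    exonic_fraction: float
    required_exonic_reads: float
    required_total_reads: float = field(init=False)

    def __post_init__(self):
        if not 0 < self.exonic_fraction <= 1:
            raise ValueError("exonic_fraction must be in (0, 1]")
        self.required_total_reads = self.required_exonic_reads / self.exonic_fraction


@dataclass
class FCAgreement:
    """Sign agreement of fold changes between a matched pair of comparisons.

    ``fraction_agree`` is None when no gene passes the selection threshold.
    """

    threshold: float
    n_selected: int
    n_agree: int
    pair_labels: tuple[str, str] = ("FFPE", "FF")

    def __post_init__(self):
        if self.n_agree > self.n_selected:
            raise ValueError("n_agree cannot exceed n_selected")

    @property
    def fraction_agree(self) -> Optional[float]:
        if self.n_selected == 0:
            return None
        return self.n_agree / self.n_selected
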
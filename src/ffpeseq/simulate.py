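"""Synthetic matched FF/FFPE study generator.

The generator emulates the statistical structure a protocol-comparison
analysis relies on:

* a shared per-tumor transcriptome on the log2 scale, with tumor-specific
  additive effects on a configurable fraction of genes (the ground-truth
  differential signal shared by both tissue preparations);
* multiplicative log-normal capture noise, independent per gene per
  library, with an extra FFPE component — this yields a closed-form
  Pearson attenuation between matched FF and FFPE log expression;
* protocol/tissue-specific read-category budgets (exon, intron/intergenic,
  rRNA, multiple-alignment, unmapped) applied to a fixed total depth;
* positional coverage along the transcript body: exponential fragment
  survival from the 3' end for degraded FFPE RNA under poly(A) capture,
  uniform coverage for ribosomal depletion, and a mild fixed 3' tilt for
  intact FF RNA under poly(A) capture.

Random streams are keyed by ``[seed, stage, tumor, tissue, protocol,
input]`` so adding samples to a design never perturbs existing ones.
"""
from __future__ import annotations

import warnings
from math import exp, sqrt

import numpy as np
import pandas as pd

from .coverage import meta_coverage
from .models import (
    MAPPING_CATEGORIES,
    PROTOCOLS,
    TISSUES,
    CountMatrix,
    CoverageProfile,
    SimConfig,
    StudyBundle,
    Truth,
    validate_gene_model,
)

# Stage codes of the seeding scheme.
_STAGE_GENE_MODEL = 0
_STAGE_TRUTH = 1
_STAGE_COUNTS = 2
_STAGE_COVERAGE = 3
_STAGE_PROTOCOL_OFFSET = 4

_TISSUE_CODE = {t: i for i, t in enumerate(TISSUES)}
_PROTOCOL_CODE = {p: i for i, p in enumerate(PROTOCOLS)}


def _rng(seed: int, stage: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage, *keys])


def make_gene_model(
    config: SimConfig,
    *,
    mean_log_length: float = 7.3,
    sd_log_length: float = 0.6,
    min_length: int = 200,
    fixed_length: int | None = None,
) -> pd.DataFrame:
    """Draw a gene universe: lengths, classes and poly(A) status.

    Lengths are log-normal (median ~1.5 kb) clipped below at
    ``min_length``; a small fraction of genes is rRNA (never
    polyadenylated) or 'other' non-poly(A) RNA. ``fixed_length`` overrides
    the length distribution (useful for coverage oracles).
    """
    rng = _rng(config.seed, _STAGE_GENE_MODEL)
    n = config.n_genes
    if fixed_length is not None:
        lengths = np.full(n, int(fixed_length))
    else:
        lengths = np.maximum(
            np.exp(rng.normal(mean_log_length, sd_log_length, n)).astype(int), min_length
        )
    classes = np.full(n, "mRNA", dtype=object)
    u = rng.random(n)
    classes[u < config.frac_rrna_genes] = "rRNA"
    classes[(u >= config.frac_rrna_genes) & (u < config.frac_rrna_genes + config.frac_other_genes)] = "other"
    has_polya = classes == "mRNA"
    width = len(str(n))
    gene_ids = [f"G{i:0{width}d}" for i in range(n)]
    gm = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": lengths,
            "gene_class": classes,
            "has_polyA": has_polya,
        }
    )
    return validate_gene_model(gm)


def simulate_truth(config: SimConfig, gene_ids=None) -> Truth:
    """Per-tumor true log2 expression and the differential-effect registry.

    Baseline expression is Normal(mu_logexpr, sigma_logexpr); each tumor
    independently perturbs a ``frac_de_genes`` fraction of genes by an
    additive Normal(0, de_effect_sd) log2 effect.
    """
    n = config.n_genes
    if gene_ids is None:
        width = len(str(n))
        gene_ids = [f"G{i:0{width}d}" for i in range(n)]
    base_rng = _rng(config.seed, _STAGE_TRUTH, 0)
    baseline = base_rng.normal(config.mu_logexpr, config.sigma_logexpr, n)
    expr = {}
    registry = {}
    for t in range(config.n_tumors):
        tumor_id = f"T{t + 1}"
        rng = _rng(config.seed, _STAGE_TRUTH, t + 1)
        is_de = rng.random(n) < config.frac_de_genes
        effects = np.zeros(n)
        effects[is_de] = rng.normal(0.0, config.de_effect_sd, int(is_de.sum()))
        expr[tumor_id] = baseline + effects
        registry[tumor_id] = pd.DataFrame(
            {
                "gene_id": np.asarray(gene_ids, dtype=object)[is_de],
                "effect": effects[is_de],
                "sign": np.sign(effects[is_de]).astype(int),
            }
        )
    return Truth(expr=pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id")), de_registry=registry)


def _allocate_categories(depth: int, fractions: np.ndarray) -> np.ndarray:
    """Integer category totals: exact rounding for exons, largest-remainder
    allocation of the remaining reads across the other four categories."""
    exon = int(round(depth * fractions[0]))
    rest = depth - exon
    others = fractions[1:]
    if others.sum() <= 0:
        alloc = np.zeros(4, dtype=int)
        alloc[-1] = rest
    else:
        quota = rest * others / others.sum()
        alloc = np.floor(quota).astype(int)
        shortfall = rest - alloc.sum()
        order = np.argsort(-(quota - alloc))
        alloc[order[:shortfall]] += 1
    return np.concatenate([[exon], alloc])


def protocol_offset(config: SimConfig, protocol: str, n_genes: int) -> np.ndarray:
    """Per-gene log2 capture bias of a library chemistry.

    Drawn once per study per protocol (Normal(0, sigma_protocol)) and
    shared by every library prepared with that protocol, so libraries of
    one protocol agree with each other more than across protocols.
    """
    if config.sigma_protocol == 0:
        return np.zeros(n_genes)
    rng = _rng(config.seed, _STAGE_PROTOCOL_OFFSET, _PROTOCOL_CODE[protocol])
    return rng.normal(0.0, config.sigma_protocol, n_genes)


def _gene_weights(truth_vector, gene_model, tissue, protocol, input_ng, config, rng):
    # shared protocol chemistry bias + independent per-library capture noise
    shift = protocol_offset(config, protocol, len(truth_vector))
    sd2 = 0.0
    if tissue == "FFPE":
        sd2 += config.sigma_tissue**2
    if input_ng < 250:
        sd2 += config.sigma_input_100ng**2
    if sd2 > 0:
        shift = shift + rng.normal(0.0, sqrt(sd2), len(truth_vector))
    w = np.exp2(np.asarray(truth_vector, dtype=float) + shift)
    w[(gene_model["gene_class"] == "rRNA").to_numpy()] = 0.0
    if protocol == "polyA":
        w[~gene_model["has_polyA"].to_numpy()] = 0.0
    return w


def _sample_positions(lengths, per_transcript_reads, tissue, protocol, config, rng):
    """Per-transcript read-position histograms (5'->3'), one array per transcript."""
    vectors = []
    lam = config.frag_mean_bp
    tilt = config.ff_polyA_tilt
    for L, n_reads in zip(lengths, per_transcript_reads):
        L = int(L)
        if n_reads == 0:
            vectors.append(np.zeros(L))
            continue
        if protocol == "polyA" and tissue == "FFPE":
            # distance from the 3' end: truncated exponential fragment survival
            u = rng.random(n_reads)
            x = -lam * np.log1p(-u * (1.0 - exp(-L / lam)))
            pos = np.clip(np.floor(L - x), 0, L - 1).astype(int)
        elif protocol == "polyA" and tissue == "FF" and tilt > 1.0:
            # mild fixed enrichment of the last quintile
            q = 0.8 * L
            p_tail = tilt * 0.2 / (0.8 + 0.2 * tilt)
            in_tail = rng.random(n_reads) < p_tail
            pos = np.empty(n_reads)
            pos[~in_tail] = rng.random((~in_tail).sum()) * q
            pos[in_tail] = q + rng.random(in_tail.sum()) * (L - q)
            pos = np.clip(np.floor(pos), 0, L - 1).astype(int)
        else:
            pos = rng.integers(0, L, n_reads)
        vectors.append(np.bincount(pos, minlength=L).astype(float))
    return vectors


def simulate_library(
    truth_vector,
    gene_model: pd.DataFrame,
    tissue: str,
    protocol: str,
    config: SimConfig,
    *,
    input_ng: float = 500.0,
    counts_rng: np.random.Generator | None = None,
    coverage_rng: np.random.Generator | None = None,
    n_bins: int = 100,
):
    """Simulate one library: exonic counts, mapping stats, coverage profile.

    Returns ``(counts, mapping_fractions, CoverageProfile)`` where
    ``counts`` is an integer Series over the gene universe and
    ``mapping_fractions`` a dict over the five read categories (derived
    from exact integer category totals, so they sum to 1).
    """
    if tissue not in TISSUES or protocol not in config.mapping_fractions.get(tissue, {}):
        raise KeyError(f"no mapping fractions for tissue={tissue!r}, protocol={protocol!r}")
    fractions = config.fractions_vector(tissue, protocol)
    counts_rng = counts_rng if counts_rng is not None else _rng(config.seed, _STAGE_COUNTS, 0)
    coverage_rng = (
        coverage_rng if coverage_rng is not None else _rng(config.seed, _STAGE_COVERAGE, 0)
    )

    category_totals = _allocate_categories(config.depth_total_reads, fractions)
    exon_total = int(category_totals[0])
    mapping = dict(zip(MAPPING_CATEGORIES, (category_totals / config.depth_total_reads).tolist()))

    w = _gene_weights(truth_vector, gene_model, tissue, protocol, input_ng, config, counts_rng)
    gene_index = pd.Index(gene_model["gene_id"], name="gene_id")
    if w.sum() == 0 or exon_total == 0:
        if exon_total > 0:
            warnings.warn(f"zero exonic capture weight for {tissue}/{protocol}; all-zero column")
        counts = pd.Series(np.zeros(len(w), dtype=np.int64), index=gene_index)
    else:
        p = w / w.sum()
        counts = pd.Series(counts_rng.multinomial(exon_total, p).astype(np.int64), index=gene_index)

    profile = _simulate_coverage_profile(
        gene_model, w, tissue, protocol, config, coverage_rng, n_bins=n_bins
    )
    return counts, mapping, profile


def _simulate_coverage_profile(gene_model, weights, tissue, protocol, config, rng, n_bins=100):
    """Meta-gene coverage from a panel of transcripts (equal-weight pooling)."""
    eligible = np.flatnonzero(weights > 0)
    if eligible.size == 0:
        return CoverageProfile(sample_id="", bins=np.ones(n_bins))
    panel = rng.choice(eligible, size=min(config.coverage_n_transcripts, eligible.size), replace=False)
    lengths = gene_model["length_bp"].to_numpy()[panel]
    reads = rng.multinomial(config.coverage_reads, np.full(panel.size, 1.0 / panel.size))
    vectors = _sample_positions(lengths, reads, tissue, protocol, config, rng)
    bins = meta_coverage(vectors, n_bins=n_bins, weight="equal")
    return CoverageProfile(sample_id="", bins=bins)


def simulate_study(config: SimConfig) -> StudyBundle:
    """Full factorial study: tumors x {FF, FFPE} x {polyA, ribo} x input amounts.

    Deterministic under a fixed config seed; the ground truth is retained
    in the bundle for recovery tests.
    """
    gene_model = make_gene_model(config)
    truth = simulate_truth(config, gene_ids=gene_model["gene_id"].tolist())

    columns, meta_rows, mapping_rows, coverage_rows = {}, [], [], []
    for t in range(config.n_tumors):
        tumor_id = f"T{t + 1}"
        for tissue in TISSUES:
            for protocol in PROTOCOLS:
                for input_ng in config.input_ng_levels:
                    sample_id = f"{tumor_id}_{tissue}_{protocol}_{int(input_ng)}ng"
                    keys = (t, _TISSUE_CODE[tissue], _PROTOCOL_CODE[protocol], int(input_ng))
                    counts, mapping, profile = simulate_library(
                        truth.expr[tumor_id].to_numpy(),
                        gene_model,
                        tissue,
                        protocol,
                        config,
                        input_ng=input_ng,
                        counts_rng=_rng(config.seed, _STAGE_COUNTS, *keys),
                        coverage_rng=_rng(config.seed, _STAGE_COVERAGE, *keys),
                    )
                    columns[sample_id] = counts
                    meta_rows.append(
                        {
                            "sample_id": sample_id,
                            "tumor_id": tumor_id,
                            "tissue": tissue,
                            "protocol": protocol,
                            "input_ng": input_ng,
                            "archive_years": 4.5 if tissue == "FFPE" else 0.0,
                            "library_size": config.depth_total_reads,
                        }
                    )
                    mapping_rows.append({"sample_id": sample_id, **mapping})
                    coverage_rows.append(
                        pd.Series(profile.bins, name=sample_id,
                                  index=[f"bin_{i + 1}" for i in range(len(profile.bins))])
                    )

    counts_df = pd.DataFrame(columns)
    counts_df.index.name = "gene_id"
    meta = pd.DataFrame(meta_rows)
    counts = CountMatrix(
        counts=counts_df,
        library_sizes=pd.Series(
            meta["library_size"].to_numpy(), index=meta["sample_id"].to_numpy()
        ),
    )
    mapping_stats = pd.DataFrame(mapping_rows).set_index("sample_id")
    coverage = pd.DataFrame(coverage_rows)
    coverage.index.name = "sample_id"
    return StudyBundle(
        gene_model=gene_model,
        counts=counts,
        meta=meta,
        mapping_stats=mapping_stats,
        coverage=coverage,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Analytic noise-attenuation helpers
# ---------------------------------------------------------------------------

def expected_pairwise_cc(sigma_signal: float, noise_sd_a: float, noise_sd_b: float) -> float:
    """Expected Pearson correlation between two noisy readouts of a shared signal.

    For x_i = s + e_i with independent per-gene noise,
    cc = s^2 / sqrt((s^2 + e_a^2)(s^2 + e_b^2)).
    """
    v = sigma_signal**2
    return v / sqrt((v + noise_sd_a**2) * (v + noise_sd_b**2))


def sigma_tissue_for_cc(target_cc: float, sigma_signal: float, sigma_protocol: float) -> float:
    """FFPE capture-noise SD for which the FF/FFPE attenuation equals ``target_cc``.

    For matched FF/FFPE libraries of the *same* protocol the protocol
    chemistry bias is shared, so it acts as signal: the shared variance is
    sigma_signal^2 + sigma_protocol^2, FF carries no independent noise and
    FFPE carries sigma_tissue. Inverting ``expected_pairwise_cc`` gives
    sigma_tissue^2 = (sigma_signal^2 + sigma_protocol^2)(1/cc^2 - 1).
    """
    if not 0 < target_cc < 1:
        raise ValueError("target_cc must be in (0, 1)")
    shared = sigma_signal**2 + sigma_protocol**2
    return sqrt(shared * (1.0 / target_cc**2 - 1.0))
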
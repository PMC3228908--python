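"""Synthetic cohorts, allele counts and indexed FASTQ reads with known truth.

The generators emulate the study design the package targets: ~52 brain
samples genotyped at one marker SNP per gene, ~70 candidate genes with only
mSNP heterozygotes assayed (3-36 per gene), per-gene/sample read depths of
roughly 1,000-75,000, and gene-specific allele amplification bias up to
~1.5-fold.  Every observable is traceable to a truth table.

Randomness uses numpy's PCG64 (``numpy.random.default_rng``), an
integer-state generator with documented, platform-independent streams; all
entry points accept a seed or Generator and are fully deterministic under a
fixed seed.

Count model: a heterozygote's gDNA carries the alleles 1:1, so the M-allele
read count is Binomial(N, b/(1+b)) where b is the allele amplification bias;
cDNA counts follow Binomial(N, b*r/(1+b*r)) for true expression ratio r.
Study-scale generation adds a per-measurement log2-normal bias jitter
(``extra_log2_sd``) representing run-to-run PCR variability, calibrated so
that ~95% of null measurements fall within the +/-0.29 log2 significance
envelope; pure-binomial behaviour is recovered by setting it to 0.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distribution_model import RegulatoryModel, RegulatoryVariant, predict_distribution
from .sequence_io import AmpliconReference, SampleIndex, revcomp

__all__ = [
    "GeneDesign",
    "StudyDesign",
    "StudyData",
    "generate_indices",
    "generate_reference",
    "generate_cohort",
    "generate_counts",
    "generate_study",
    "generate_fastq",
    "default_study_design",
    "default_extra_log2_sd",
    "calibrated_gdna_ratios",
    "calibrated_error_cloud",
]

# observed per-gene/sample read-depth spans of the assay being emulated
GDNA_DEPTH_RANGE = (1_079, 33_250)
CDNA_DEPTH_RANGE = (1_277, 75_440)
#: log2 variance of the allele ratio induced by Binomial(N, 1/2) sampling
_BINOM_LOG2_VAR = 4.0 / math.log(2.0) ** 2  # divide by N


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _log_uniform_int(rng, lo: float, hi: float, size=None):
    return np.asarray(
        np.round(np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))), dtype=int
    )


def generate_indices(n: int, seed=None, min_distance: int = 2) -> list[SampleIndex]:
    """n unique 5-base sample indices with position-1 == position-5 redundancy.

    Indices are greedily packed to pairwise Hamming distance >= ``min_distance``
    over the full 5-mer.  The redundant position caps what this design can
    achieve: at most ~16 indices exist at distance 3 (single-error-correcting),
    so the default is 2, which suffices for a 52-sample run; request
    ``min_distance=3`` for small runs needing unambiguous 1-mismatch
    correction.
    """
    rng = _rng(seed)
    candidates = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
    rng.shuffle(candidates)
    chosen: list[str] = []
    for c in candidates:
        idx = c[0] + c[1:] + c[0]
        if all(
            sum(a != b for a, b in zip(idx, other)) >= min_distance for other in chosen
        ):
            chosen.append(idx)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(
            f"could only pack {len(chosen)} indices at min distance {min_distance}"
        )
    return [SampleIndex(f"S{i + 1:03d}", s) for i, s in enumerate(sorted(chosen))]


def generate_reference(
    n_genes: int, seed=None, length_range: tuple[int, int] = (76, 100)
) -> list[AmpliconReference]:
    """Random amplicon references with centrally placed marker SNPs."""
    rng = _rng(seed)
    refs = []
    for i in range(n_genes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        offset = length // 2 + int(rng.integers(-5, 6))
        allele_M = seq[offset]
        allele_m = rng.choice([b for b in "ACGT" if b != allele_M])
        refs.append(
            AmpliconReference(
                gene=f"GENE{i + 1:03d}",
                amplicon_seq=seq,
                msnp_offset=offset,
                allele_M=allele_M,
                allele_m=str(allele_m),
                numerator_allele=str(rng.choice(["M", "m"])),
            )
        )
    return refs


def generate_cohort(n: int, marker_freq: float, seed=None) -> pd.DataFrame:
    """Genotypes (MM/Mm/mm) for n samples under Hardy-Weinberg equilibrium."""
    if not (0.0 < marker_freq < 1.0):
        raise ValueError("marker_freq must be in (0,1)")
    rng = _rng(seed)
    p = marker_freq
    probs = [p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]
    calls = rng.choice(["MM", "Mm", "mm"], size=n, p=probs)
    return pd.DataFrame(
        {"sample_id": [f"S{i + 1:03d}" for i in range(n)], "genotype": calls}
    )


def generate_counts(
    true_ratio: float, bias: float, depth: int, template: str, seed=None
) -> tuple[int, int]:
    """Binomial (count_M, count_m) for one measurement.

    gDNA ignores ``true_ratio`` (alleles are 1:1 in the genome); cDNA mixes
    the expression ratio r with the amplification bias b so that
    P(M read) = b*r/(1+b*r).
    """
    if true_ratio <= 0 or bias <= 0:
        raise ValueError("true_ratio and bias must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed)
    eff = bias if template == "gDNA" else bias * true_ratio
    p = eff / (1.0 + eff)
    c_m = int(rng.binomial(depth, p))
    return c_m, depth - c_m


@functools.lru_cache(maxsize=8)
def default_extra_log2_sd(
    depth_range: tuple[int, int] = GDNA_DEPTH_RANGE,
    envelope_halfwidth: float = 0.29,
    confidence: float = 0.95,
) -> float:
    """Extra-binomial log2 bias-jitter sd calibrated to the error envelope.

    Solves for the per-measurement log2-normal jitter such that, pooled over
    a log-uniform depth distribution, the central ``confidence`` mass of null
    log2 ratios spans +/-``envelope_halfwidth``.  This is the study condition
    the default design encodes: measurement error dominated by PCR
    variability rather than read sampling.
    """
    n_grid = np.exp(np.linspace(math.log(depth_range[0]), math.log(depth_range[1]), 256))
    binom_var = _BINOM_LOG2_VAR / n_grid

    def coverage(s0: float) -> float:
        sd = np.sqrt(s0 * s0 + binom_var)
        return float(np.mean(2 * stats.norm.cdf(envelope_halfwidth / sd) - 1))

    return float(
        optimize.brentq(lambda s: coverage(s) - confidence, 1e-4, 1.0, xtol=1e-8)
    )


@dataclass
class GeneDesign:
    """Per-gene simulation parameters.

    ``model`` draws each heterozygote's true cDNA log2 ratio from a
    regulatory-variant mixture; ``true_log2`` plants a constant instead; both
    None means a null gene (ratio 1).  ``extra_log2_sd`` None resolves to the
    calibrated default at generation time.
    """

    name: str
    marker_freq: float
    bias: float = 1.0
    model: RegulatoryModel | None = None
    true_log2: float | None = None
    gdna_depth_range: tuple[int, int] = GDNA_DEPTH_RANGE
    cdna_depth_range: tuple[int, int] = CDNA_DEPTH_RANGE
    extra_log2_sd: float | None = None


@dataclass
class StudyDesign:
    n_samples: int = 52
    genes: list[GeneDesign] = field(default_factory=list)
    seed: int = 0


@dataclass
class StudyData:
    counts: pd.DataFrame
    genotypes: pd.DataFrame
    truth: pd.DataFrame


def default_study_design(seed: int = 0, n_samples: int = 52, n_genes: int = 70) -> StudyDesign:
    """A study-scale design mirroring the assay's published composition.

    Genes split ~11% null (no regulatory variant), ~29% weakly regulated
    (small effect, weak marker linkage) and ~60% clearly regulated (single
    cis variant, moderate-to-complete linkage); biases drawn from
    [0.67, 1.5]; marker frequencies spread so per-gene heterozygote counts
    land in the study's 3-36 range.
    """
    rng = _rng(seed)
    n_null = round(n_genes * 8 / 70)
    n_weak = round(n_genes * 20 / 70)
    categories = ["null"] * n_null + ["weak"] * n_weak
    categories += ["strong"] * (n_genes - len(categories))
    rng.shuffle(categories)
    genes = []
    for i, cat in enumerate(categories):
        marker_freq = float(rng.uniform(0.08, 0.92))
        bias = float(rng.uniform(0.67, 1.5))
        model = None
        if cat != "null":
            sign = float(rng.choice([-1.0, 1.0]))
            if cat == "strong":
                effect = sign * float(rng.uniform(0.3, 0.9))
                dprime = float(rng.uniform(0.25, 1.0))
            else:
                effect = sign * float(rng.uniform(0.10, 0.22))
                dprime = float(rng.uniform(0.0, 0.35))
            model = RegulatoryModel(
                marker_freq=marker_freq,
                variants=[
                    RegulatoryVariant("A", float(rng.uniform(0.2, 0.8)), effect, dprime)
                ],
                noise_sd=0.0,
            )
        genes.append(
            GeneDesign(
                name=f"GENE{i + 1:03d}",
                marker_freq=marker_freq,
                bias=bias,
                model=model,
            )
        )
    return StudyDesign(n_samples=n_samples, genes=genes, seed=seed)


def generate_study(design: StudyDesign) -> StudyData:
    """Allele counts, genotypes and truth table for a full study design.

    For each gene, samples are genotyped under HWE at the gene's marker
    frequency; heterozygotes receive one gDNA and one cDNA measurement with
    log-uniform read depths, the gene's amplification bias perturbed by the
    per-measurement jitter, and (for cDNA) a true log2 ratio drawn from the
    gene's regulatory model.
    """
    rng = np.random.default_rng(design.seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(design.n_samples)]
    count_rows, geno_rows, truth_rows = [], [], []
    for gene in design.genes:
        s0 = (
            gene.extra_log2_sd
            if gene.extra_log2_sd is not None
            else default_extra_log2_sd()
        )
        p = gene.marker_freq
        genos = rng.choice(
            ["MM", "Mm", "mm"],
            size=design.n_samples,
            p=[p * p, 2 * p * (1 - p), (1 - p) * (1 - p)],
        )
        for s, g in zip(sample_ids, genos):
            geno_rows.append({"sample_id": s, "gene": gene.name, "genotype": g})
        het = [s for s, g in zip(sample_ids, genos) if g == "Mm"]
        if not het:
            continue
        if gene.model is not None:
            true_log2 = predict_distribution(gene.model).sample(
                len(het), rng=rng, sort=False
            )
        elif gene.true_log2 is not None:
            true_log2 = np.full(len(het), float(gene.true_log2))
        else:
            true_log2 = np.zeros(len(het))
        for s, tl in zip(het, true_log2):
            depth_g = int(_log_uniform_int(rng, *gene.gdna_depth_range))
            depth_c = int(_log_uniform_int(rng, *gene.cdna_depth_range))
            b_g = gene.bias * 2.0 ** rng.normal(0.0, s0)
            b_c = gene.bias * 2.0 ** rng.normal(0.0, s0)
            gm = int(rng.binomial(depth_g, b_g / (1 + b_g)))
            r = 2.0**tl
            cm = int(rng.binomial(depth_c, b_c * r / (1 + b_c * r)))
            count_rows.append(
                {"sample_id": s, "gene": gene.name, "template": "gDNA",
                 "count_M": gm, "count_m": depth_g - gm}
            )
            count_rows.append(
                {"sample_id": s, "gene": gene.name, "template": "cDNA",
                 "count_M": cm, "count_m": depth_c - cm}
            )
            truth_rows.append(
                {"sample_id": s, "gene": gene.name, "genotype": "Mm",
                 "true_log2": float(tl), "bias": gene.bias,
                 "bias_gdna_effective": b_g, "bias_cdna_effective": b_c,
                 "gdna_depth": depth_g, "cdna_depth": depth_c}
            )
    return StudyData(
        counts=pd.DataFrame(count_rows),
        genotypes=pd.DataFrame(geno_rows),
        truth=pd.DataFrame(truth_rows),
    )


def calibrated_gdna_ratios(
    n: int = 1371,
    envelope_halfwidth: float = 0.29,
    confidence: float = 0.95,
    depth_range: tuple[int, int] = GDNA_DEPTH_RANGE,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized gDNA linear ratios whose 95% envelope is the given half-width.

    Draws log-uniform read depths, solves the extra-binomial jitter so the
    pooled central ``confidence`` interval of log2 ratios spans
    +/-``envelope_halfwidth``, then simulates binomial counts with jittered
    1:1 bias.  Returns (linear ratios, read depths).
    """
    rng = _rng(seed)
    s0 = default_extra_log2_sd(depth_range, envelope_halfwidth, confidence)
    depths = _log_uniform_int(rng, *depth_range, size=n)
    jitter = 2.0 ** rng.normal(0.0, s0, size=n)
    p = jitter / (1.0 + jitter)
    c_m = rng.binomial(depths, p)
    c_m = np.clip(c_m, 1, depths - 1)  # ratios require both alleles observed
    ratios = c_m / (depths - c_m)
    return ratios, depths


def calibrated_error_cloud(
    n: int = 20_000,
    anchors: tuple[tuple[float, float], ...] = ((1_000, 0.16), (13_500, 0.10), (24_300, 0.09)),
    max_reads: float = 75_440,
    confidence: float = 0.95,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (log2 ratio, reads) cloud with prescribed tail quantiles.

    Construction, not measurement: read depths are log-uniform over
    (X_1, max_reads] and the log2 spread is piecewise-constant per depth band,
    with band sds solved (top band first) so that the pooled central
    ``confidence`` quantile of |log2 ratio| among points with reads > X_i
    equals E_i for every anchor (X_i, E_i).  Used to validate the rectangle
    error estimator against known truth.
    """
    rng = _rng(seed)
    anchors = tuple(sorted(anchors))
    xs = [a[0] for a in anchors]
    es = [a[1] for a in anchors]
    edges = xs + [float(max_reads)]
    if any(hi <= lo for lo, hi in zip(edges, edges[1:])):
        raise ValueError("anchor thresholds must be increasing and below max_reads")
    weights = np.diff(np.log(edges))
    k = len(anchors)
    z = stats.norm.ppf((1 + confidence) / 2)
    sds = np.empty(k)
    sds[k - 1] = es[k - 1] / z
    for i in range(k - 2, -1, -1):
        w = weights[i:]
        upper_cov = sum(
            wj * (2 * stats.norm.cdf(es[i] / sds[j]) - 1)
            for j, wj in zip(range(i + 1, k), w[1:])
        )
        target = confidence * w.sum() - upper_cov
        if not (0 < target < w[0]):
            raise ValueError(
                f"anchors infeasible at X={xs[i]}: higher-depth bands already "
                "exceed the requested coverage"
            )
        band_cov = target / w[0]
        sds[i] = es[i] / stats.norm.ppf((1 + band_cov) / 2)
    bands = rng.choice(k, size=n, p=weights / weights.sum())
    reads = np.exp(
        rng.uniform(np.log(np.array(edges[:-1]))[bands], np.log(np.array(edges[1:]))[bands])
    )
    log2_ratios = rng.normal(0.0, sds[bands])
    return log2_ratios, reads


def generate_fastq(
    path,
    counts: pd.DataFrame,
    references,
    indices,
    *,
    frac_failed_match: float = 0.30,
    frac_missing_msnp: float = 0.03,
    frac_full_length: float = 0.85,
    read_len: int = 76,
    error_rate: float = 0.0,
    min_read_length: int = 30,
    seed=None,
) -> pd.DataFrame:
    """Indexed FASTQ with planted allele counts and triage categories.

    ``counts`` (sample_id, gene, count_M, count_m) fixes the usable reads;
    extra reads are planted so that ``frac_failed_match`` of all reads carry
    random inserts that match no amplicon and ``frac_missing_msnp`` are
    truncated before the mSNP; ``frac_full_length`` of all reads have the
    full ``read_len``.  Substitution errors at ``error_rate`` apply across
    the whole read, including the index (index errors are recoverable only
    with correction-mode demultiplexing).  Returns the per-read truth table.
    """
    if frac_failed_match + frac_missing_msnp >= 1:
        raise ValueError("triage fractions must sum to < 1")
    rng = _rng(seed)
    ref_by_gene = {r.gene: r for r in references}
    idx_by_sample = {i.sample_id: i.index_seq for i in indices}
    idx_list = [i.index_seq for i in indices]

    n_usable = int((counts["count_M"] + counts["count_m"]).sum())
    total = int(round(n_usable / (1.0 - frac_failed_match - frac_missing_msnp)))
    n_fail = int(round(total * frac_failed_match))
    n_miss = max(total - n_usable - n_fail, 0)
    n_full_target = int(round(total * frac_full_length))
    n_usable_full = int(np.clip(n_full_target - n_fail, 0, n_usable))

    def msnp_read_pos(ref: AmpliconReference, orientation: str) -> int:
        """0-based mSNP position in read coordinates (after the index)."""
        if orientation == "forward":
            return ref.msnp_offset
        return len(ref.amplicon_seq) - 1 - ref.msnp_offset

    def build_body(ref: AmpliconReference, allele: str, orientation: str) -> str:
        seq = list(ref.amplicon_seq)
        seq[ref.msnp_offset] = ref.allele_M if allele == "M" else ref.allele_m
        s = "".join(seq)
        return s if orientation == "forward" else revcomp(s)

    specs: list[dict] = []
    for row in counts.itertuples():
        for allele, c in (("M", int(row.count_M)), ("m", int(row.count_m))):
            for _ in range(c):
                specs.append(
                    {"category": "usable", "sample_id": row.sample_id,
                     "gene": row.gene, "allele": allele}
                )
    full_flags = np.zeros(n_usable, dtype=bool)
    full_flags[rng.permutation(n_usable)[:n_usable_full]] = True

    reads: list[tuple[str, dict]] = []
    for spec, full in zip(specs, full_flags):
        ref = ref_by_gene[spec["gene"]]
        orientation = str(rng.choice(["forward", "reverse"]))
        pos = msnp_read_pos(ref, orientation)
        body = build_body(ref, spec["allele"], orientation)
        seq = idx_by_sample[spec["sample_id"]] + body
        if full or len(seq) < read_len:
            length = min(read_len, len(seq))
        else:
            lo = max(min_read_length + 1, 5 + pos + 2)
            length = int(rng.integers(lo, read_len)) if lo < read_len else read_len
        spec = {**spec, "orientation": orientation, "length": length}
        reads.append((seq[:length], spec))

    for _ in range(n_miss):
        row = counts.iloc[int(rng.integers(len(counts)))]
        ref = ref_by_gene[row["gene"]]
        orientation = "forward"
        pos = msnp_read_pos(ref, orientation)
        if pos + 5 <= min_read_length:  # mSNP too close to the read start: flip
            orientation = "reverse"
            pos = msnp_read_pos(ref, orientation)
        allele = str(rng.choice(["M", "m"]))
        body = build_body(ref, allele, orientation)
        length = int(rng.integers(min_read_length, min(5 + pos, read_len) + 1))
        seq = (idx_by_sample[row["sample_id"]] + body)[:length]
        reads.append(
            (seq, {"category": "missing_msnp", "sample_id": row["sample_id"],
                   "gene": row["gene"], "allele": allele,
                   "orientation": orientation, "length": length})
        )

    for _ in range(n_fail):
        idx = str(rng.choice(idx_list))
        body = "".join(rng.choice(list("ACGT"), size=read_len - 5))
        reads.append(
            (idx + body, {"category": "failed_match", "sample_id": "",
                          "gene": "", "allele": "", "orientation": "",
                          "length": read_len})
        )

    order = rng.permutation(len(reads))
    truth_rows = []
    with open(path, "w") as fh:
        for out_i, i in enumerate(order):
            seq, spec = reads[i]
            if error_rate > 0:
                arr = list(seq)
                for pos_err in np.flatnonzero(rng.random(len(arr)) < error_rate):
                    arr[pos_err] = str(
                        rng.choice([b for b in "ACGT" if b != arr[pos_err]])
                    )
                seq = "".join(arr)
            rid = f"r{out_i + 1:07d}"
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            truth_rows.append({"read_id": rid, **spec})
    return pd.DataFrame(truth_rows)
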
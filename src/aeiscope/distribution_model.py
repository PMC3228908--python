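"""Population-genetic model of log2 allelic-expression-imbalance distributions.

A transcribed marker SNP (mSNP, alleles M/m) distinguishes the two mRNA copies
of a gene within a heterozygous individual.  Cis-acting regulatory variants
(rVar) that are themselves heterozygous, and whose high-expression allele sits
in cis with one of the marker alleles, displace the log2 AEI ratio of that
individual away from zero.  Across a population of mSNP heterozygotes the
ordered log2AEI values therefore form a characteristic distribution whose
shape encodes, for each regulatory variant:

* its allele frequency ``P``,
* its additive contribution ``e`` (log2 units) when phased high-on-M,
* its linkage disequilibrium ``D'`` with the marker, and
* (optionally) pairwise ``D'`` between regulatory variants.

Effects combine additively on the log2 scale, i.e. multiplicatively on
expression.  Trans-acting factors scale both alleles equally and cancel in the
ratio; together with other unmodeled factors they are represented by a single
Gaussian noise term (``noise_sd``, log2 units).

The model is exact: for up to four regulatory variants the joint haplotype
distribution is enumerated, diplotypes are formed by random union of
haplotypes (Hardy-Weinberg) and conditioned on marker heterozygosity, and the
predicted log2AEI distribution is the resulting finite mixture convolved with
the noise term.  Fitting is a deterministic grid search minimizing a
quantile-matching objective between observed order statistics and the exact
mixture quantiles.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "RegulatoryVariant",
    "RegulatoryModel",
    "DiplotypeConfig",
    "PredictedDistribution",
    "GridSpec",
    "FitResult",
    "RegulatoryModelFitter",
    "haplotype_freqs",
    "build_joint",
    "enumerate_diplotypes",
    "expected_log2aei",
    "predict_distribution",
    "classify_shape",
    "fit_model",
    "example_models",
]

_IPF_TOL = 1e-10
_IPF_MAX_ITER = 5000


def haplotype_freqs(p_a: float, p_m: float, dprime: float) -> np.ndarray:
    """Two-locus haplotype frequencies from allele frequencies and D'.

    D' is the linkage-disequilibrium coefficient D normalized by its
    frequency-constrained maximum, so any value in [-1, 1] yields a valid
    (non-negative) frequency vector.

    Parameters
    ----------
    p_a : frequency of allele A at the first locus, in (0, 1).
    p_m : frequency of allele M at the second locus, in (0, 1).
    dprime : normalized LD coefficient in [-1, 1].

    Returns
    -------
    ndarray of four frequencies ordered (AM, Am, aM, am); sums to 1 and
    preserves both marginals.
    """
    if not (0.0 < p_a < 1.0) or not (0.0 < p_m < 1.0):
        raise ValueError(f"allele frequencies must be in (0,1); got {p_a}, {p_m}")
    if abs(dprime) > 1.0 + 1e-12:
        raise ValueError(f"|D'| must be <= 1; got {dprime}")
    if dprime >= 0:
        dmax = min(p_a * (1.0 - p_m), (1.0 - p_a) * p_m)
    else:
        dmax = min(p_a * p_m, (1.0 - p_a) * (1.0 - p_m))
    d = dprime * dmax
    f = np.array(
        [
            p_a * p_m + d,
            p_a * (1.0 - p_m) - d,
            (1.0 - p_a) * p_m - d,
            (1.0 - p_a) * (1.0 - p_m) + d,
        ]
    )
    # guard tiny negative round-off at |D'| = 1
    f = np.clip(f, 0.0, None)
    return f / f.sum()


@dataclass
class RegulatoryVariant:
    """A cis-acting regulatory variant.

    ``freq`` is the frequency of the indexed (high/low-expression) allele A;
    ``effect`` is its signed additive contribution to log2AEI when A lies on
    the M haplotype and a on the m haplotype; ``dprime_marker`` is D'(A,M).
    ``dprime_pairs`` optionally maps other variant names to pairwise D'.
    """

    name: str
    freq: float
    effect: float
    dprime_marker: float
    dprime_pairs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.freq < 1.0):
            raise ValueError(f"variant {self.name}: freq must be in (0,1)")
        if abs(self.dprime_marker) > 1.0:
            raise ValueError(f"variant {self.name}: |D'(to marker)| must be <= 1")
        if not math.isfinite(self.effect):
            raise ValueError(f"variant {self.name}: effect must be finite")


@dataclass
class RegulatoryModel:
    """Marker SNP plus a set of regulatory variants and a noise term."""

    marker_freq: float
    variants: list[RegulatoryVariant] = field(default_factory=list)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.marker_freq < 1.0):
            raise ValueError("marker_freq must be in (0,1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = [v.name for v in self.variants]
        if len(set(names)) != len(names):
            raise ValueError("variant names must be unique")

    @property
    def n_loci(self) -> int:
        return len(self.variants) + 1

    def to_dict(self) -> dict:
        return {
            "marker_freq": self.marker_freq,
            "noise_sd": self.noise_sd,
            "variants": [
                {
                    "name": v.name,
                    "freq": v.freq,
                    "effect": v.effect,
                    "dprime_marker": v.dprime_marker,
                    **(
                        {"dprime_pairs": dict(v.dprime_pairs)}
                        if v.dprime_pairs
                        else {}
                    ),
                }
                for v in self.variants
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegulatoryModel":
        variants = [
            RegulatoryVariant(
                name=v["name"],
                freq=float(v["freq"]),
                effect=float(v["effect"]),
                dprime_marker=float(v.get("dprime_marker", v.get("dprime", 0.0))),
                dprime_pairs=v.get("dprime_pairs"),
            )
            for v in d.get("variants", [])
        ]
        return cls(
            marker_freq=float(d["marker_freq"]),
            variants=variants,
            noise_sd=float(d.get("noise_sd", 0.0)),
        )


def build_joint(model: RegulatoryModel) -> tuple[np.ndarray, np.ndarray]:
    """Joint haplotype distribution over (variants..., marker).

    Haplotypes are rows of a 0/1 matrix; column ``i`` is variant ``i`` (1 =
    its indexed allele A), the last column is the marker (1 = M).  The joint
    reproduces every variant's allele frequency and its D' to the marker.
    With only variant-marker constraints the maximum-entropy solution makes
    variants conditionally independent given the marker allele and is built
    in closed form; when pairwise variant-variant D' values are supplied the
    joint is completed by iterative proportional fitting (IPF) to tolerance
    1e-10.

    Raises
    ------
    RuntimeError if the pairwise constraint set is infeasible (IPF fails to
    converge), naming the worst-fitting pair.
    """
    k = len(model.variants)
    if k > 4:
        raise ValueError("exact enumeration supports at most 4 variants")
    p_m = model.marker_freq
    haps = np.array(list(itertools.product([0, 1], repeat=k + 1)), dtype=np.int8)

    # two-locus target tables, indexed [variant_allele, marker_allele]
    marker_tables = []
    for v in model.variants:
        f_am, f_a_m, f_aM, f_am0 = haplotype_freqs(v.freq, p_m, v.dprime_marker)
        t = np.empty((2, 2))
        t[1, 1], t[1, 0], t[0, 1], t[0, 0] = f_am, f_a_m, f_aM, f_am0
        marker_tables.append(t)

    has_pairs = any(v.dprime_pairs for v in model.variants)
    if not has_pairs:
        # max-ent with (variant, marker) margins only: variants independent given marker
        freqs = np.where(haps[:, -1] == 1, p_m, 1.0 - p_m).astype(float)
        for i, t in enumerate(marker_tables):
            cond = t / t.sum(axis=0, keepdims=True)  # P(variant allele | marker)
            freqs *= cond[haps[:, i], haps[:, -1]]
        return haps, freqs

    # IPF over all specified pairwise constraints
    name_to_idx = {v.name: i for i, v in enumerate(model.variants)}
    constraints: list[tuple[tuple[int, int], np.ndarray, str]] = []
    for i, (v, t) in enumerate(zip(model.variants, marker_tables)):
        constraints.append(((i, k), t, f"({v.name}, marker)"))
    seen = set()
    for i, v in enumerate(model.variants):
        for other, dp in (v.dprime_pairs or {}).items():
            if other not in name_to_idx:
                raise ValueError(f"unknown variant in dprime_pairs: {other}")
            j = name_to_idx[other]
            key = tuple(sorted((i, j)))
            if key in seen:
                continue
            seen.add(key)
            f_ab, f_a_b, f_aB, f_ab0 = haplotype_freqs(
                v.freq, model.variants[j].freq, dp
            )
            t = np.empty((2, 2))
            t[1, 1], t[1, 0], t[0, 1], t[0, 0] = f_ab, f_a_b, f_aB, f_ab0
            constraints.append(((i, j), t, f"({v.name}, {model.variants[j].name})"))

    freqs = np.full(len(haps), 1.0 / len(haps))
    marg_freqs = [v.freq for v in model.variants] + [p_m]
    for col, p in enumerate(marg_freqs):
        freqs *= np.where(haps[:, col] == 1, p, 1.0 - p) * 2.0

    def pair_marginal(f: np.ndarray, cols: tuple[int, int]) -> np.ndarray:
        m = np.zeros((2, 2))
        np.add.at(m, (haps[:, cols[0]], haps[:, cols[1]]), f)
        return m

    for _ in range(_IPF_MAX_ITER):
        max_dev = 0.0
        worst = constraints[0][2]
        for cols, target, label in constraints:
            cur = pair_marginal(freqs, cols)
            dev = float(np.abs(cur - target).max())
            if dev > max_dev:
                max_dev, worst = dev, label
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
            freqs = freqs * ratio[haps[:, cols[0]], haps[:, cols[1]]]
        if max_dev < _IPF_TOL:
            break
    else:
        raise RuntimeError(
            f"IPF did not converge: constraint {worst} deviates by {max_dev:.3g}; "
            "the pairwise D' set is likely infeasible"
        )
    return haps, freqs


@dataclass(frozen=True)
class DiplotypeConfig:
    """Phase configuration of a marker-heterozygous diplotype.

    ``phases[v]`` is +1 if variant v's indexed allele lies on the M haplotype
    and the alternate allele on the m haplotype, -1 for the reverse phase, and
    0 if the individual is homozygous at v.
    """

    phases: tuple[int, ...]
    prob: float


def enumerate_diplotypes(
    haps: np.ndarray, freqs: np.ndarray
) -> list[DiplotypeConfig]:
    """Diplotypes by random union of haplotypes, conditioned on Mm marker het.

    Under Hardy-Weinberg the two haplotypes are independent draws; conditioning
    on the event {one carries M, the other m} makes the M- and m-haplotype
    independent draws from their renormalized frequency vectors.  Config
    probabilities sum to 1.
    """
    marker = haps[:, -1]
    f_M = float(freqs[marker == 1].sum())
    f_m = float(freqs[marker == 0].sum())
    if f_M <= 0 or f_m <= 0:
        raise ValueError("marker must be polymorphic: no heterozygotes exist")
    m_haps = haps[marker == 1, :-1]
    m_freqs = freqs[marker == 1] / f_M
    o_haps = haps[marker == 0, :-1]
    o_freqs = freqs[marker == 0] / f_m
    acc: dict[tuple[int, ...], float] = {}
    for hx, fx in zip(m_haps, m_freqs):
        if fx == 0:
            continue
        for hy, fy in zip(o_haps, o_freqs):
            p = fx * fy
            if p == 0:
                continue
            phases = tuple(int(a - b) for a, b in zip(hx, hy))
            acc[phases] = acc.get(phases, 0.0) + p
    return [DiplotypeConfig(ph, p) for ph, p in sorted(acc.items())]


def expected_log2aei(config: DiplotypeConfig, effects) -> float:
    """Additive log2AEI of one phase configuration: sum of effect * phase."""
    return float(np.dot(np.asarray(config.phases, dtype=float), np.asarray(effects, dtype=float)))


@dataclass
class PredictedDistribution:
    """Exact log2AEI mixture (support points + weights) plus Gaussian noise.

    ``values`` holds sorted sampled log2AEI ratios when a sample was drawn.
    """

    support: np.ndarray
    weights: np.ndarray
    noise_sd: float
    values: np.ndarray | None = None
    n_samples: int | None = None

    def mean(self) -> float:
        return float(np.dot(self.weights, self.support))

    def var(self) -> float:
        mu = self.mean()
        return float(np.dot(self.weights, (self.support - mu) ** 2) + self.noise_sd**2)

    def cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.noise_sd == 0:
            out = np.array(
                [float(self.weights[self.support <= xi].sum()) for xi in x]
            )
        else:
            z = (x[:, None] - self.support[None, :]) / self.noise_sd
            out = stats.norm.cdf(z) @ self.weights
        return out if out.size > 1 else float(out[0])

    def quantile(self, q) -> np.ndarray:
        """Exact mixture quantiles (inverse CDF)."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile levels must be in (0,1)")
        if self.noise_sd == 0:
            order = np.argsort(self.support)
            s, w = self.support[order], self.weights[order]
            cw = np.cumsum(w)
            idx = np.searchsorted(cw, q, side="left")
            return s[np.clip(idx, 0, len(s) - 1)]
        lo = float(self.support.min() - 8 * self.noise_sd)
        hi = float(self.support.max() + 8 * self.noise_sd)
        out = np.empty_like(q)
        for i, qi in enumerate(q):
            out[i] = optimize.brentq(
                lambda x: float(self.cdf(x)) - qi, lo, hi, xtol=1e-10
            )
        return out

    def expected_order_statistics(self, n: int) -> np.ndarray:
        """Mixture quantiles at Blom plotting positions (i-0.375)/(n+0.25)."""
        i = np.arange(1, n + 1)
        return self.quantile((i - 0.375) / (n + 0.25))

    def sample(self, n: int, rng=None, sort: bool = True) -> np.ndarray:
        """Draw n log2AEI values (config draw + Gaussian noise)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(rng)
        idx = rng.choice(len(self.support), size=n, p=self.weights)
        vals = self.support[idx]
        if self.noise_sd > 0:
            vals = vals + rng.normal(0.0, self.noise_sd, size=n)
        return np.sort(vals) if sort else vals


def predict_distribution(
    model: RegulatoryModel, n_samples: int | None = None, seed=None
) -> PredictedDistribution:
    """Predicted log2AEI distribution among marker heterozygotes.

    Returns the exact mixture; when ``n_samples`` is given the distribution
    additionally carries a seeded, sorted sample in ``.values``.
    """
    haps, freqs = build_joint(model)
    configs = enumerate_diplotypes(haps, freqs)
    effects = [v.effect for v in model.variants]
    acc: dict[float, float] = {}
    for c in configs:
        val = round(expected_log2aei(c, effects), 12)
        acc[val] = acc.get(val, 0.0) + c.prob
    support = np.array(sorted(acc))
    weights = np.array([acc[s] for s in support])
    weights = weights / weights.sum()
    dist = PredictedDistribution(support=support, weights=weights, noise_sd=model.noise_sd)
    if n_samples is not None:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        dist.values = dist.sample(n_samples, rng=seed)
        dist.n_samples = n_samples
    return dist


def classify_shape(values, threshold: float = 0.29) -> str:
    """Classify an ordered log2AEI distribution.

    null: no significant values; uniphasic: all significant values share one
    sign; biphasic: the minority sign holds >= 25% of significant values;
    skewed: otherwise.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values to classify a distribution")
    pos = int(np.sum(v > threshold))
    neg = int(np.sum(v < -threshold))
    if pos + neg == 0:
        return "null"
    minority = min(pos, neg)
    if minority == 0:
        return "uniphasic"
    if minority / (pos + neg) >= 0.25:
        return "biphasic"
    return "skewed"


@dataclass
class GridSpec:
    """Search grid for one regulatory variant (shared by all variants)."""

    freqs: np.ndarray
    effects: np.ndarray
    dprimes: np.ndarray

    @classmethod
    def default(cls, k: int = 1) -> "GridSpec":
        if k <= 1:
            return cls(
                freqs=np.round(np.arange(0.1, 0.91, 0.1), 10),
                effects=np.round(np.arange(-1.5, 1.51, 0.1), 10),
                dprimes=np.round(np.arange(0.0, 1.001, 0.125), 10),
            )
        return cls(
            freqs=np.array([0.3, 0.5, 0.7]),
            effects=np.round(np.arange(-1.2, 1.21, 0.3), 10),
            dprimes=np.array([0.0, 0.5, 1.0]),
        )


@dataclass
class FitResult:
    model: RegulatoryModel
    objective: float
    n_evaluated: int
    flat_objective: bool = False


def _phase_weights_k1(p_a: float, p_m: float, dprime: float) -> tuple[float, float, float]:
    """(w+, w-, w0) for a single variant among marker heterozygotes."""
    f = haplotype_freqs(p_a, p_m, dprime)
    f_M = f[0] + f[2]
    f_m = f[1] + f[3]
    qx = f[0] / f_M  # P(A on the M haplotype)
    qy = f[3] / f_m  # P(a on the m haplotype)
    w_plus = qx * qy
    w_minus = (1 - qx) * (1 - qy)
    return w_plus, w_minus, 1.0 - w_plus - w_minus


def _batch_mixture_quantiles(
    mus: np.ndarray, ws: np.ndarray, sigma: float, qs: np.ndarray, n_grid: int = 1024
) -> np.ndarray:
    """Quantiles of many Gaussian mixtures sharing one sigma.

    mus, ws: (n_models, n_support); returns (n_models, len(qs)).  Uses a dense
    shared CDF grid with linear inverse interpolation (adequate for a
    quantile-matching objective on a 0.1-spaced effect grid).
    """
    sigma = max(float(sigma), 1e-6)
    lo = float(mus.min() - 6 * sigma)
    hi = float(mus.max() + 6 * sigma)
    xg = np.linspace(lo, hi, n_grid)
    out = np.empty((mus.shape[0], qs.size))
    chunk = max(1, int(2e7 // (mus.shape[1] * n_grid)))
    for start in range(0, mus.shape[0], chunk):
        m = mus[start : start + chunk]
        w = ws[start : start + chunk]
        cdf = np.einsum(
            "ms,msg->mg", w, stats.norm.cdf((xg[None, None, :] - m[:, :, None]) / sigma)
        )
        for i in range(cdf.shape[0]):
            out[start + i] = np.interp(qs, cdf[i], xg)
    return out


def fit_model(
    observed,
    k: int = 1,
    marker_freq: float = 0.5,
    noise_sd: float | None = 0.1,
    error_curve=None,
    reads=None,
    grid: GridSpec | None = None,
    parsimony_tol: float = 0.05,
    seed=None,
) -> FitResult:
    """Fit a k-variant regulatory model to observed log2AEI values.

    Deterministic grid search over (P, effect, D') per variant, minimizing the
    mean squared difference between the sorted observed values and the exact
    mixture quantiles at Blom plotting positions for the matched sample size.
    Ties (objectives within ``parsimony_tol`` relative of the best) are broken
    toward the smallest total |effect| — the weakest model that explains the
    data.

    ``marker_freq`` is the known population frequency of the marker allele.
    When an ``error_curve`` and per-observation ``reads`` are supplied, the
    noise sd is set to the mean depth-specific error bound divided by the
    normal quantile of the curve's confidence level.  ``seed`` is accepted for
    interface symmetry; the search is deterministic.
    """
    obs = np.sort(np.asarray(observed, dtype=float))
    n = obs.size
    if n < 5:
        raise ValueError("need at least 5 observed values")
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if error_curve is not None and reads is not None:
        z = stats.norm.ppf((1 + error_curve.confidence) / 2)
        noise_sd = float(np.mean(error_curve.lookup(np.asarray(reads))) / z)
    if noise_sd is None:
        raise ValueError("provide noise_sd or (error_curve and reads)")
    grid = grid or GridSpec.default(k)
    qs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)

    flat = bool(np.ptp(obs) == 0)
    if flat:
        warnings.warn("observed values are all identical; objective is nearly flat")

    if k == 1:
        combos = []
        mus, ws = [], []
        for p in grid.freqs:
            for dp in grid.dprimes:
                wp, wm, w0 = _phase_weights_k1(float(p), marker_freq, float(dp))
                for e in grid.effects:
                    combos.append((float(p), float(e), float(dp)))
                    mus.append((e, -e, 0.0))
                    ws.append((wp, wm, w0))
        mus = np.asarray(mus)
        ws = np.asarray(ws)
        quants = _batch_mixture_quantiles(mus, ws, noise_sd, qs)
        objs = np.mean((quants - obs[None, :]) ** 2, axis=1)
        params_list = combos
        sum_abs_e = np.abs(mus[:, 0])
    else:
        per_variant = list(
            itertools.product(grid.freqs, grid.effects, grid.dprimes)
        )
        combos_iter = itertools.combinations_with_replacement(per_variant, k)
        params_list, mus_l, ws_l = [], [], []
        n_support = 3**k
        for combo in combos_iter:
            variants = [
                RegulatoryVariant(chr(ord("A") + i), float(p), float(e), float(dp))
                for i, (p, e, dp) in enumerate(combo)
            ]
            m = RegulatoryModel(marker_freq=marker_freq, variants=variants)
            haps, freqs = build_joint(m)
            configs = enumerate_diplotypes(haps, freqs)
            mu = np.zeros(n_support)
            w = np.zeros(n_support)
            effects = [v.effect for v in variants]
            for j, c in enumerate(configs):
                mu[j] = expected_log2aei(c, effects)
                w[j] = c.prob
            params_list.append(combo)
            mus_l.append(mu)
            ws_l.append(w)
        mus = np.asarray(mus_l)
        ws = np.asarray(ws_l)
        quants = _batch_mixture_quantiles(mus, ws, noise_sd, qs)
        objs = np.mean((quants - obs[None, :]) ** 2, axis=1)
        sum_abs_e = np.array([sum(abs(e) for (_, e, _) in c) for c in params_list])

    best = float(objs.min())
    tol = best * parsimony_tol + 1e-12
    cand = np.flatnonzero(objs <= best + tol)
    # parsimony: weakest total effect, then weakest total linkage, then first
    if k == 1:
        keys = [(sum_abs_e[i], abs(params_list[i][2]), i) for i in cand]
    else:
        keys = [
            (sum_abs_e[i], sum(abs(dp) for (_, _, dp) in params_list[i]), i)
            for i in cand
        ]
    pick = min(keys)[2]

    if k == 1:
        p, e, dp = params_list[pick]
        variants = [RegulatoryVariant("A", p, e, dp)]
    else:
        variants = [
            RegulatoryVariant(chr(ord("A") + i), float(p), float(e), float(dp))
            for i, (p, e, dp) in enumerate(params_list[pick])
        ]
    model = RegulatoryModel(
        marker_freq=marker_freq, variants=variants, noise_sd=float(noise_sd)
    )
    return FitResult(
        model=model,
        objective=float(objs[pick]),
        n_evaluated=int(len(objs)),
        flat_objective=flat,
    )


class RegulatoryModelFitter(BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_model`.

    ``fit(X)`` takes a 1-d array of observed log2AEI values; fitted attributes
    are ``model_``, ``objective_`` and ``n_evaluated_``.
    """

    def __init__(
        self,
        k: int = 1,
        marker_freq: float = 0.5,
        noise_sd: float | None = 0.1,
        grid: GridSpec | None = None,
        parsimony_tol: float = 0.05,
    ):
        self.k = k
        self.marker_freq = marker_freq
        self.noise_sd = noise_sd
        self.grid = grid
        self.parsimony_tol = parsimony_tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).ravel()
        res = fit_model(
            X,
            k=self.k,
            marker_freq=self.marker_freq,
            noise_sd=self.noise_sd,
            grid=self.grid,
            parsimony_tol=self.parsimony_tol,
        )
        self.model_ = res.model
        self.objective_ = res.objective
        self.n_evaluated_ = res.n_evaluated
        return self

    def predict_distribution(self, n_samples: int | None = None, seed=None):
        if not hasattr(self, "model_"):
            raise AttributeError("fit must be called first")
        return predict_distribution(self.model_, n_samples=n_samples, seed=seed)


def example_models() -> dict[str, RegulatoryModel]:
    """Named parameterizations producing the three canonical shapes.

    uniphasic: one variant fully linked to the marker with matched frequency —
    every heterozygote is displaced the same way.  skewed: one partially
    linked variant plus one unlinked weaker variant — mostly one sign with a
    minority tail.  biphasic: two unlinked variants — balanced positive and
    negative displacements.
    """
    return {
        "uniphasic": RegulatoryModel(
            marker_freq=0.45,
            variants=[RegulatoryVariant("A", 0.45, 0.8, 1.0)],
            noise_sd=0.10,
        ),
        "skewed": RegulatoryModel(
            marker_freq=0.5,
            variants=[
                RegulatoryVariant("A", 0.5, 0.7, 0.6),
                RegulatoryVariant("B", 0.5, 0.4, 0.0),
            ],
            noise_sd=0.10,
        ),
        "biphasic": RegulatoryModel(
            marker_freq=0.5,
            variants=[
                RegulatoryVariant("A", 0.5, 0.6, 0.0),
                RegulatoryVariant("B", 0.5, 0.45, 0.0),
            ],
            noise_sd=0.12,
        ),
    }
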
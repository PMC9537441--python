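"""Enrichment and clonal-origin statistics for barcode count data.

The central statistic is a conservative posterior log2 fold change for
single-replicate count data (the "generalized fold change" idea): each
barcode's read rate in a sample is given a Gamma posterior,
``lambda ~ Gamma(k + alpha) / N`` with ``k`` the observed count, ``alpha`` a
prior pseudocount and ``N`` the sample's assigned-read total, and the
statistic is the ``c``-quantile (default c = 0.01) of the posterior of
``log2(lambda_trt / lambda_ctl)``.  A barcode is called enriched in a
treated replicate when this value exceeds a threshold (default 4).

Cross-replicate recurrence separates resistance origins: a barcode enriched
in all R independent replicates is a preexistence candidate, one enriched in
exactly one replicate is late-emerging (acquired during treatment).  The
chance probability of a non-preexisting barcode recurring in r of R
replicates is binomial, ``C(R, r) p^r (1-p)^(R-r)``, with ``p`` the
per-replicate selection probability estimated as
(union of enriched barcodes) / (detected barcode complexity); a
Bonferroni-style multiplication by the complexity adjusts for testing every
detected barcode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon_io import BarcodeCountTable

ORIGIN_PREEXISTING = "preexisting_candidate"
ORIGIN_LATE = "late_emerging"
ORIGIN_INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class EnrichmentRecord:
    """Posterior log2 fold-change statistic for one barcode in one
    treated-vs-control comparison."""

    barcode_key: str
    k_trt: int
    k_ctl: int
    n_trt: int
    n_ctl: int
    alpha: float
    c: float
    gfold_value: float
    point_l2fc: float


def gfold_statistic(
    k_trt: int,
    k_ctl: int,
    n_trt: int,
    n_ctl: int,
    alpha: float = 1.0,
    c: float = 0.01,
    method: str = "numeric",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """The c-quantile of the posterior log2 fold change of a count pair.

    Posterior rates are ``Gamma(k + alpha, 1) / N`` for treatment and
    control.  ``numeric`` evaluates the quantile in closed form through the
    Beta representation of a Gamma ratio (if ``G_t ~ Gamma(a)`` and
    ``G_c ~ Gamma(b)`` are independent then ``G_t / (G_t + G_c) ~
    Beta(a, b)``, and the ratio quantile is a monotone transform of the Beta
    quantile); ``monte_carlo`` draws from the two Gamma posteriors directly.
    """
    if not 0 < c < 0.5:
        raise ValueError("posterior quantile level c must be in (0, 0.5)")
    if n_trt <= 0 or n_ctl <= 0:
        raise ValueError("sample totals must be positive")
    a = k_trt + alpha
    b = k_ctl + alpha
    if method == "numeric":
        q = stats.beta.ppf(c, a, b)
        return float(np.log2(q / (1.0 - q)) + np.log2(n_ctl / n_trt))
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        lam_t = rng.gamma(a, size=n_draws) / n_trt
        lam_c = rng.gamma(b, size=n_draws) / n_ctl
        return float(np.quantile(np.log2(lam_t / lam_c), c))
    raise ValueError(f"unknown method {method!r}")


def point_l2fc(
    k_trt: int, k_ctl: int, n_trt: int, n_ctl: int, alpha: float = 1.0
) -> float:
    """Plug-in log2 fold change of normalized counts with pseudocounts."""
    return float(
        np.log2((k_trt + alpha) / n_trt) - np.log2((k_ctl + alpha) / n_ctl)
    )


def _gfold_vector(
    k_trt: np.ndarray, k_ctl: np.ndarray, n_trt: int, n_ctl: int,
    alpha: float, c: float,
) -> np.ndarray:
    q = stats.beta.ppf(c, k_trt + alpha, k_ctl + alpha)
    return np.log2(q / (1.0 - q)) + np.log2(n_ctl / n_trt)


@dataclass
class EnrichmentSummary:
    """Per-replicate enriched barcode sets at a GFOLD threshold."""

    threshold: float
    enriched_sets: dict[str, set[str]]
    records: pd.DataFrame  # barcode_key x replicate gfold values

    @property
    def n_enriched_per_replicate(self) -> dict[str, int]:
        return {r: len(s) for r, s in self.enriched_sets.items()}

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.enriched_sets.values():
            out |= s
        return out

    @property
    def n_enriched_union(self) -> int:
        return len(self.union)

    def replicate_count(self, barcode_key: str) -> int:
        return sum(barcode_key in s for s in self.enriched_sets.values())


def call_enriched(
    table: BarcodeCountTable,
    control_sample: str,
    treated_samples: list[str],
    threshold: float = 4.0,
    alpha: float = 1.0,
    c: float = 0.01,
    depleted: bool = False,
) -> EnrichmentSummary:
    """Call barcodes enriched (GFOLD value > threshold) in each treated
    replicate against the control sample."""
    for s in [control_sample, *treated_samples]:
        if s not in table.sample_ids:
            raise ValueError(f"sample {s!r} not in table")
    totals = table.totals
    if (totals[[control_sample, *treated_samples]] == 0).any():
        raise ValueError("a sample has zero assigned reads")
    k_ctl = table.counts[control_sample].to_numpy()
    n_ctl = int(totals[control_sample])
    gfold = {}
    enriched: dict[str, set[str]] = {}
    keys = np.array(table.barcode_keys)
    for rep in treated_samples:
        k_trt = table.counts[rep].to_numpy()
        n_trt = int(totals[rep])
        if depleted:
            # upper-tail quantile of the *control over treatment* ratio
            g = -_gfold_vector(k_ctl, k_trt, n_ctl, n_trt, alpha, c)
        else:
            g = _gfold_vector(k_trt, k_ctl, n_trt, n_ctl, alpha, c)
        gfold[rep] = g
        enriched[rep] = set(keys[g > threshold])
    records = pd.DataFrame(gfold, index=table.counts.index)
    return EnrichmentSummary(threshold=threshold, enriched_sets=enriched,
                             records=records)


@dataclass(frozen=True)
class PreexistenceModel:
    """Binomial chance model for cross-replicate recurrence of enrichment."""

    p: float
    n_replicates: int = 5
    complexity: int = 230_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("P must be in [0, 1]")
        if self.complexity < 1:
            raise ValueError("complexity must be >= 1")


def preexistence_probability(
    p: float,
    n_replicates: int = 5,
    r: int = 5,
    complexity: int = 230_000,
    adjust: bool = False,
    cap: bool = False,
) -> float:
    """Chance probability that a non-preexisting barcode is enriched in
    exactly ``r`` of ``n_replicates`` replicates: C(R, r) p^r (1-p)^(R-r).

    With ``adjust`` the value is multiplied by the detected barcode
    complexity (a Bonferroni-style correction over all detected barcodes);
    ``cap`` additionally clips the adjusted value at 1.
    """
    if r > n_replicates:
        raise ValueError("r cannot exceed the number of replicates")
    if r < 0:
        raise ValueError("r must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("P must be in [0, 1]")
    prob = math.comb(n_replicates, r) * p**r * (1.0 - p) ** (n_replicates - r)
    if adjust:
        prob *= complexity
        if cap:
            prob = min(prob, 1.0)
    return prob


def estimate_selection_probability(
    n_enriched_union: int, complexity: int
) -> tuple[float, float]:
    """Per-replicate selection probability and the percentage of founder
    clones contributing to resistance.

    ``P = n_enriched_union / complexity``; the percentage is ``P * 100``.
    """
    if complexity <= 0:
        raise ValueError("complexity must be positive")
    if not 0 <= n_enriched_union <= complexity:
        raise ValueError("need 0 <= n_enriched_union <= complexity")
    p = n_enriched_union / complexity
    return p, p * 100.0


@dataclass
class DynamicsSummary:
    """Clonal dynamics of the count table plus cross-replicate overlap of
    the top enriched barcodes."""

    cumulative_curves: dict[str, np.ndarray]
    max_clone_share: dict[str, float]
    overlap_histogram: dict[str, np.ndarray]
    origin_labels: dict[str, str]
    top_k_shares: dict[str, dict[int, float]] = field(default_factory=dict)

    def top_k_share(self, sample: str, k: int) -> float:
        curve = self.cumulative_curves[sample]
        if len(curve) == 0:
            return 0.0
        return float(curve[min(k, len(curve)) - 1])


def _rank_enriched(
    summary: EnrichmentSummary, table: BarcodeCountTable, rep: str, top_n: int
) -> list[str]:
    """Top-n enriched barcodes of a replicate: gfold desc, ties by treated
    count desc then lexicographic key."""
    members = sorted(summary.enriched_sets[rep])
    if not members:
        return []
    g = summary.records.loc[members, rep]
    k = table.counts.loc[members, rep]
    order = sorted(members, key=lambda b: (-g[b], -k[b], b))
    return order[:top_n]


def dynamics_summary(
    table: BarcodeCountTable,
    samples: list[str] | None = None,
    enrichment: EnrichmentSummary | None = None,
    top_n: int = 50,
    top_k: tuple[int, ...] = (1, 10),
) -> DynamicsSummary:
    """Cumulative clone-share curves per sample and, when enrichment calls
    are given, the cross-replicate overlap histogram of each replicate's
    top-n enriched barcodes plus per-barcode origin labels.

    Origin rule: enriched in every replicate -> preexisting candidate;
    enriched in exactly one -> late-emerging; otherwise intermediate.
    """
    samples = samples or table.sample_ids
    if not samples:
        raise ValueError("at least one sample required")
    frac = table.fractions()
    curves: dict[str, np.ndarray] = {}
    max_share: dict[str, float] = {}
    top_shares: dict[str, dict[int, float]] = {}
    for s in samples:
        f = np.sort(frac[s].to_numpy())[::-1]
        f = f[f > 0]
        curve = np.cumsum(f)
        curves[s] = curve
        max_share[s] = float(f[0]) if len(f) else 0.0
        top_shares[s] = {
            k: float(curve[min(k, len(curve)) - 1]) if len(curve) else 0.0
            for k in top_k
        }

    overlap: dict[str, np.ndarray] = {}
    origins: dict[str, str] = {}
    if enrichment is not None:
        reps = list(enrichment.enriched_sets)
        n_rep = len(reps)
        for rep in reps:
            avail = len(enrichment.enriched_sets[rep])
            if 0 < avail < top_n:
                warnings.warn(
                    f"{rep}: only {avail} enriched barcodes available "
                    f"(top_n={top_n}); using all"
                )
            top = _rank_enriched(enrichment, table, rep, top_n)
            hist = np.zeros(n_rep)
            for b in top:
                hist[enrichment.replicate_count(b) - 1] += 1
            if top:
                hist /= len(top)
            overlap[rep] = hist
        for b in enrichment.union:
            m = enrichment.replicate_count(b)
            if m == n_rep:
                origins[b] = ORIGIN_PREEXISTING
            elif m == 1:
                origins[b] = ORIGIN_LATE
            else:
                origins[b] = ORIGIN_INTERMEDIATE

    return DynamicsSummary(
        cumulative_curves=curves,
        max_clone_share=max_share,
        overlap_histogram=overlap,
        origin_labels=origins,
        top_k_shares=top_shares,
    )


def enrichment_table(
    summary: EnrichmentSummary,
    table: BarcodeCountTable,
    control_sample: str,
    origins: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flat per-barcode report: counts, gfold per replicate, enriched flags,
    replicate recurrence and origin label, sorted by max gfold descending."""
    reps = list(summary.enriched_sets)
    rows = []
    for b in sorted(summary.union):
        row: dict[str, object] = {"barcode_key": b, "k_ctl": int(table.counts.loc[b, control_sample])}
        for rep in reps:
            row[f"k_{rep}"] = int(table.counts.loc[b, rep])
            row[f"gfold_{rep}"] = float(summary.records.loc[b, rep])
            row[f"enriched_{rep}"] = b in summary.enriched_sets[rep]
        row["n_replicates_enriched"] = summary.replicate_count(b)
        if origins:
            row["origin"] = origins.get(b, "")
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            by=[f"gfold_{r}" for r in reps], ascending=False, kind="mergesort"
        ).reset_index(drop=True)
    return df
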
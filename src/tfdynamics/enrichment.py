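"""TF over-representation Z-scores per (stage range × anatomy term) and
tissue-pair repertoire-overlap Z-scores.

The observed TF count in a cell is compared with random draws of the same
number of genes (TF + non-TF, without replacement) from a gene universe.
Because draws are without replacement from a finite universe, the null is
exactly hypergeometric, so an analytic closed form for the null mean and sd
is available alongside the sampling procedure and serves as its independent
oracle:

    mean = d * K / N
    var  = d * (K/N) * (1 - K/N) * (N - d) / (N - 1)

with d = n + m genes drawn, K TFs among N universe genes.  A cell is called
significantly TF-enriched iff Z >= 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import EnrichmentResult, GeneCatalog, STAGE_LABELS, StageTissueMatrix

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class SamplingNull:
    """Monte-Carlo null for the TF count in a random gene draw."""

    n_iterations: int = 10_000
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), 6])


def _analytic_moments(d: int, K: int, N: int) -> tuple[float, float]:
    if N <= 1:
        raise ValueError("universe must contain more than one gene")
    p = K / N
    mean = d * p
    var = d * p * (1 - p) * (N - d) / (N - 1)
    return mean, float(np.sqrt(max(var, 0.0)))


def _result(stage_range, term, n_tf, n_nontf, mean, sd,
            z_threshold) -> EnrichmentResult:
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (n_tf - mean) / sd
    return EnrichmentResult(
        stage_range=stage_range, term=term, n_tf=n_tf, n_nontf=n_nontf,
        expected_tf=mean, null_sd=sd, z=z,
        significant=(not degenerate) and z >= z_threshold,
        degenerate=degenerate,
    )


def enrichment_z_sampled(
    n_tf: int,
    n_nontf: int,
    universe: GeneCatalog,
    null: SamplingNull,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    stage_range: str = "",
    term: str = "",
) -> EnrichmentResult:
    """Z-score of the observed TF count against ``n_iterations`` random
    draws of n_tf + n_nontf genes without replacement from the universe."""
    N, K, d = len(universe), len(universe.tf_ids), n_tf + n_nontf
    if d > N:
        raise ValueError("draw size exceeds universe size")
    counts = null.rng().hypergeometric(K, N - K, d, size=null.n_iterations)
    mean, sd = float(counts.mean()), float(counts.std(ddof=0))
    return _result(stage_range, term, n_tf, n_nontf, mean, sd, z_threshold)


def enrichment_z_analytic(
    n_tf: int,
    n_nontf: int,
    universe: GeneCatalog,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    stage_range: str = "",
    term: str = "",
) -> EnrichmentResult:
    """Closed-form hypergeometric null; the exact, zero-cost alternative to
    sampling."""
    N, K, d = len(universe), len(universe.tf_ids), n_tf + n_nontf
    if d > N:
        raise ValueError("draw size exceeds universe size")
    mean, sd = _analytic_moments(d, K, N)
    return _result(stage_range, term, n_tf, n_nontf, mean, sd, z_threshold)


def enrich_all(
    matrix: StageTissueMatrix,
    catalog: GeneCatalog,
    null: SamplingNull | None = None,
    method: str = "analytic",
    universe: str = "assayed",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> list[EnrichmentResult]:
    """One enrichment result per (stage range, anatomy term) cell with at
    least one expressed gene.

    ``universe`` selects the resampling pool: "assayed" (genes of the matrix
    with any expression information; default) or "all" (every catalogued
    gene).  ``method`` is "analytic" (exact hypergeometric) or "sampled"
    (Monte Carlo; requires ``null``).
    """
    if method not in ("analytic", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    if method == "sampled" and null is None:
        raise ValueError("sampled method requires a SamplingNull")
    if universe == "assayed":
        pool_ids = matrix.expressed_anywhere()
        pool = GeneCatalog([catalog[g] for g in sorted(pool_ids) if g in catalog])
    elif universe == "all":
        pool = catalog
    else:
        raise ValueError(f"unknown universe {universe!r}")

    results = []
    for s_idx, stage in enumerate(STAGE_LABELS):
        by_term: dict[str, list[str]] = {}
        for g in matrix.genes:
            for t in matrix.terms_at(g, s_idx):
                by_term.setdefault(t, []).append(g)
        for term in sorted(by_term):
            genes = [g for g in by_term[term] if g in catalog]
            n_tf = sum(1 for g in genes if catalog.is_tf(g))
            n_nontf = len(genes) - n_tf
            if n_tf + n_nontf == 0:
                logger.info("skipping empty cell (%s, %s)", stage, term)
                continue
            if len(pool) <= 1 or n_tf + n_nontf >= len(pool):
                # universe too small for a null with spread
                res = _result(stage, term, n_tf, n_nontf, float(n_tf), 0.0,
                              z_threshold)
            elif method == "analytic":
                res = enrichment_z_analytic(
                    n_tf, n_nontf, pool, z_threshold, stage, term
                )
            else:
                res = enrichment_z_sampled(
                    n_tf, n_nontf, pool, null, z_threshold, stage, term
                )
            results.append(res)
    return results


def tissue_overlap_z(
    set_a: set[str],
    set_b: set[str],
    family_universe: set[str],
    null: SamplingNull,
) -> float:
    """Standardized score of the observed repertoire overlap |A ∩ B| against
    independent random draws of |A| and |B| genes from the universe.

    Negative values are meaningful (avoidance of overlap).
    """
    if not set_a or not set_b:
        raise ValueError("both repertoires must be nonempty")
    universe = set(family_universe)
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("repertoires must be subsets of the universe")
    N, a, b = len(universe), len(set_a), len(set_b)
    observed = len(set_a & set_b)
    # drawing A then B independently: |A ∩ B| ~ Hypergeometric(N, a, b)
    counts = null.rng().hypergeometric(a, N - a, b, size=null.n_iterations)
    sd = counts.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate overlap null (sd = 0)")
    return float((observed - counts.mean()) / sd)


def overlap_z_analytic(set_a: set[str], set_b: set[str],
                       family_universe: set[str]) -> float:
    """Exact-moment version of :func:`tissue_overlap_z`."""
    if not set_a or not set_b:
        raise ValueError("both repertoires must be nonempty")
    N, a, b = len(family_universe), len(set_a), len(set_b)
    mean, sd = _analytic_moments(b, a, N)
    if sd == 0:
        raise ValueError("degenerate overlap null (sd = 0)")
    return float((len(set_a & set_b) - mean) / sd)
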
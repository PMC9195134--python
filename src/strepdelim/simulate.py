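"""Synthetic sequence pairs and metric tables with known ground truth.

Two generators back the test pyramid:

* :func:`simulate_pair` draws a random nucleotide sequence and derives a
  partner by flipping each site independently to its transition partner
  with probability ``p`` or to one of its two transversion partners
  (equiprobably) with probability ``q``.  Divergence is parametrized
  directly by the site-change proportions, so the closed-form Kimura
  two-parameter distance at (p, q) is the exact ground truth — no rate
  matrices or branch lengths involved.  No indels are generated.

* :func:`simulate_metric_table` draws ANIm values uniformly and produces
  dDDH through an exponential link with additive Gaussian noise, then the
  MLSA distance from dDDH through a second exponential link, emulating the
  statistical structure of the curated *Streptomyces* table.  Default link
  parameters are the values fitted to that table.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mlsa import classify_sites, k2p_distance, k2p_from_proportions, SaturationError
from .pair_metrics import MetricTable, StrainPairRecord

__all__ = [
    "SimulatedPair",
    "RecoverySummary",
    "SyntheticMetricTable",
    "simulate_pair",
    "recovery_experiment",
    "simulate_metric_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# index arithmetic: transition partner of base i is i XOR 2 (A<->G, C<->T);
# the two transversion partners are the other parity class.
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class SimulatedPair:
    seq_a: str
    seq_b: str
    true_p: float
    true_q: float
    true_d: float
    seed: int


def _check_pq(p: float, q: float) -> None:
    if p < 0 or q < 0 or 2 * p + q >= 1 or 2 * q >= 1:
        raise ValueError(
            f"(p={p}, q={q}) outside the valid region: need p,q >= 0, "
            "2p+q < 1 and 2q < 1"
        )


def simulate_pair(length: int, p: float, q: float, seed: int) -> SimulatedPair:
    """Generate one diverged sequence pair with known (p, q)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    _check_pq(p, q)
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=length)
    u = rng.random(length)
    b = a.copy()
    is_transition = u < p
    is_transversion = (u >= p) & (u < p + q)
    b[is_transition] = _TRANSITION[a[is_transition]]
    which = rng.integers(0, 2, size=int(is_transversion.sum()))
    b[is_transversion] = _TRANSVERSIONS[a[is_transversion], which]
    seq_a = _BASES[a].tobytes().decode("ascii")
    seq_b = _BASES[b].tobytes().decode("ascii")
    return SimulatedPair(
        seq_a=seq_a,
        seq_b=seq_b,
        true_p=p,
        true_q=q,
        true_d=k2p_from_proportions(p, q),
        seed=seed,
    )


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of K2P distance recovery."""

    true_d: float
    mean_d: float
    sd_d: float
    relative_bias: float
    replicates: int
    saturated: int


def recovery_experiment(
    length: int, p: float, q: float, replicates: int, seed: int
) -> RecoverySummary:
    """Estimate the K2P distance on simulated pairs and compare to truth.

    Replicates where the correction saturates are counted and excluded
    from the mean (they do not occur in the parameter range of interest).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    _check_pq(p, q)
    true_d = k2p_from_proportions(p, q)
    seeds = np.random.SeedSequence(seed).spawn(replicates)
    estimates = []
    saturated = 0
    for child in seeds:
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        pair = simulate_pair(length, p, q, sub_seed)
        try:
            estimates.append(
                k2p_distance(classify_sites(pair.seq_a, pair.seq_b))
            )
        except SaturationError:
            saturated += 1
    est = np.asarray(estimates)
    mean_d = float(est.mean())
    rel_bias = (mean_d - true_d) / true_d if true_d > 0 else mean_d - true_d
    return RecoverySummary(
        true_d=true_d,
        mean_d=mean_d,
        sd_d=float(est.std(ddof=1)),
        relative_bias=float(rel_bias),
        replicates=replicates,
        saturated=saturated,
    )


@dataclass
class SyntheticMetricTable:
    """A synthetic metric table plus the generating link parameters."""

    table: MetricTable
    link_a: float
    link_b: float
    sigma: float
    mlsa_link_a: float
    mlsa_link_b: float
    mlsa_sigma: float
    truncated: list[bool] = field(default_factory=list)


def simulate_metric_table(
    n: int,
    anim_range: tuple[float, float] = (90.0, 100.0),
    link_a: float = 0.0028,
    link_b: float = 0.1048,
    sigma: float = 0.5,
    seed: int = 0,
    mlsa_link_a: float = 0.287,
    mlsa_link_b: float = -0.0508,
    mlsa_sigma: float = 0.002,
) -> SyntheticMetricTable:
    """Metric table with exponential ANIm->dDDH and dDDH->MLSA links.

    Default link parameters reproduce the shape fitted to the curated
    80-pair *Streptomyces* table; noise is additive Gaussian.  dDDH is
    truncated to [0, 100] and truncation is recorded per record so that
    regression tests can exclude clipped points; MLSA is clipped at 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    if link_a <= 0:
        raise ValueError("link_a must be > 0")
    lo, hi = anim_range
    for edge in (lo, hi):
        noiseless = link_a * np.exp(link_b * edge)
        if not (0 < noiseless <= 100):
            raise ValueError(
                f"noiseless dDDH {noiseless:.3g} at ANIm={edge} is outside "
                "(0, 100]: adjust link parameters or anim_range"
            )
    rng = np.random.default_rng(seed)
    anim = rng.uniform(lo, hi, size=n)
    ddh_clean = link_a * np.exp(link_b * anim)
    ddh = ddh_clean + rng.normal(0.0, sigma, size=n)
    truncated = (ddh > 100) | (ddh < 0)
    ddh = np.clip(ddh, 0.0, 100.0)
    mlsa = mlsa_link_a * np.exp(mlsa_link_b * ddh)
    mlsa = np.maximum(mlsa + rng.normal(0.0, mlsa_sigma, size=n), 0.0)
    records = [
        StrainPairRecord(
            species_a=f"synthetic_sp_{2 * i + 1:03d}",
            species_b=f"synthetic_sp_{2 * i + 2:03d}",
            anim=round(float(anim[i]), 6),
            mlsa=round(float(mlsa[i]), 6),
            ddh=round(float(ddh[i]), 6),
        )
        for i in range(n)
    ]
    return SyntheticMetricTable(
        table=MetricTable(records=records, source=f"synthetic:seed={seed}"),
        link_a=link_a,
        link_b=link_b,
        sigma=sigma,
        mlsa_link_a=mlsa_link_a,
        mlsa_link_b=mlsa_link_b,
        mlsa_sigma=mlsa_sigma,
        truncated=list(map(bool, truncated)),
    )
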
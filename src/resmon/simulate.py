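"""Seeded stochastic generators for monitoring campaigns and QC replicates.

The monitoring generator emulates the structure of a market-basket
surveillance campaign: a fixed roster of commodities with per-commodity
sample counts, independent Bernoulli contamination of samples, lognormal
residue concentrations (field residue levels commonly span about two orders
of magnitude), and a configurable fraction of residues drawn above the
applicable MRL.  Unlike the deterministic survey fixture, contaminated
samples here may carry several residues, exercising the worst-verdict
sample rule.

Everything is driven by ``numpy.random.default_rng(seed)``: a fixed seed
reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import Group, MRLEntry, MRLSource, ResidueMeasurement, SampleRecord
from .validation import SpikeReplicateSet

__all__ = ["SimConfig", "generate_monitoring_dataset", "generate_validation_replicates"]


@dataclass
class SimConfig:
    """Parameters of a simulated monitoring campaign.

    commodities
        ``(name, group, n_samples)`` triples.
    pesticides
        ``(name, function_class_code, lod, loq)`` tuples.
    detection_prob
        Probability that a sample is contaminated at all (the survey-wide
        any-residue rate; the 2020 Incheon campaign observed 0.079).
    violation_prob
        Probability that a detected residue exceeds its MRL (the survey's
        violating fraction of detections, 11/91 ~ 0.12).
    conc_lognormal
        ``(mu, sigma)`` of log-concentration for compliant residues.
    multi_residue_rate
        Poisson rate of *extra* residues in a contaminated sample (0 keeps
        one residue per contaminated sample).
    mrl
        Registered MRL (mg/kg) applied to every pesticide x commodity pair
        of the simulation.
    """

    commodities: Sequence[Tuple[str, Group, int]]
    pesticides: Sequence[Tuple[str, str, float, float]]
    detection_prob: float = 0.079
    violation_prob: float = 11.0 / 91.0
    conc_lognormal: Tuple[float, float] = (-2.5, 1.2)
    multi_residue_rate: float = 0.1
    mrl: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("detection_prob", self.detection_prob),
                        ("violation_prob", self.violation_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.conc_lognormal[1] <= 0:
            raise ValueError("lognormal sigma must be > 0")
        if any(n < 0 for _, _, n in self.commodities):
            raise ValueError("n_samples must be >= 0")
        if self.multi_residue_rate < 0:
            raise ValueError("multi_residue_rate must be >= 0")
        if self.mrl <= 0:
            raise ValueError("mrl must be > 0")


def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         low: float, high: float) -> float:
    """A lognormal draw conditioned on (low, high]; falls back to clipping
    if the window has negligible mass."""
    for _ in range(200):
        x = float(rng.lognormal(mu, sigma))
        if low < x <= high:
            return x
    return float(min(max(rng.lognormal(mu, sigma), low * 1.000001), high))


def generate_monitoring_dataset(
    config: SimConfig,
) -> Tuple[List[SampleRecord], List[ResidueMeasurement], List[MRLEntry]]:
    """Simulate one monitoring campaign.

    Each sample is independently contaminated with ``detection_prob``; a
    contaminated sample carries ``1 + Poisson(multi_residue_rate)`` distinct
    pesticides.  Compliant residues are lognormal truncated to (LOD, MRL];
    violating residues (probability ``violation_prob`` per residue) are
    drawn uniformly in (MRL, 3 x MRL].

    Returns the samples, the measurements and the registered MRL table.
    """
    rng = np.random.default_rng(config.seed)
    pesticide_names = [p for p, _, _, _ in config.pesticides]
    lods = {p: lod for p, _, lod, _ in config.pesticides}
    loqs = {p: loq for p, _, _, loq in config.pesticides}
    mu, sigma = config.conc_lognormal

    samples: List[SampleRecord] = []
    measurements: List[ResidueMeasurement] = []
    mrl_table = [
        MRLEntry(p, name, config.mrl, MRLSource.REGISTERED)
        for name, _, _ in config.commodities
        for p in pesticide_names
    ]

    for name, group, n in config.commodities:
        slug = name.lower().replace(" ", "-")
        for i in range(n):
            sid = f"{slug}-{i + 1:04d}"
            samples.append(SampleRecord(sid, name, Group(group)))
            if not pesticide_names or rng.random() >= config.detection_prob:
                continue
            k = 1 + int(rng.poisson(config.multi_residue_rate))
            k = min(k, len(pesticide_names))
            chosen = rng.choice(len(pesticide_names), size=k, replace=False)
            for j in sorted(int(c) for c in chosen):
                pesticide = pesticide_names[j]
                if rng.random() < config.violation_prob:
                    conc = float(config.mrl * (1.0 + 2.0 * rng.random()))
                else:
                    conc = _truncated_lognormal(rng, mu, sigma, lods[pesticide], config.mrl)
                measurements.append(
                    ResidueMeasurement(sid, pesticide, conc, lods[pesticide], loqs[pesticide])
                )
    return samples, measurements, mrl_table


def generate_validation_replicates(
    spike: float,
    recovery_mean: float,
    cv: float,
    n: int = 5,
    seed: int = 0,
    pesticide: str = "synthetic",
) -> SpikeReplicateSet:
    """Simulate replicate determinations of a spiked sample.

    Measured values are Normal(spike x recovery_mean/100, cv/100 x mean),
    truncated at 0.  ``cv = 0`` gives identical replicates (RSD 0).
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    mean = spike * recovery_mean / 100.0
    values = np.maximum(rng.normal(mean, cv / 100.0 * mean, size=n), 0.0)
    return SpikeReplicateSet(pesticide, spike, tuple(float(v) for v in values))
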
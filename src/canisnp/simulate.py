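"""Synthetic genotype generation from population frequency tables.

The generator replaces raw study samples: individuals are drawn i.i.d. per
locus from a population's published genotype-state distribution (default) or
from Hardy–Weinberg proportions of its allele frequency.  Loci are simulated
independently (linkage equilibrium); no mutation or genotyping-error model is
included beyond optional locus-wise missingness driven by one-time
genotyping success rates.

Reproducibility contract: a config's seed fully determines the output.  A
single RNG stream is consumed in individuals-major, loci-minor order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .panel import (
    GenotypeMatrix,
    PanelDefinition,
    PopulationFrequencyTable,
    SuccessTable,
)

__all__ = ["SimulationConfig", "simulate_population", "simulate_f1_hybrids", "apply_missingness"]

MODES = ("genotype_freq", "hwe")


@dataclass
class SimulationConfig:
    """Settings for :func:`simulate_population`.

    ``mode='genotype_freq'`` samples the published genotype-state
    distribution directly, preserving observed departures from
    Hardy–Weinberg; ``mode='hwe'`` draws allele_a dosage Binomial(2, p_a).
    """

    population: str
    n_individuals: int
    mode: str = "genotype_freq"
    seed: int = 0
    missingness: Optional[SuccessTable] = None
    id_prefix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.mode not in MODES:
            raise ValueError(f"unknown simulation mode {self.mode!r}; expected one of {MODES}")


def _state_probs(freqs: PopulationFrequencyTable, population: str, mode: str) -> np.ndarray:
    """(loci x 3) probabilities over (HOM_A, HET, HOM_B), normalized."""
    if mode == "genotype_freq":
        probs = freqs.genotype_probs(population).to_numpy(float)
    else:
        p = freqs.allele_a_freq(population).to_numpy(float)
        probs = np.stack([p**2, 2 * p * (1 - p), (1 - p) ** 2], axis=1)
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum(axis=1, keepdims=True)


def _draw_states(probs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw dosages for n individuals given per-locus state probabilities."""
    n_loci = probs.shape[0]
    u = rng.random((n, n_loci))  # individuals-major, loci-minor
    cum = np.cumsum(probs, axis=1)  # (loci, 3)
    # state index = number of cumulative bins strictly below u
    state = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2)
    dosage = (2 - state).astype(np.int8)  # state 0 -> HOM_A (dosage 2)
    return dosage


def simulate_population(
    freqs: PopulationFrequencyTable, config: SimulationConfig
) -> GenotypeMatrix:
    """Simulate ``config.n_individuals`` from one population's frequencies."""
    if config.population not in freqs.populations:
        raise ValueError(
            f"population {config.population!r} not in frequency table "
            f"({freqs.populations})"
        )
    rng = np.random.default_rng(config.seed)
    probs = _state_probs(freqs, config.population, config.mode)
    dosage = _draw_states(probs, config.n_individuals, rng)
    prefix = config.id_prefix if config.id_prefix is not None else config.population
    ids = [f"{prefix}_{i + 1:04d}" for i in range(config.n_individuals)]
    matrix = GenotypeMatrix(
        panel=freqs.panel,
        dosage=pd.DataFrame(dosage, index=ids, columns=freqs.panel.locus_ids),
        populations=pd.Series(config.population, index=ids),
    )
    if config.missingness is not None:
        matrix = _apply_missingness_rng(matrix, config.missingness, rng)
    return matrix


def simulate_f1_hybrids(
    freqs_a: PopulationFrequencyTable,
    freqs_b: PopulationFrequencyTable,
    n: int,
    seed: int = 0,
    population_a: Optional[str] = None,
    population_b: Optional[str] = None,
    label: str = "hybrid",
) -> GenotypeMatrix:
    """Simulate first-generation crosses between two populations.

    Each individual receives, at every locus, one allele drawn from
    population a's allele frequencies and one from population b's.
    ``freqs_a`` and ``freqs_b`` may be the same table holding both
    populations; by default each table's single (or first) population is
    used.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pop_a = population_a or freqs_a.populations[0]
    pop_b = population_b or freqs_b.populations[0]
    if freqs_a.panel.locus_ids != freqs_b.panel.locus_ids:
        raise ValueError("parental frequency tables must cover the same panel loci")
    pa = freqs_a.allele_a_freq(pop_a).to_numpy(float)
    pb = freqs_b.allele_a_freq(pop_b).to_numpy(float)
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(pa), 2))  # individuals-major, loci-minor, parent-last
    dosage = ((u[:, :, 0] < pa) .astype(np.int8) + (u[:, :, 1] < pb).astype(np.int8))
    ids = [f"{label}_{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(
        panel=freqs_a.panel,
        dosage=pd.DataFrame(dosage, index=ids, columns=freqs_a.panel.locus_ids),
        populations=pd.Series(label, index=ids),
    )


def apply_missingness(
    matrix: GenotypeMatrix, success: SuccessTable, seed: int = 0
) -> GenotypeMatrix:
    """Mask calls at random with per-(locus, population) failure rates.

    Each call is independently set MISSING with probability
    ``1 - one_time_success(locus, population_of_individual)``.  The input
    matrix is not modified.
    """
    return _apply_missingness_rng(matrix, success, np.random.default_rng(seed))


def _apply_missingness_rng(
    matrix: GenotypeMatrix, success: SuccessTable, rng: np.random.Generator
) -> GenotypeMatrix:
    for locus in matrix.locus_ids:
        if locus not in success.locus_ids:
            raise ValueError(f"success table does not cover locus {locus}")
    unknown = set(matrix.populations) - set(success.populations)
    if unknown:
        raise ValueError(f"success table does not cover populations {sorted(unknown)}")
    # (individuals x loci) success rates by each individual's population
    rates = np.stack(
        [
            success.rates.loc[matrix.locus_ids, pop].to_numpy(float)
            for pop in matrix.populations
        ]
    )
    mask = rng.random(rates.shape) >= rates
    out = matrix.copy()
    d = out.dosage.to_numpy()
    d[mask] = -1
    out.dosage = pd.DataFrame(d, index=out.dosage.index, columns=out.dosage.columns)
    return out
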
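"""Unit conversions tying model parameters to field quantities.

The effective haploid deme size K is derived from an areal population
density: census size = density x cell area; one third of a forager
population is assumed reproductively mature, and doubling converts diploid
individuals into gene copies.  Sequencing error rates map to NGS Phred
quality scores via Q = -10 log10(eps).
"""

from __future__ import annotations

import math

from .world import GENERATION_YEARS


def k_from_density(
    density_per_km2: float,
    cell_km: float = 100.0,
    mature_fraction: float = 1.0 / 3.0,
    ploidy: int = 2,
) -> float:
    """Effective haploid deme size (gene copies) from density in /km^2.

    E.g. 0.0675 /km^2 on a 100 x 100 km cell -> 450 gene copies.
    """
    if density_per_km2 < 0:
        raise ValueError("density must be non-negative")
    census = density_per_km2 * cell_km**2
    return census * mature_fraction * ploidy


def phred_quality(error_rate: float) -> float:
    """NGS Phred quality score Q = -10 log10(error rate)."""
    if not 0 < error_rate <= 1:
        raise ValueError("error rate must be in (0, 1]")
    return -10.0 * math.log10(error_rate)


def ldd_mean_km(shape: float, rate: float, cell_km: float = 100.0) -> float:
    """Mean long-distance dispersal displacement of the gamma kernel, in km."""
    if shape <= 0 or rate <= 0:
        raise ValueError("kernel parameters must be positive")
    return shape / rate * cell_km


def generations_to_years(generations: float, gen_years: float = GENERATION_YEARS) -> float:
    return generations * gen_years


def years_to_generations(years: float, gen_years: float = GENERATION_YEARS) -> float:
    return years / gen_years
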
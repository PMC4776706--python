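"""Derived demographic quantities reported alongside posterior summaries.

These are the arithmetic identities used when translating posterior
parameter summaries into interpretable quantities: kernel means into
kilometres, carrying capacities into census densities, and long-distance
migrant counts into fractions of deme size.
"""

from __future__ import annotations

import importlib.resources as resources

import yaml

#: deme area for the default 150-km lattice
DEME_AREA_KM2 = 150.0 * 150.0
#: conventional effective:census population-size ratio for hunter-gatherers
EFFECTIVE_TO_CENSUS = 3.0


def ldd_mean_distance_km(mu_bar_demes: float, deme_side_km: float = 150.0) -> float:
    """Mean long-distance dispersal distance in km from the kernel mean in
    demes."""
    return mu_bar_demes * deme_side_km


def census_density_per_km2(
    k_diploid: float,
    effective_to_census: float = EFFECTIVE_TO_CENSUS,
    deme_area_km2: float = DEME_AREA_KM2,
) -> float:
    """Census population density (individuals/km^2) implied by a deme's
    effective carrying capacity."""
    return k_diploid * effective_to_census / deme_area_km2


def ldd_migrant_fraction_pct(ldd_migrants: float, k_diploid: float) -> float:
    """Long-distance migrants per generation as a percentage of deme
    effective size."""
    return 100.0 * ldd_migrants / k_diploid


def expected_ldd_migrants(k_diploid: float, m: float, ldd_prop: float) -> float:
    """Expected LDD migrant genes per generation of a deme at capacity:
    2*K*m*LDD_PROP (haploid gene copies)."""
    return 2.0 * k_diploid * m * ldd_prop


def load_reference_posterior() -> dict:
    """The packaged posterior summaries (mode/mean/median per parameter)
    of the best-fitting model, used by worked examples and reports."""
    text = resources.files("rangeabc").joinpath("data", "reference_posterior.yaml").read_text()
    return yaml.safe_load(text)
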
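"""Back-of-the-planet combinatorics: how many replicator-sized assemblies fit
in an early-ocean surface layer, and what lipid concentration that implies.

Combined with the multiset count of possible compositions
(:func:`gardsim.compostats.n_compositions`), these order-of-magnitude
estimates say whether *every* possible composition of a small assembly could
have been realised somewhere on the planet at once.
"""

from __future__ import annotations

from .model_core import GardError

__all__ = [
    "replicator_count",
    "planetary_capacity",
    "lipid_concentration",
    "sphere_volume",
    "KM2",
]

#: one square kilometre in square metres
KM2 = 1.0e6


def replicator_count(total_volume: float, replicator_volume: float,
                     volume_fraction: float = 1.0) -> float:
    """Number of replicators in ``total_volume`` (m^3) when each occupies
    ``replicator_volume`` (m^3) and replicators fill ``volume_fraction`` of
    the suspension.

    Equivalently: one replicator per ``replicator_volume / volume_fraction``
    of suspension.
    """
    if total_volume <= 0 or replicator_volume <= 0 or not 0 < volume_fraction <= 1:
        raise GardError("volumes must be positive and 0 < volume_fraction <= 1")
    return total_volume * volume_fraction / replicator_volume


def planetary_capacity(surface_area: float, depth: float, replicator_volume: float,
                       volume_fraction: float = 1.0) -> float:
    """Replicator capacity of a surface layer: area (m^2) x depth (m) divided
    by the per-replicator suspension volume.  Linear in every argument."""
    if surface_area <= 0 or depth <= 0:
        raise GardError("surface area and depth must be positive")
    return replicator_count(surface_area * depth, replicator_volume, volume_fraction)


def lipid_concentration(volume_fraction: float, molar_mass: float,
                        density: float = 1.0) -> float:
    """Molar concentration (mol/L) of lipid dispersed at ``volume_fraction``
    with ``molar_mass`` in g/mol and ``density`` in g/mL.

    c = fraction * density[g/mL] * 1000[mL/L] / M[g/mol];  a 10^-5 fraction
    of a 500 Da lipid at unit density is 20 uM.
    """
    if volume_fraction < 0 or molar_mass <= 0 or density <= 0:
        raise GardError("molar mass and density must be positive, fraction non-negative")
    return volume_fraction * density * 1000.0 / molar_mass


def sphere_volume(diameter: float) -> float:
    """Volume (m^3) of a sphere of the given diameter (m); a 10 nm micelle
    (about 100 lipids) occupies ~5.2e-25 m^3."""
    import math

    if diameter <= 0:
        raise GardError("diameter must be positive")
    return math.pi * diameter**3 / 6.0
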
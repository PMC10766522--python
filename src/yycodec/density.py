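"""Closed-form physical-density and net-information-density calculators.

Physical density of a DNA storage design is the information carried per
nucleotide divided by the mass a stored nucleotide occupies:

    density [bits/g] = i / (m_nt * c * (1 + rho))

where ``i = 2 * payload_nt / total_nt`` is the average information per
nucleotide (2 bits is the theoretical ceiling), ``m_nt`` the average
mass of one nucleotide (330.95 g/mol over the Avogadro constant),
``c`` the average molecule copy number needed for reliable recovery and
``rho`` the logical-redundancy fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AVG_NT_MOLAR_MASS",
    "AVOGADRO",
    "DensityInputs",
    "info_per_nt",
    "physical_density",
    "physical_density_from_info",
    "PROFILES",
]

#: average molecular weight per incorporated nucleotide, g/mol
AVG_NT_MOLAR_MASS = 330.95
#: CODATA 2018 exact value, 1/mol
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class DensityInputs:
    """Parameters of one storage design.

    ``payload_nt``/``total_nt`` describe one sequence (or the whole
    fragment); ``avg_copy_number`` is the physical redundancy and
    ``redundancy_fraction`` the logical redundancy (e.g. 0.30 for 30%
    extra segments).
    """

    payload_nt: float
    total_nt: float
    avg_copy_number: float = 1.0
    redundancy_fraction: float = 0.0
    avg_nt_molar_mass: float = AVG_NT_MOLAR_MASS
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.total_nt <= 0 or self.payload_nt < 0:
            raise ValueError("nucleotide counts must be positive")
        if self.payload_nt > self.total_nt:
            raise ValueError("payload cannot exceed total length")
        if self.avg_copy_number < 1:
            raise ValueError("avg_copy_number must be >= 1")
        if self.redundancy_fraction < 0:
            raise ValueError("redundancy_fraction must be >= 0")


def info_per_nt(inputs: DensityInputs) -> float:
    """Average information carried per nucleotide, bits/nt (at most 2)."""
    return 2.0 * inputs.payload_nt / inputs.total_nt


def physical_density_from_info(
    info_bits_per_nt: float,
    avg_copy_number: float = 1.0,
    redundancy_fraction: float = 0.0,
    avg_nt_molar_mass: float = AVG_NT_MOLAR_MASS,
    avogadro: float = AVOGADRO,
) -> dict[str, float]:
    """Density from a stated information content; returns bits/g and bytes/g."""
    if not 0.0 < info_bits_per_nt <= 2.0:
        raise ValueError("information per nucleotide must be in (0, 2] bits")
    mass_per_nt = avg_nt_molar_mass / avogadro
    bits_per_gram = info_bits_per_nt / (
        mass_per_nt * avg_copy_number * (1.0 + redundancy_fraction)
    )
    return {"bits_per_gram": bits_per_gram, "bytes_per_gram": bits_per_gram / 8.0}


def physical_density(inputs: DensityInputs) -> dict[str, float]:
    """Physical density of a storage design, in bits/g and bytes/g."""
    return physical_density_from_info(
        info_per_nt(inputs),
        inputs.avg_copy_number,
        inputs.redundancy_fraction,
        inputs.avg_nt_molar_mass,
        inputs.avogadro,
    )


#: Named design profiles: the 200 nt oligo-pool design (128 nt payload,
#: copy number 100 for reliable recovery, ~30% logical redundancy
#: including pseudobinary fillers), the 54,240 bp single-copy
#: chromosome-integrated fragment, and a published single-copy in vivo
#: design carrying 1.19 bits/nt for comparison.
PROFILES: dict[str, dict] = {
    "invitro-oligo": {
        "inputs": DensityInputs(
            payload_nt=128, total_nt=200, avg_copy_number=100, redundancy_fraction=0.30
        )
    },
    "invivo-fragment": {
        "inputs": DensityInputs(
            payload_nt=51528, total_nt=54240, avg_copy_number=1, redundancy_fraction=0.0
        )
    },
    "chen2021": {"info_bits_per_nt": 1.19, "avg_copy_number": 1, "redundancy_fraction": 0.0},
}


def profile_density(name: str) -> dict[str, float]:
    """Density of a named profile from :data:`PROFILES`."""
    spec = PROFILES[name]
    if "inputs" in spec:
        return physical_density(spec["inputs"])
    return physical_density_from_info(
        spec["info_bits_per_nt"],
        spec.get("avg_copy_number", 1.0),
        spec.get("redundancy_fraction", 0.0),
    )
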
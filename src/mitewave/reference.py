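"""Published summary statistics for the MER6/MER6A MITE families.

Default calibration inputs for the dating module: per-genome divergence of
copies from the species consensus (percent, Jukes-Cantor), the
Boreoeutheria split time used as the calibration event, and the mammalian
neutral substitution rate applied to the youngest-copy divergence floor.
"""

from __future__ import annotations

__all__ = [
    "MER6_CONSENSUS_DIVERGENCE_PCT",
    "MER6A_CONSENSUS_DIVERGENCE_PCT",
    "BOREOEUTHERIA_SPLIT_YEARS",
    "MAMMALIAN_NEUTRAL_RATE",
    "YOUNGEST_COPY_DIVERGENCE",
]

#: Divergence from the species-specific MER6 consensus (%), per genome.
MER6_CONSENSUS_DIVERGENCE_PCT: dict[str, float] = {
    "Homo sapiens": 19.2,
    "Pan troglodytes": 19.2,
    "Callithrix jacchus": 21.9,
    "Macaca mulatta": 20.2,
    "Carlito syrichta": 22.9,
    "Microcebus murinus": 19.8,
}

#: Divergence from the species-specific MER6A consensus (%), per genome.
MER6A_CONSENSUS_DIVERGENCE_PCT: dict[str, float] = {
    "Homo sapiens": 19.0,
    "Pan troglodytes": 19.1,
    "Callithrix jacchus": 21.6,
    "Macaca mulatta": 19.8,
    "Carlito syrichta": 22.1,
    "Microcebus murinus": 19.3,
    "Pteropus vampyrus": 18.6,
    "Myotis lucifugus": 19.2,
    "Condylura cristata": 30.2,
    "Erinaceus europaeus": 34.9,
    "Solenodon paradoxus": 27.6,
}

#: Euarchontoglires/Laurasiatheria split: (low, point, high) in years.
BOREOEUTHERIA_SPLIT_YEARS: tuple[float, float, float] = (91e6, 96e6, 102e6)

#: Neutral nucleotide substitution rate in mammals (substitutions/site/year).
MAMMALIAN_NEUTRAL_RATE: float = 2.2e-9

#: Jukes-Cantor divergence floor of the youngest copies across genomes.
YOUNGEST_COPY_DIVERGENCE: float = 0.12
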
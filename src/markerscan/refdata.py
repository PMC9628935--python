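"""Published reference data bundled with the package.

``REFERENCE_LOCUS_TABLE`` holds the reported characteristics of the 17
housekeeping genes used across the five *Bacillus subtilis* MLST schemes,
as published for a 21-strain comparative panel of *B. subtilis* and its
close relatives (*B. siamensis*, *B. velezensis*, *B. amyloliquefaciens*,
*B. atrophaeus*): gene length, number of alleles, number of polymorphic
sites, dN/dS, typing efficiency (TE) and Hunter–Gaston discriminatory
power (DP). These are the canonical check values for the typing statistics
and the default locus lengths for the synthetic panel generator.

``SPECIES_PRIMERS`` holds the published *B. subtilis*-specific primer pairs
against *pycA* (pyruvate carboxylase) and *aroE* (shikimate dehydrogenase)
with their expected product sizes.
"""

from __future__ import annotations

from typing import NamedTuple


class ReferenceLocus(NamedTuple):
    length_bp: int
    n_alleles: int
    n_polymorphic_sites: int
    dnds: float
    te: float
    dp: float


#: locus → published characteristics (21-strain Bacillus panel)
REFERENCE_LOCUS_TABLE: dict[str, ReferenceLocus] = {
    "adk": ReferenceLocus(654, 11, 78, 0.4057, 0.141, 0.935),
    "aroE": ReferenceLocus(843, 18, 322, 0.3909, 0.056, 0.983),
    "ccpA": ReferenceLocus(1005, 16, 269, 0.4046, 0.059, 0.974),
    "glpF": ReferenceLocus(828, 17, 247, 0.4122, 0.069, 0.978),
    "gmk": ReferenceLocus(615, 15, 136, 0.4143, 0.110, 0.965),
    "gyrA": ReferenceLocus(2466, 17, 718, 0.4098, 0.024, 0.978),
    "gyrB": ReferenceLocus(1917, 17, 532, 0.4116, 0.032, 0.978),
    "ilvD": ReferenceLocus(1677, 18, 458, 0.4057, 0.039, 0.983),
    "mutL": ReferenceLocus(1892, 16, 648, 0.3972, 0.025, 0.970),
    "pta": ReferenceLocus(972, 15, 232, 0.3973, 0.065, 0.965),
    "purH": ReferenceLocus(1539, 17, 428, 0.4011, 0.040, 0.978),
    "pycA": ReferenceLocus(3450, 19, 1075, 0.3990, 0.018, 0.991),
    "pyrE": ReferenceLocus(651, 14, 228, 0.4015, 0.061, 0.961),
    "rpoD": ReferenceLocus(1122, 16, 218, 0.4300, 0.073, 0.974),
    "spo0A": ReferenceLocus(804, 16, 187, 0.4068, 0.086, 0.970),
    "sucC": ReferenceLocus(1158, 15, 219, 0.4048, 0.068, 0.965),
    "tpiA": ReferenceLocus(762, 16, 114, 0.3823, 0.140, 0.952),
}


class ReferencePrimerPair(NamedTuple):
    forward_name: str
    forward_seq: str
    reverse_name: str
    reverse_seq: str
    expected_size_bp: int


#: published species-specific primer pairs for *B. subtilis* (5'→3')
SPECIES_PRIMERS: dict[str, ReferencePrimerPair] = {
    "pycA": ReferencePrimerPair(
        "pycA-F", "GTCTTCCGTTCAGGAAAGGC", "pycA-R", "GATCTCCCGTTTGGATCGGCTC", 233
    ),
    "aroE": ReferencePrimerPair(
        "aroE-F", "GGGGAAGGCTTCGTGAAGTC", "aroE-R", "CCCACAGACGTTGTATGGATG", 278
    ),
}
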
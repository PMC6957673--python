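"""Bundled reference data for the Indonesian coelacanth analyses.

``latimeria_aa_replacements`` is a transcription of the published table of
amino-acid replacements among the three key *Latimeria* mitogenomes: the
new Papua specimen (MK748470), the Manado specimen of *L. menadoensis*
(GQ911586), and an individual of *L. chalumnae* (AP012199), across the
three protein-coding genes sequenced in the new specimen (ND1, ND2, COI).
``CALIBRATION_WINDOWS`` are the three fossil calibration age windows (Ma)
used for the vertebrate dating analyses.
"""

from __future__ import annotations

from .datingpl import Calibration
from .mitoprotein import AaReplacementTable

__all__ = [
    "latimeria_aa_replacements",
    "TAXON_PAPUA",
    "TAXON_MANADO",
    "TAXON_CHALUMNAE",
    "vertebrate_calibrations",
    "CALIBRATION_WINDOWS",
    "NEW_SPECIMEN_BP",
    "REFERENCE_MITOGENOME_BP",
]

#: Bases sequenced in the new Papua specimen (half mitogenome: D-loop, 12S,
#: 16S, ND1, ND2, COI) and the full length of the Manado reference
#: mitogenome GQ911586.
NEW_SPECIMEN_BP = 8164
REFERENCE_MITOGENOME_BP = 16446

# Amino-acid replacement columns: (protein, 1-based position,
# Papua state, GQ911586 state, AP012199 state).
_AA_REPLACEMENTS = [
    ("ND1", 14, "I", "V", "V"),
    ("ND1", 78, "A", "A", "T"),
    ("ND1", 79, "A", "A", "T"),
    ("ND1", 86, "L", "L", "M"),
    ("ND1", 98, "Y", "H", "H"),
    ("ND1", 157, "S", "S", "A"),
    ("ND1", 176, "T", "A", "A"),
    ("ND1", 181, "M", "M", "T"),
    ("ND1", 266, "V", "V", "I"),
    ("ND1", 305, "L", "L", "M"),
    ("ND1", 315, "L", "L", "F"),
    ("ND1", 323, "T", "A", "T"),
    ("ND2", 41, "I", "T", "T"),
    ("ND2", 95, "T", "T", "A"),
    ("ND2", 96, "Q", "Q", "P"),
    ("ND2", 98, "T", "I", "I"),
    ("ND2", 108, "V", "M", "V"),
    ("ND2", 143, "F", "Y", "Y"),
    ("ND2", 155, "M", "M", "T"),
    ("ND2", 190, "V", "V", "M"),
    ("ND2", 191, "I", "I", "V"),
    ("ND2", 209, "I", "V", "I"),
    ("ND2", 224, "T", "T", "A"),
    ("ND2", 232, "M", "M", "T"),
    ("ND2", 235, "T", "T", "A"),
    ("ND2", 240, "T", "T", "A"),
    ("ND2", 243, "M", "M", "T"),
    ("ND2", 286, "T", "T", "A"),
    ("ND2", 298, "Y", "Y", "H"),
    ("ND2", 313, "T", "T", "I"),
    ("ND2", 319, "T", "T", "P"),
    ("ND2", 320, "D", "D", "G"),
    ("COI", 56, "I", "I", "V"),
    ("COI", 72, "I", "V", "I"),
    ("COI", 133, "G", "S", "G"),
]

TAXON_PAPUA = "Papua"
TAXON_MANADO = "GQ911586"
TAXON_CHALUMNAE = "AP012199"


def latimeria_aa_replacements() -> AaReplacementTable:
    """The 35 amino-acid replacement columns among the three key genomes."""
    proteins = tuple(r[0] for r in _AA_REPLACEMENTS)
    positions = tuple(r[1] for r in _AA_REPLACEMENTS)
    states = {
        TAXON_PAPUA: "".join(r[2] for r in _AA_REPLACEMENTS),
        TAXON_MANADO: "".join(r[3] for r in _AA_REPLACEMENTS),
        TAXON_CHALUMNAE: "".join(r[4] for r in _AA_REPLACEMENTS),
    }
    return AaReplacementTable(proteins, positions, states)


#: Fossil calibration windows (Ma): (clade label, min age, max age).
CALIBRATION_WINDOWS = {
    "fish_tetrapod": (416.1, 421.75),      # Actinopterygii-Sarcopterygii
    "amniote_amphibian": (330.4, 350.1),   # Reptiliomorpha-Batrachomorpha
    "reptile_mammal": (312.3, 330.4),      # Sauropsida-Synapsida
}


def vertebrate_calibrations(tip_map: dict[str, tuple[str, ...]]) -> list[Calibration]:
    """Build the three calibrations for a given tip labelling.

    ``tip_map`` maps each window name in :data:`CALIBRATION_WINDOWS` to the
    tip labels whose MRCA the window constrains.
    """
    cals = []
    for name, (lo, hi) in CALIBRATION_WINDOWS.items():
        cals.append(Calibration(frozenset(tip_map[name]), lo, hi, soft=True, label=name))
    return cals
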
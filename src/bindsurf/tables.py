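"""Published interface-burial tables and calcium-site constants.

These are the per-residue BSA/ASA ratios reported for the docked
Aβ(1–42):calmodulin models (structures 1–2, built from PDB 1Z0Q/1IYT + 1CLL)
and the Aβ(1–42):calbindin-D28k models (structures 1–3, from 1IYT + 6FIE).
The docked pose coordinate files themselves were never deposited, so these
tables are shipped as parsed data: they are inputs to pose evaluation and
peptide design, not quantities this package can recompute.

Also shipped here:

* the EF-hand Ca2+-coordinating positions of calmodulin in 1CLL author
  numbering (loop positions 1, 3, 5, 7, 9, 12 of the four 12-residue loops),
  used by pose selection to reject poses that occlude calcium sites;
* a synthetic reference geometry for the mimetic-design calibration (see
  :mod:`bindsurf.mimetic_design`): collinear Cα stand-in coordinates, NOT
  the crystallographic 1CLL coordinates.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# (three-letter name, author residue number, BSA/ASA ratio); listed from high
# to low ratio exactly as published.  Threshold >= 0.5 on both sides for the
# calmodulin tables; >= 0.5 (peptide) / >= 0.6 (protein) for calbindin.
ABETA_CAM = {
    1: {
        "abeta": [
            ("GLY", 37, 1.0), ("GLY", 38, 1.0), ("VAL", 36, 0.98),
            ("PHE", 20, 0.97), ("VAL", 40, 0.89), ("LEU", 34, 0.83),
            ("VAL", 39, 0.82), ("MET", 35, 0.77), ("LYS", 28, 0.72),
            ("VAL", 24, 0.66),
        ],
        "cam": [
            ("ILE", 27, 1.0), ("LEU", 32, 1.0), ("ILE", 52, 1.0),
            ("ILE", 63, 1.0), ("PHE", 68, 1.0), ("MET", 71, 1.0),
            ("PHE", 19, 0.99), ("PHE", 89, 0.99), ("GLY", 98, 0.98),
            ("VAL", 55, 0.89), ("MET", 51, 0.88), ("ARG", 86, 0.85),
            ("MET", 36, 0.76), ("MET", 72, 0.74), ("LYS", 75, 0.73),
            ("THR", 79, 0.70), ("GLY", 96, 0.68), ("ASN", 97, 0.64),
        ],
    },
    2: {
        "abeta": [
            ("VAL", 39, 0.99), ("ALA", 42, 0.99), ("GLY", 38, 0.98),
            ("MET", 35, 0.96), ("ILE", 41, 0.82), ("VAL", 24, 0.79),
            ("LYS", 16, 0.5),
        ],
        "cam": [
            ("VAL", 136, 1.0), ("PHE", 141, 1.0), ("PHE", 92, 0.997),
            ("LEU", 105, 0.99), ("ALA", 88, 0.90), ("GLU", 87, 0.85),
            ("LEU", 112, 0.77), ("MET", 124, 0.63), ("MET", 109, 0.61),
            ("VAL", 91, 0.57), ("MET", 145, 0.56), ("ALA", 128, 0.52),
        ],
    },
}

ABETA_CALBINDIN = {
    1: {
        "abeta": [
            ("VAL", 24, 1.0), ("PHE", 20, 0.98), ("LEU", 34, 0.94),
            ("ASP", 23, 0.93), ("LEU", 17, 0.91), ("HIS", 14, 0.90),
            ("VAL", 18, 0.88), ("GLY", 38, 0.86), ("ILE", 31, 0.84),
            ("ALA", 21, 0.65), ("ILE", 41, 0.63), ("GLY", 33, 0.62),
            ("ALA", 30, 0.55), ("GLY", 37, 0.52),
        ],
        "calbindin": [
            ("VAL", 173, 0.96), ("ILE", 73, 0.94), ("VAL", 181, 0.88),
            ("LEU", 179, 0.86), ("LYS", 72, 0.85), ("GLU", 177, 0.85),
            ("HIS", 80, 0.84), ("SER", 28, 0.83), ("GLU", 57, 0.82),
            ("PHE", 61, 0.81), ("PRO", 172, 0.68), ("TYR", 30, 0.67),
            ("SER", 156, 0.61),
        ],
    },
    2: {
        "abeta": [
            ("GLY", 33, 0.98), ("GLY", 37, 0.96), ("ILE", 31, 0.91),
            ("PHE", 20, 0.86), ("ASP", 23, 0.78), ("LEU", 17, 0.75),
            ("ALA", 30, 0.75), ("LEU", 34, 0.74), ("HIS", 13, 0.68),
            ("LYS", 16, 0.66), ("ALA", 42, 0.63), ("ILE", 41, 0.55),
            ("VAL", 36, 0.54),
        ],
        "calbindin": [
            ("HIS", 80, 0.95), ("ARG", 47, 0.95), ("PRO", 172, 0.92),
            ("LEU", 89, 0.82), ("GLU", 57, 0.78), ("ARG", 93, 0.77),
            ("LEU", 82, 0.76), ("LYS", 98, 0.74), ("SER", 55, 0.74),
            ("GLU", 77, 0.73), ("PRO", 83, 0.72), ("LEU", 52, 0.71),
            ("VAL", 81, 0.63),
        ],
    },
    3: {
        "abeta": [
            ("GLY", 37, 0.99), ("ALA", 21, 0.95), ("ILE", 31, 0.92),
            ("LEU", 17, 0.80), ("ILE", 41, 0.78), ("LEU", 34, 0.76),
            ("GLY", 38, 0.71), ("HIS", 14, 0.69), ("VAL", 40, 0.63),
            ("PHE", 20, 0.62), ("ALA", 30, 0.53), ("ALA", 42, 0.52),
        ],
        "calbindin": [
            ("GLY", 188, 0.99), ("SER", 28, 0.95), ("ASN", 157, 0.87),
            ("ALA", 258, 0.84), ("GLU", 166, 0.83), ("PHE", 177, 0.80),
            ("ASN", 192, 0.72), ("CYS", 257, 0.70), ("ARG", 249, 0.70),
            ("SER", 156, 0.67), ("PHE", 191, 0.67), ("THR", 250, 0.63),
            ("GLN", 182, 0.63),
        ],
    },
}

#: ΔG metadata (kcal/mol) of the docked models, as reported by the docking
#: program; consumed as pose metadata, never computed here.
DELTA_G_CAM = {1: -17.0, 2: -15.0}
DELTA_G_CALBINDIN = {1: -17.0, 2: -12.0, 3: -11.6}

#: First residue of each 12-residue EF-hand Ca2+-binding loop of calmodulin
#: (1CLL author numbering) and the in-loop coordinating positions.
CAM_EF_LOOP_STARTS = (20, 56, 93, 129)
EF_COORDINATING_OFFSETS = (0, 2, 4, 6, 8, 11)  # loop positions 1,3,5,7,9,12

CAM_CALCIUM_SITE_RESIDUES = frozenset(
    start + off
    for start in CAM_EF_LOOP_STARTS
    for off in EF_COORDINATING_OFFSETS
)

#: Synthetic stand-in Cα geometry for the mimetic-design calibration: the
#: seven calmodulin hot spots the shipped calibration treats as the pairing
#: residues, laid out collinearly with spacings chosen so that nearest-
#: neighbor ordering and the 3.8 A virtual-bond spacer rule emit the
#: published antagonist sequence.  These are NOT crystallographic
#: coordinates.
REFERENCE_HOT_SPOT_RESIDUES = ("ILE27", "PHE19", "PHE89", "MET71",
                               "PHE68", "MET51", "LEU32")
REFERENCE_CA_GEOMETRY = {
    ("A", 27, "ILE"): (0.0, 0.0, 0.0),
    ("A", 19, "PHE"): (3.8, 0.0, 0.0),
    ("A", 89, "PHE"): (11.4, 0.0, 0.0),
    ("A", 71, "MET"): (19.0, 0.0, 0.0),
    ("A", 68, "PHE"): (26.6, 0.0, 0.0),
    ("A", 51, "MET"): (30.4, 0.0, 0.0),
    ("A", 32, "LEU"): (34.2, 0.0, 0.0),
}
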
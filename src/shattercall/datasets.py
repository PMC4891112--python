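"""Bundled demo truth tables.

These tables describe the curated rearrangement and copy-number landscape
of a proton-microbeam-irradiated oral-carcinoma monoclonal subline
(14 validated junctions, 16 de novo copy-number segments) expressed in
GRCh37-style coordinates.  They are the default truth set for the
synthetic-data generator, so every pipeline stage can be exercised and
validated against a known answer without external downloads.
"""

from __future__ import annotations

from .events import InsertionOrigin, JunctionSpec, RearrangementEvent

# GRCh37 chromosome lengths (bp), used as the coordinate system of the
# bundled tables and as the length-weighted null for localization tests.
GRCH37_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
    "X": 155_270_560,
}

# (id, chrom1, pos1, chrom2, pos2, rtype, junction-chemistry)
# Junction column: ("mh", seq) microhomology, ("blunt", None), or
# ("ins", seq) insertion.  Three junctions with no resolved chemistry are
# recorded as blunt, which reproduces the published 9/3/2 census.
_REARRANGEMENT_ROWS = [
    ("ID23", "2", 15_742_392, "2", 16_708_640, "RF", ("ins", "CTGAA")),
    ("ID29", "2", 48_937_454, "2", 81_807_507, "RF", ("mh", "C")),
    ("ID30", "2", 53_106_380, "2", 53_252_037, "LD", ("mh", "AA")),
    ("ID50", "3", 144_705_944, "12", 28_795_184, "CT", ("mh", "TT")),
    ("ID76", "5", 6_330_710, "5", 6_378_473, "RF", ("mh", "TG")),
    ("ID80", "5", 19_854_137, "5", 89_613_562, "LD", ("blunt", None)),
    ("ID91", "5", 89_613_939, "20", 14_453_942, "CT", ("mh", "TGGA")),
    ("ID93", "5", 95_994_652, "5", 96_157_380, "RF", ("mh", "GAT")),
    ("ID108", "7", 26_274_055, "7", 123_601_513, "LD", ("blunt", None)),
    ("ID109", "7", 51_228_098, "7", 51_281_802, "RF", ("mh", "TT")),
    ("ID119", "7", 127_757_875, "7", 127_820_864, "FF", ("mh", "TTT")),
    ("ID120", "7", 127_757_880, "11", 23_404_604, "CT", ("blunt", None)),
    ("ID143", "12", 53_845_481, "20", 5_707_700, "CT", ("mh", "G")),
    (
        "ID167",
        "20",
        57_562_329,
        "20",
        57_708_236,
        "LD",
        ("ins", "GCTCTGGTCCTGCATGACGTCCGTAGGATCACTT"),
    ),
]

# The ID167 insert is templated: it matches the reference 79 bp upstream
# of breakpoint 2, in reverse orientation.
_TEMPLATED_ORIGINS = {"ID167": InsertionOrigin("break2", -79, "reverse")}

# (chrom, call, start, end) -- 16 copy-number segments; the published
# length column equals end - start for every row.
_CNA_ROWS = [
    ("2", "Amp", 16_112_059, 16_374_530),
    ("2", "Amp", 48_874_201, 83_960_470),
    ("5", "Del", 60_181_452, 95_997_250),
    ("5", "Del", 96_133_485, 180_693_128),
    ("7", "Del", 26_267_811, 56_070_567),
    ("7", "Del", 90_400_492, 91_667_757),
    ("7", "Del", 93_403_513, 117_737_887),
    ("7", "Del", 127_700_973, 159_119_487),
    ("8", "Del", 164_984, 146_293_415),
    ("12", "Del", 191_619, 28_788_116),
    ("12", "Del", 30_194_870, 34_823_250),
    ("13", "Del", 19_058_717, 115_103_530),
    ("14", "Amp", 82_396_465, 82_542_289),
    ("16", "Del", 78_925_534, 79_054_884),
    ("17", "Del", 8_547, 81_051_008),
    ("21", "Del", 43_557_092, 43_634_574),
]


def demo_rearrangements() -> list[RearrangementEvent]:
    """The 14 validated demo rearrangements with junction chemistry."""
    events = []
    for rid, c1, p1, c2, p2, rtype, (kind, seq) in _REARRANGEMENT_ROWS:
        if kind == "mh":
            spec = JunctionSpec.microhomology(seq)
        elif kind == "blunt":
            spec = JunctionSpec.blunt()
        else:
            spec = JunctionSpec.insertion(seq, _TEMPLATED_ORIGINS.get(rid))
        events.append(RearrangementEvent(rid, c1, p1, c2, p2, rtype, spec))
    return events


def demo_cna_segments() -> list[dict]:
    """The 16 demo copy-number segments as plain records.

    Each record carries chrom/start/end/call plus a planted ``copy``
    value (1.0 for deletions, 3.0 for amplifications) used by the probe
    track simulator.
    """
    return [
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "call": call,
            "copy": 3.0 if call == "Amp" else 1.0,
        }
        for chrom, call, start, end in _CNA_ROWS
    ]
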
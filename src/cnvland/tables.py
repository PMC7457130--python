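"""Published reference values bundled as in-package fixtures.

Transcriptions of the printed contingency tables (region carrier counts by
WHO grade, surgical history, tumor size, gender, location, peritumoral
brain edema, and lesion multiplicity), the recurrent-region catalogue with
carrier frequencies, and cohort-level constants from a 383-patient
meningioma SNP-array study.  These support the reproduction suite: the
package's chi-square routine must recover the published p-values from the
published counts, and carrier counts must reconcile with the published
region frequencies.

Each contingency entry carries ``rel_tol``, the relative tolerance for
matching its published p-value: 0.005 (3 significant figures) for the
entries whose printed value is exact, 0.25 for the four entries whose
printed value appears rounded more coarsely (their recomputed values are
1.88e-5, 4.26e-3, 2.41e-3 and 2.44e-3 against printed 1.90e-5, 4.00e-3,
2.00e-3 and 2.00e-3).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ContingencyFixture",
    "CONTINGENCY_TABLES",
    "MCR_CATALOG",
    "COHORT_SIZE",
    "N_FEMALE",
    "N_MALE",
    "FREQUENCY_CHECKS",
]

COHORT_SIZE = 383
N_FEMALE = 265
N_MALE = 118


@dataclass(frozen=True)
class ContingencyFixture:
    """A published region-by-phenotype table with its published p-value."""

    region: str
    phenotype: str
    row_states: tuple[str, ...]  # subset of ('loss', 'no change', 'gain')
    col_levels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]
    published_p: float
    rel_tol: float = 0.005


_GRADE = ("I", "II", "III")
_HIST = ("primary", "recurrent")
_SIZE = ("small", "large")
_GENDER = ("female", "male")
_LOC = ("non-skull-base", "skull-base")
_PBE = ("no", "yes")
_MULT = ("single", "multiple")

CONTINGENCY_TABLES: tuple[ContingencyFixture, ...] = (
    # --- WHO grade ---
    ContingencyFixture("1p22.1", "who_grade", ("loss", "no change"), _GRADE,
                       ((40, 16, 4), (291, 30, 2)), 9.42e-7),
    ContingencyFixture("1p31.3", "who_grade", ("loss", "no change", "gain"), _GRADE,
                       ((50, 19, 4), (244, 24, 2), (37, 3, 0)), 1.90e-5, rel_tol=0.25),
    ContingencyFixture("1p34.3", "who_grade", ("loss", "no change", "gain"), _GRADE,
                       ((56, 18, 4), (243, 21, 2), (32, 7, 0)), 9.30e-5),
    ContingencyFixture("1q31.3", "who_grade", ("no change", "gain"), _GRADE,
                       ((300, 35, 3), (31, 11, 3)), 2.20e-4),
    ContingencyFixture("1q42.12", "who_grade", ("loss", "no change", "gain"), _GRADE,
                       ((36, 8, 1), (264, 27, 1), (31, 11, 4)), 7.64e-6),
    ContingencyFixture("2p24.1", "who_grade", ("loss", "no change", "gain"), _GRADE,
                       ((19, 2, 3), (294, 39, 3), (18, 5, 0)), 1.88e-4),
    ContingencyFixture("4q13.3", "who_grade", ("loss", "no change"), _GRADE,
                       ((22, 4, 4), (309, 42, 2)), 4.01e-7),
    ContingencyFixture("6q22.31", "who_grade", ("loss", "no change"), _GRADE,
                       ((15, 8, 4), (316, 38, 2)), 4.05e-10),
    ContingencyFixture("7p12.3", "who_grade", ("loss", "no change", "gain"), _GRADE,
                       ((18, 6, 3), (266, 37, 1), (47, 3, 2)), 3.49e-5),
    ContingencyFixture("9p21.3", "who_grade", ("loss", "no change"), _GRADE,
                       ((9, 6, 2), (322, 40, 4)), 1.55e-5),
    ContingencyFixture("10p11.22", "who_grade", ("loss", "no change", "gain"), _GRADE,
                       ((12, 5, 2), (301, 39, 4), (18, 2, 0)), 4.48e-3),
    ContingencyFixture("11p12", "who_grade", ("loss", "no change"), _GRADE,
                       ((12, 7, 1), (319, 39, 5)), 1.86e-3),
    ContingencyFixture("14q23.1", "who_grade", ("loss", "no change"), _GRADE,
                       ((39, 13, 2), (292, 33, 4)), 4.00e-3, rel_tol=0.25),
    ContingencyFixture("14q32.2", "who_grade", ("loss", "no change", "gain"), _GRADE,
                       ((29, 14, 3), (277, 30, 3), (25, 2, 0)), 2.44e-5),
    ContingencyFixture("22q13.2", "who_grade", ("loss", "no change"), _GRADE,
                       ((91, 21, 5), (240, 25, 1)), 7.92e-4),
    # --- history of surgery ---
    ContingencyFixture("1p22.1", "history", ("loss", "no change"), _HIST,
                       ((42, 18), (296, 27)), 1.75e-6),
    ContingencyFixture("1p31.3", "history", ("loss", "no change", "gain"), _HIST,
                       ((52, 21), (249, 21), (37, 3)), 3.38e-6),
    ContingencyFixture("1p34.3", "history", ("loss", "no change", "gain"), _HIST,
                       ((55, 23), (247, 19), (36, 3)), 3.50e-7),
    ContingencyFixture("6q22.31", "history", ("loss", "no change"), _HIST,
                       ((17, 10), (321, 35)), 2.31e-5),
    ContingencyFixture("9p21.3", "history", ("loss", "no change"), _HIST,
                       ((10, 7), (328, 38)), 1.16e-4),
    ContingencyFixture("11p12", "history", ("loss", "no change"), _HIST,
                       ((13, 7), (325, 38)), 9.10e-4),
    ContingencyFixture("14q23.1", "history", ("loss", "no change"), _HIST,
                       ((41, 13), (297, 32)), 2.00e-3, rel_tol=0.25),
    # --- tumor size ---
    ContingencyFixture("1p31.3", "size_group", ("loss", "no change", "gain"), _SIZE,
                       ((26, 47), (151, 119), (15, 25)), 2.10e-3),
    ContingencyFixture("1p34.3", "size_group", ("loss", "no change", "gain"), _SIZE,
                       ((25, 53), (155, 111), (12, 27)), 9.65e-6),
    # --- gender ---
    ContingencyFixture("1p22.1", "gender", ("loss", "no change"), _GENDER,
                       ((30, 30), (235, 88)), 4.55e-4),
    ContingencyFixture("1p31.3", "gender", ("loss", "no change", "gain"), _GENDER,
                       ((37, 36), (198, 72), (30, 10)), 6.98e-4),
    ContingencyFixture("1p34.3", "gender", ("loss", "no change", "gain"), _GENDER,
                       ((37, 41), (201, 65), (27, 12)), 1.38e-5),
    ContingencyFixture("6p21.33", "gender", ("loss", "no change", "gain"), _GENDER,
                       ((50, 20), (204, 81), (11, 17)), 1.77e-3),
    ContingencyFixture("14q23.1", "gender", ("loss", "no change"), _GENDER,
                       ((19, 35), (246, 83)), 5.23e-9),
    ContingencyFixture("14q32.2", "gender", ("loss", "no change", "gain"), _GENDER,
                       ((20, 26), (223, 87), (22, 5)), 1.77e-4),
    ContingencyFixture("19p12", "gender", ("loss", "no change"), _GENDER,
                       ((25, 23), (240, 95)), 6.05e-3),
    # --- tumor location ---
    ContingencyFixture("1p22.1", "location", ("loss", "no change"), _LOC,
                       ((33, 27), (111, 212)), 2.00e-3, rel_tol=0.25),
    ContingencyFixture("8p11.22", "location", ("loss", "no change", "gain"), _LOC,
                       ((28, 30), (107, 166), (9, 43)), 2.20e-3),
    ContingencyFixture("14q32.2", "location", ("loss", "no change", "gain"), _LOC,
                       ((27, 19), (114, 196), (3, 24)), 2.15e-4),
    ContingencyFixture("22q11.1", "location", ("no change", "gain"), _LOC,
                       ((112, 136), (32, 103)), 3.45e-5),
    ContingencyFixture("22q13.2", "location", ("loss", "no change"), _LOC,
                       ((66, 51), (78, 188)), 4.63e-7),
    # --- peritumoral brain edema ---
    ContingencyFixture("1p22.1", "edema", ("loss", "no change"), _PBE,
                       ((31, 29), (234, 89)), 1.37e-3),
    ContingencyFixture("4p16.3", "edema", ("loss", "no change"), _PBE,
                       ((18, 19), (247, 99)), 4.41e-3),
    ContingencyFixture("9p21.3", "edema", ("loss", "no change"), _PBE,
                       ((6, 11), (259, 107)), 1.96e-3),
    ContingencyFixture("14q23.1", "edema", ("loss", "no change"), _PBE,
                       ((29, 25), (236, 93)), 7.83e-3),
    ContingencyFixture("20q13.33", "edema", ("no change", "gain"), _PBE,
                       ((252, 100), (13, 18)), 6.07e-4),
    # --- lesion multiplicity ---
    ContingencyFixture("10q23.31", "multiple", ("loss", "no change", "gain"), _MULT,
                       ((58, 0), (257, 16), (44, 8)), 3.49e-3),
)

# Recurrent-region catalogue: (cytoband, type, chrom, start_bp, end_bp,
# size_kb, n_genes, frequency_percent) — boundaries 1-based inclusive.
MCR_CATALOG = (
    ("1p12", "gain", "1", 117631472, 121239762, 3608, 29, 2.87),
    ("1p31.3", "gain", "1", 62921155, 63282308, 361, 3, 10.44),
    ("1p34.3", "gain", "1", 35453772, 35870648, 417, 4, 10.44),
    ("1q31.3", "gain", "1", 196525315, 199864159, 3339, 22, 11.75),
    ("1q42.12", "gain", "1", 225137135, 225458504, 321, 1, 12.01),
    ("2p24.1", "gain", "2", 20078572, 20173435, 95, 3, 6.01),
    ("3q26.33", "gain", "3", 180322742, 180397085, 74, 2, 4.96),
    ("6p21.33", "gain", "6", 31237665, 31322196, 85, 2, 8.09),
    ("6p22.1", "gain", "6", 29910981, 29913077, 2, 1, 6.79),
    ("7p12.3", "gain", "7", 48313001, 48318810, 6, 1, 13.58),
    ("8p11.22", "gain", "8", 38971607, 39678651, 707, 6, 13.58),
    ("9p22.2", "gain", "9", 17269438, 17484335, 215, 1, 6.27),
    ("9q21.2", "gain", "9", 79827895, 80010024, 182, 1, 9.66),
    ("10p11.22", "gain", "10", 32740815, 33165314, 424, 1, 5.22),
    ("10q23.31", "gain", "10", 91469746, 91505720, 36, 1, 13.58),
    ("11q22.3", "gain", "11", 103004336, 103153757, 149, 1, 10.70),
    ("12p12.2", "gain", "12", 21011481, 21417898, 406, 4, 11.23),
    ("12q21.32", "gain", "12", 88465703, 88566416, 101, 3, 12.01),
    ("13q32.1", "gain", "13", 96506648, 96705463, 199, 1, 10.70),
    ("14q11.2", "gain", "14", 1, 20425050, 20425, 16, 13.58),
    ("14q32.2", "gain", "14", 96756059, 96813532, 57, 1, 7.05),
    ("15q22.2", "gain", "15", 62202415, 62332979, 131, 1, 16.45),
    ("16q23.1", "gain", "16", 75766089, 76806431, 1040, 1, 6.27),
    ("17q21.31", "gain", "17", 41256213, 41276031, 20, 1, 11.75),
    ("17q24.3", "gain", "17", 66878095, 67324998, 447, 7, 10.97),
    ("18p11.32", "gain", "18", 2533131, 2831495, 298, 4, 7.83),
    ("20q13.33", "gain", "20", 58405221, 58519202, 114, 4, 8.09),
    ("22q11.1", "gain", "22", 1, 18300886, 18301, 27, 35.25),
    ("1p22.1", "loss", "1", 93620394, 94027864, 407, 4, 15.67),
    ("1p31.3", "loss", "1", 62767954, 63632517, 865, 4, 19.06),
    ("1p34.3", "loss", "1", 35444038, 35900519, 456, 5, 20.63),
    ("1q42.12", "loss", "1", 224916594, 225590674, 674, 1, 11.75),
    ("2p24.1", "loss", "2", 20076455, 20197016, 121, 2, 6.27),
    ("2q33.2", "loss", "2", 203621938, 204193687, 572, 5, 10.18),
    ("3p14.3", "loss", "3", 57187079, 57994564, 807, 8, 5.22),
    ("4p16.3", "loss", "4", 1, 493146, 493, 8, 9.66),
    ("4q13.3", "loss", "4", 58064465, 77139509, 19075, 104, 7.83),
    ("4q28.2", "loss", "4", 128748468, 129193525, 445, 4, 8.88),
    ("6p21.33", "loss", "6", 31324926, 31467364, 142, 3, 11.75),
    ("6p21.33b", "loss", "6", 31239830, 31368124, 128, 1, 10.18),
    ("6q22.31", "loss", "6", 73934060, 152442820, 78509, 397, 7.05),
    ("7p12.3", "loss", "7", 48147076, 48981328, 834, 2, 7.05),
    ("7q11.21", "loss", "7", 57531190, 64451645, 6920, 19, 7.57),
    ("8p11.22", "loss", "8", 39142265, 39771450, 629, 5, 15.14),
    ("8q13.1", "loss", "8", 67577141, 68113721, 537, 11, 6.79),
    ("9p21.3", "loss", "9", 21865843, 22447070, 581, 4, 4.44),
    ("9q21.2", "loss", "9", 79783752, 80039005, 255, 2, 9.66),
    ("10p11.22", "loss", "10", 32634973, 33190566, 556, 1, 4.96),
    ("10q23.31", "loss", "10", 91405045, 91592197, 187, 2, 15.14),
    ("11p12", "loss", "11", 36680720, 43605303, 6925, 7, 5.22),
    ("11p15.1", "loss", "11", 17062455, 17408024, 346, 5, 6.79),
    ("11q22.3", "loss", "11", 102935067, 103734644, 800, 2, 9.66),
    ("12p12.2", "loss", "12", 21069809, 21417617, 348, 2, 12.27),
    ("12q21.32", "loss", "12", 88439501, 88890670, 451, 2, 11.23),
    ("13q13.1", "loss", "13", 32886039, 32977098, 91, 1, 17.23),
    ("14q11.2", "loss", "14", 1, 20443750, 20444, 16, 28.98),
    ("14q23.1", "loss", "14", 58734239, 59101447, 367, 4, 14.10),
    ("14q32.2", "loss", "14", 96731074, 96846091, 115, 1, 12.01),
    ("15q22.2", "loss", "15", 61509172, 62359861, 851, 1, 15.14),
    ("17q21.31", "loss", "17", 41180695, 41278115, 97, 1, 4.96),
    ("19p12", "loss", "19", 19906363, 23958291, 4052, 42, 12.53),
    ("19p13.2", "loss", "19", 11842324, 12757476, 915, 25, 10.44),
    ("19q13.12", "loss", "19", 36950172, 38319896, 1370, 34, 8.36),
    ("22q13.2", "loss", "22", 42518427, 42557362, 39, 2, 30.55),
)

# Internal-consistency checks: published carrier counts against the
# published region frequency (percent of the 383-patient cohort).
FREQUENCY_CHECKS = {
    # region, type: (carrier count from the location table, published percent)
    ("22q11.1", "gain"): (32 + 103, 35.25),
    ("22q13.2", "loss"): (66 + 51, 30.55),
}

FEMALE_MALE_RATIO = 2.24  # published cohort ratio 265:118
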
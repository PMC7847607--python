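"""Published rice PHAS coordinates used as frozen fixtures.

Binding-site -> cleavage-site pairs from characterized Oryza sativa
trigger and tasiRNA interactions (1-based inclusive target coordinates),
plus phasiRNA identifiers in the field's D-position naming with its
typographic variation.  All cleavage sites sit opposite sRNA position 10,
i.e. at binding_end - 9.
"""

# (binding_start, binding_end, cleavage_site) of sRNA triggers on their
# PHAS precursors; includes 21- and 22-nt triggers.
TRIGGER_CLEAVAGE_PAIRS = [
    (424, 444, 435),
    (176, 197, 188),
    (1875, 1896, 1887),
    (1528, 1549, 1540),
    (50, 71, 62),
    (1676, 1697, 1688),
    (4873, 4894, 4885),
    (5007, 5027, 5018),
    (922, 943, 934),
    (1103, 1124, 1115),
    (4578, 4599, 4590),
]

# (miru_start, miru_end, cut_site) of tasiRNA-target interactions.
TASIRNA_CUT_PAIRS = [
    (1676, 1696, 1687),
    (343, 363, 354),
    (802, 823, 814),
    (1248, 1268, 1259),
    (500, 520, 511),
    (1195, 1215, 1206),
    (2137, 2157, 2148),
    (1093, 1113, 1104),
    (648, 668, 659),
    (4632, 4652, 4643),
    (97, 117, 108),
    (2050, 2070, 2061),
    (1315, 1335, 1326),
    (1021, 1041, 1032),
    (1714, 1734, 1725),
    (1030, 1050, 1041),
    (973, 993, 984),
    (1071, 1091, 1082),
    (1760, 1780, 1771),
    (1330, 1350, 1341),
    (1324, 1344, 1335),
    (2034, 2054, 2045),
    (1340, 1360, 1351),
    (651, 671, 662),
    (445, 465, 456),
    (1026, 1046, 1037),
    (1082, 1102, 1093),
    (929, 949, 940),
    (1586, 1606, 1597),
    (1457, 1477, 1468),
    (1454, 1474, 1465),
    (1740, 1760, 1751),
    (1453, 1473, 1464),
    (1375, 1395, 1386),
    (1584, 1604, 1595),
    (1758, 1778, 1769),
    (1020, 1040, 1031),
    (4240, 4260, 4251),
    (1312, 1332, 1323),
    (1365, 1385, 1376),
    (1753, 1773, 1764),
]

# phasiRNA identifiers as printed in the field's tables, with curly
# primes, stray spaces and unicode minus signs; each maps to the parsed
# (locus, anchor, k, arm, index, strand).
PUBLISHED_PHASIRNA_NAMES = [
    ("LOC_Os02g18750.1(189)21 3’D26 (+)",
     ("LOC_Os02g18750.1", 189, 21, "3'", 26, "+")),
    ("LOC_Os05g43650.1(1540)21 3’D2(+)",
     ("LOC_Os05g43650.1", 1540, 21, "3'", 2, "+")),
    ("LOC_Os05g43650.1(1540)21 3’D2(−)",
     ("LOC_Os05g43650.1", 1540, 21, "3'", 2, "-")),
    ("LOC_Os06g30680.1(62)21 3′ D2(+)",
     ("LOC_Os06g30680.1", 62, 21, "3'", 2, "+")),
    ("LOC_Os12g42380.1(414)21 5’D7(+)",
     ("LOC_Os12g42380.1", 414, 21, "5'", 7, "+")),
    ("LOC_Os01g37325.1(1684) 24 5’D12(+)",
     ("LOC_Os01g37325.1", 1684, 24, "5'", 12, "+")),
]

# A 24-nt phasiRNA with a known promoter binding site at 111-134 on a
# 200-nt promoter (complementary orientation).
PROMOTER_PHASIRNA_RNA = "AUCAUGACUUGGGUAUUACGUUUC"
PROMOTER_HIT_SPAN = (111, 134)
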
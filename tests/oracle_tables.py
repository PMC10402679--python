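"""Independently transcribed reference tables used as test oracles.

These were written down by hand, directly from the published band rules and
tables, before the implementation was tested against them — they must never
be generated from the code under test.
"""

# 10x10 risk grid, one string row per occurrence rank O = 10 down to 1,
# one letter per severity rank S = 1..10 (L low, M medium, H high).
# Hand tally: 32 L, 19 M, 49 H.
RISK_GRID_BY_O = {
    10: "LHHHHHHHHH",
    9: "LHHHHHHHHH",
    8: "LMHHHHHHHH",
    7: "LMMHHHHHHH",
    6: "LLMMHHHHHH",
    5: "LLLMMMHHHH",
    4: "LLLLMMMHHH",
    3: "LLLLLMMMHH",
    2: "LLLLLLMMMH",
    1: "LLLLLLLLMM",
}


def oracle_level(S: int, O: int) -> str:
    return {"L": "low", "M": "medium", "H": "high"}[RISK_GRID_BY_O[O][S - 1]]


# Published per-interval mean severity indices (grid D1..D60) and occurrence
# ranks for the six QC items of the study machine.
PUBLISHED_S_MEANS = {
    1: (1.200, 2.950, 4.350, 4.950, 5.800, 7.500),
    2: (1.200, 2.950, 4.350, 4.950, 5.800, 7.500),
    3: (1.125, 2.188, 3.938, 4.875, 5.688, 7.438),
    4: (1.412, 3.647, 5.471, 5.941, 7.294, 8.647),
    5: (2.278, 5.389, 6.556, 7.556, 8.333, 9.056),
    6: (1.615, 4.308, 6.462, 7.538, 8.308, 9.308),
}
PUBLISHED_O_RANKS = {1: 6, 2: 2, 3: 2, 4: 2, 5: 2, 6: 2}

# Published recommended intervals under default (nearest) rounding. Item 5 is
# excluded: no single rounding convention reproduces its printed interval
# without breaking item 1 (see docs/methods.md).
PUBLISHED_RECOMMENDATIONS = {1: 7, 2: 60, 3: 60, 4: 30, 6: 21}

# Published schedule evaluations: item -> ((O_new, D_new), (O_old, D_old)).
PUBLISHED_SCHEDULE_RANKS = {
    1: ((2, 1), (2, 5)),
    2: ((2, 1), (2, 1)),
    3: ((2, 1), (2, 1)),
    4: ((2, 1), (2, 1)),
    5: ((2, 1), (2, 1)),
    6: ((2, 6), (2, 7)),
}
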
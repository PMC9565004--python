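"""Frozen published reference values for the husbands' dataset.

The minsup ladder families and phase tallies asserted in the tests, as the
study report prints them; the miner must reproduce them itemset-for-itemset.
"""

HUSBANDS_SINGLETON_SUPPORTS = {1: 3900, 2: 3946, 3: 4425, 4: 2889, 5: 2008}

# Trimmed-and-merged patterns at 38% minsup (frequent items {1,2,3,4}).
HUSBANDS_TRIMMED_38 = {
    (1,): 480,
    (2,): 346,
    (3,): 699,
    (4,): 215,
    (1, 2): 360,
    (1, 3): 279,
    (1, 4): 81,
    (2, 3): 329,
    (2, 4): 112,
    (3, 4): 276,
    (1, 2, 3): 733,
    (1, 2, 4): 96,
    (1, 3, 4): 139,
    (2, 3, 4): 238,
    (1, 2, 3, 4): 1732,
}

# Fully accumulated phase-3 supports of every candidate at 38% minsup.
HUSBANDS_ACCUMULATED_38 = {
    (1,): 3900,
    (2,): 3946,
    (3,): 4425,
    (4,): 2889,
    (1, 2): 2921,
    (1, 3): 2883,
    (1, 4): 2048,
    (2, 3): 3032,
    (2, 4): 2178,
    (3, 4): 2385,
    (1, 2, 3): 2465,
    (1, 2, 4): 1828,
    (1, 3, 4): 1871,
    (2, 3, 4): 1970,
    (1, 2, 3, 4): 1732,
}

# Minsup ladder for the husbands' dataset: percent -> frequent family.
HUSBANDS_LADDER = {
    70: {(3,)},
    63: {(2,), (3,)},
    62: {(1,), (2,), (3,)},
    48: {(1,), (2,), (3,), (2, 3)},
    46: {(1,), (2,), (3,), (4,), (1, 2), (1, 3), (2, 3)},
    39: {(1,), (2,), (3,), (4,), (1, 2), (1, 3), (2, 3), (1, 2, 3)},
    38: {(1,), (2,), (3,), (4,), (1, 2), (1, 3), (2, 3), (3, 4), (1, 2, 3)},
    34: {(1,), (2,), (3,), (4,), (1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (1, 2, 3)},
    32: {(1,), (2,), (3,), (4,), (5,), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4), (1, 2, 3)},
    31: {(1,), (2,), (3,), (4,), (5,), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4), (1, 2, 3), (2, 3, 4)},
    26: {(1,), (2,), (3,), (4,), (5,), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4), (3, 5),
         (1, 2, 3), (1, 2, 4), (1, 3, 4), (2, 3, 4), (1, 2, 3, 4)},
}

# Wives-side percentage supports as published (transcribed, not recomputed:
# the wives' raw data is not available at desk scale).
WIVES_TRANSCRIBED_PCT = {
    (2, 3): 60,
    (3, 4): 55,
    (1, 2): 55,
    (2, 4): 51,
    (1, 3): 52,
}
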
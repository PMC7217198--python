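"""Worked four-arm dataset: one simulated run of the stratified design.

Cumulative per-centre sample sizes and success counts at every interim
each arm was present.  Arm 2 was eliminated by arm 1 at interim 4,
arm 4 by arm 1 at interim 5, and arm 3 by arm 1 at interim 12, leaving
arm 1 the sole winner after 1188 patients.
"""

# arm -> centre -> (cumulative n, cumulative S)
TABLE5 = {
    1: {
        1: ([11, 18, 30, 41, 50, 57, 65, 76, 86, 92, 98, 103],
            [10, 17, 27, 35, 41, 46, 53, 63, 69, 74, 78, 83]),
        2: ([10, 16, 25, 33, 41, 49, 60, 71, 82, 88, 96, 100],
            [10, 14, 20, 25, 30, 34, 40, 47, 58, 61, 65, 67]),
        3: ([7, 17, 25, 35, 44, 55, 63, 68, 72, 83, 90, 104],
            [6, 11, 16, 20, 26, 32, 36, 41, 43, 49, 55, 64]),
        4: ([8, 21, 28, 35, 45, 55, 64, 73, 84, 97, 112, 125],
            [4, 13, 15, 20, 27, 34, 38, 45, 48, 53, 62, 68]),
    },
    2: {
        1: ([12, 24, 31, 39], [9, 17, 19, 25]),
        2: ([6, 13, 25, 30], [4, 8, 12, 13]),
        3: ([7, 16, 22, 35], [5, 11, 15, 21]),
        4: ([11, 19, 30, 40], [1, 5, 8, 11]),
    },
    3: {
        1: ([9, 19, 29, 39, 48, 57, 67, 74, 85, 91, 102, 111],
            [8, 15, 21, 27, 33, 41, 49, 56, 65, 70, 79, 85]),
        2: ([7, 15, 24, 32, 40, 49, 57, 64, 72, 79, 88, 94],
            [5, 9, 15, 22, 28, 31, 33, 38, 44, 47, 52, 56]),
        3: ([9, 17, 25, 32, 42, 50, 58, 68, 76, 90, 101, 111],
            [3, 5, 8, 13, 21, 27, 31, 37, 41, 48, 55, 60]),
        4: ([11, 21, 30, 41, 50, 60, 70, 82, 91, 100, 105, 116],
            [4, 7, 12, 15, 18, 23, 26, 34, 37, 42, 44, 45]),
    },
    4: {
        1: ([9, 15, 23, 36, 50], [5, 11, 17, 24, 32]),
        2: ([9, 20, 32, 42, 47], [6, 11, 16, 24, 27]),
        3: ([11, 19, 28, 32, 40], [5, 8, 12, 14, 18]),
        4: ([7, 18, 25, 34, 43], [3, 9, 10, 13, 16]),
    },
}

# (interim, eliminated arm, eliminating arm)
ELIMINATIONS = [(4, 2, 1), (5, 4, 1), (12, 3, 1)]
WINNER = 1
K_FINAL = 12
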
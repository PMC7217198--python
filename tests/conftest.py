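import pytest

from seqelim import fixture_table5, get_design


@pytest.fixture(scope="session")
def table5():
    return fixture_table5()


@pytest.fixture(scope="session")
def two_arm():
    return get_design("two_arm_tri")


@pytest.fixture(scope="session")
def four_arm():
    return get_design("four_arm_sepsis")


@pytest.fixture(scope="session")
def four_arm_simple():
    return get_design("four_arm_simple")


# Terminal data of 12 reference realizations of the two-arm triangular
# test, with their naive analyses; columns:
# case, stop interim, n per arm, S1, S2, Z*, V*, boundary, theta_hat, lo, hi
TWO_ARM_CASES = [
    (1, 2, 72, 35, 59, -12.0, 8.160, 0, -1.471, -2.157, -0.784),
    (2, 3, 108, 68, 87, -9.5, 10.943, 0, -0.868, -1.461, -0.276),
    (3, 4, 144, 102, 118, -8.0, 12.986, 0, -0.616, -1.160, -0.072),
    (4, 10, 360, 284, 285, -0.5, 29.833, 0, -0.017, -0.376, 0.342),
    (5, 8, 288, 201, 201, 0.0, 30.359, 0, 0.000, -0.356, 0.356),
    (6, 13, 468, 275, 259, 8.0, 57.337, 0, 0.140, -0.119, 0.398),
    (7, 9, 324, 252, 222, 15.0, 31.819, 1, 0.471, 0.124, 0.819),
    (8, 6, 216, 120, 88, 16.0, 26.963, 1, 0.593, 0.216, 0.971),
    (9, 6, 216, 161, 130, 15.5, 23.745, 1, 0.653, 0.251, 1.055),
    (10, 5, 180, 135, 108, 13.5, 19.744, 1, 0.684, 0.243, 1.125),
    (11, 5, 180, 124, 92, 16.0, 21.600, 1, 0.741, 0.319, 1.162),
    (12, 3, 108, 82, 55, 13.5, 12.527, 1, 1.078, 0.524, 1.631),
]

# Reference Rao-Blackwellized analyses of the same 12 cases:
# case -> (RB1 theta, RB1 SE, RB2 % complete, RB2 theta, RB2 SE)
RB_RESULTS = {
    1: (-1.463, 0.360, 99.3, -1.473, 0.383),
    2: (-0.823, 0.325, 89.3, -0.834, 0.334),
    3: (-0.560, 0.298, 79.9, -0.567, 0.295),
    4: (0.046, 0.204, 55.7, 0.046, 0.158),
    5: (0.051, 0.201, 67.0, 0.052, 0.183),
    6: (0.224, 0.166, 17.0, 0.227, 0.158),
    7: (0.420, 0.197, 63.7, 0.424, 0.185),
    8: (0.519, 0.214, 56.0, 0.529, 0.213),
    9: (0.580, 0.226, 54.9, 0.584, 0.229),
    10: (0.653, 0.239, 85.7, 0.658, 0.245),
    11: (0.655, 0.238, 58.5, 0.671, 0.243),
    12: (1.059, 0.291, 95.8, 1.069, 0.312),
}

# Comparative statistics derived from the worked four-arm dataset:
# pair -> (interim, per-centre (Z, V), total (Z, V))
PAIR_COMPARISONS = {
    (1, 2): (4, [(4.25, 3.75), (5.10, 3.76), (-0.50, 4.25), (5.53, 4.53)],
             (14.38, 16.28)),
    (1, 3): (12, [(2.14, 9.02), (3.60, 11.24), (4.02, 13.11), (9.39, 14.98)],
             (19.15, 48.35)),
    (1, 4): (5, [(4.50, 4.93), (3.44, 5.00), (2.95, 5.23), (5.01, 5.49)],
             (15.91, 20.64)),
    (2, 3): (4, [(-1.00, 4.33), (-3.94, 3.81), (3.23, 4.18), (-1.84, 4.41)],
             (-3.54, 16.73)),
    (2, 4): (4, [(-0.48, 4.24), (-2.42, 4.37), (2.72, 4.17), (-1.97, 4.03)],
             (-2.15, 16.81)),
    (3, 4): (5, [(1.16, 5.47), (2.71, 5.02), (1.02, 5.11), (-0.28, 5.36)],
             (4.62, 20.97)),
}
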
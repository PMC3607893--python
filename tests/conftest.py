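import pytest

from mitopop import default_reference, load_default_tree


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def tree():
    return load_default_tree()


# Table of printed rho/sigma/years/SD cells used as conversion inputs
# (divergence block then coalescence block).
RHO_TABLE = [
    ("divergence", "L0d", 10.8580, 2.2635, 96601, 20138),
    ("divergence", "L0d1a", 7.1351, 2.0865, 63480, 18563),
    ("divergence", "L0d1b", 4.6709, 1.5502, 41556, 13792),
    ("divergence", "L0d1c", 6.7119, 2.2906, 59714, 20379),
    ("divergence", "L0d2a", 3.8242, 1.7380, 34023, 15463),
    ("divergence", "L0d2b", 8.5000, 2.4777, 75623, 22044),
    ("divergence", "L0d2c", 3.2941, 1.5519, 29307, 13807),
    ("divergence", "L0d2d", 5.0000, 1.8559, 44484, 16512),
    ("divergence", "L0d3", 8.0000, 2.6273, 71174, 23375),
    ("divergence", "L0dx", 4.0000, 1.5411, 35587, 13711),
    ("divergence", "L0k1", 8.5161, 2.8144, 75766, 25039),
    ("coalescence", "L0d", 9.8580, 2.0307, 87705, 18067),
    ("coalescence", "L0d1", 6.4286, 1.2576, 57194, 11189),
    ("coalescence", "L0d2", 4.8718, 1.6199, 43343, 14412),
    ("coalescence", "L0d1a", 4.1351, 1.1634, 36789, 10351),
    ("coalescence", "L0d1b", 3.6709, 1.1845, 32659, 10538),
    ("coalescence", "L0d1c", 4.7119, 1.8019, 41921, 16031),
    ("coalescence", "L0d2a", 1.8242, 1.0143, 16230, 9024),
    ("coalescence", "L0d2b", 6.5000, 2.0344, 57829, 18100),
    ("coalescence", "L0d2c", 2.2941, 1.1867, 20410, 10558),
    ("coalescence", "L0d2d", 4.0000, 1.5635, 35587, 13910),
    ("coalescence", "L0d3", 4.0000, 1.7037, 35587, 15157),
    ("coalescence", "L0dx", 3.0000, 1.1726, 26690, 10432),
    ("coalescence", "L0k1", 1.5161, 0.9596, 13488, 8538),
]
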
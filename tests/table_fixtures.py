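"""Frozen copies of the published factor score tables and grading schemes.

These are typed out independently of the package's shipped CSV so that the
fidelity tests compare two separate transcriptions cell by cell.  Binned
entries are (lower, upper, score) with None for an open end; categorical
entries are (class name, code, score).
"""

PRINTED_BINNED = {
    "Pr": [(None, 100, 1.7), (100, 200, 3.4), (200, 400, 5.1),
           (400, 600, 6.8), (600, 800, 8.5), (800, None, 10.0)],
    "T": [(None, -5, 2.0), (-5, -3, 4.0), (-3, 0, 6.0), (0, 10, 8.0),
          (10, None, 10.0)],
    "Di": [(None, 0.05, 2.0), (0.05, 0.2, 4.0), (0.2, 0.5, 6.0),
           (0.5, 0.65, 8.0), (0.65, None, 10.0)],
    "Al": [(None, 2300, 10.0), (2300, 3600, 8.0), (3600, 4400, 6.0),
           (4400, 5000, 4.0), (5000, None, 2.0)],
    "Par": [(None, 3300, 2.0), (3300, 3500, 4.0), (3500, 3700, 6.0),
            (3700, 3800, 8.0), (3800, None, 10.0)],
    "At": [(None, 500, 1.25), (500, 1000, 2.50), (1000, 2000, 3.75),
           (2000, 3000, 5.00), (3000, 4000, 6.25), (4000, 5000, 7.50),
           (5000, 6000, 8.75), (6000, None, 10.00)],
    "Sd": [(None, 10, 2.5), (10, 30, 5.0), (30, 100, 7.5),
           (100, None, 10.0)],
    "St": [(None, 0.25, 2.5), (0.25, 0.5, 5.0), (0.5, 0.75, 7.5),
           (0.75, None, 10.0)],
    "Som": [(None, 0.8, 2.0), (0.8, 2.7, 4.0), (2.7, 5, 6.0),
            (5, 9.2, 8.0), (9.2, None, 10.0)],
    "Sm": [(None, 0.06, 2.0), (0.06, 0.077, 4.0), (0.077, 0.098, 6.0),
           (0.098, 0.122, 8.0), (0.122, None, 10.0)],
    "Vc": [(None, 5, 2.0), (5, 50, 4.0), (50, 100, 6.0), (100, 158, 8.0),
           (158, None, 10.0)],
    "Vr": [(None, 0.005, 2.0), (0.005, 0.01, 4.0), (0.01, 0.02, 6.0),
           (0.02, 0.22, 8.0), (0.22, None, 10.0)],
    "NPP": [(None, 50, 2.0), (50, 100, 4.0), (100, 500, 6.0),
            (500, 1000, 8.0), (1000, None, 10.0)],
}

PRINTED_CATEGORICAL = {
    "Sei": [("Severe", 1, 1.7), ("Extreme slightly", 2, 3.4),
            ("Strength", 3, 5.1), ("Moderate", 4, 6.8), ("Mild", 5, 8.5),
            ("Slightly", 6, 10.0)],
    "Vrr": [("Desert, swamp, others", 1, 2.0),
            ("Grassland, grass, meadow, cultivated vegetation", 2, 6.0),
            ("Shrub", 3, 8.0), ("Woodland", 4, 10.0)],
    "A": [("Sunny slope", 1, 2.5), ("Half sunny slope", 2, 5.0),
          ("Half shady slope", 3, 7.5), ("Shady slope", 4, 10.0)],
}

# published five-class grading schemes: interior breaks + labels low->high
PRINTED_SCHEMES = {
    "cqi": ([2.89, 3.82, 4.85, 6.21], ["LeCQ", "LCQ", "GCQ", "HCQ", "HeCQ"]),
    "sqi": ([3.88, 5.14, 6.36, 7.41], ["LeSQ", "LSQ", "GSQ", "HSQ", "HeSQ"]),
    "vqi": ([3.53, 5.02, 6.55, 7.80], ["LeVQ", "LVQ", "GVQ", "HVQ", "HeVQ"]),
    "eai_risk": ([2.66, 3.66, 4.86, 6.18],
                 ["HeERA", "HERA", "LERA", "LeERA", "PERA"]),
}


def probes(lo, hi, eps=1e-6):
    """Probe values safely inside a bin: near both edges and the middle."""
    pts = []
    if lo is not None:
        pts.append(lo + eps)
    if hi is not None:
        pts.append(hi - eps)
    if lo is not None and hi is not None:
        pts.append((lo + hi) / 2.0)
    elif lo is None and hi is not None:
        pts.append(hi - 1.0)
    elif hi is None and lo is not None:
        pts.append(lo + 1.0)
    return pts
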
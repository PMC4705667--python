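"""Idealized planar nucleobase and Watson-Crick pair geometry (generated).

All coordinates are 2-D positions (x, y) in Angstrom inside the base plane;
bases are exactly planar by construction.  Internal base geometry follows the
ideal coordinates of the chemical component dictionary projected into the
least-squares ring plane.  Pairs were assembled against consensus heavy-atom
hydrogen-bond distances under a pseudo-dyad (equal glycosidic angle)
constraint; the pair frame has its origin at the C1'-C1' midpoint, +y toward
the purine C1' and +x toward the bases.

Generated by tools/generate_base_geometry.py -- do not edit by hand.
"""

# fmt: off
PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: isolated planar bases, each in its own arbitrary in-plane frame
BASE_COORDS = {
    "DA": {
        "N1": (-2.0819, +0.6430),
        "C2": (-2.0397, -0.6756),
        "N3": (-0.9080, -1.3471),
        "C4": (+0.2584, -0.7093),
        "C5": (+0.2669, +0.6960),
        "C6": (-0.9672, +1.3669),
        "N7": (+1.5642, +1.0858),
        "C8": (+2.3327, +0.0358),
        "N9": (+1.5745, -1.0955),
        "N6": (-1.0212, +2.7498),
        "C1'": (+2.0733, -2.4735),
    },
    "DC": {
        "N1": (-0.6527, +1.1781),
        "C2": (+0.6913, +1.1448),
        "N3": (+1.3504, -0.0128),
        "C4": (+0.6952, -1.1654),
        "C5": (-0.7145, -1.1644),
        "C6": (-1.3698, +0.0197),
        "O2": (+1.3176, +2.1919),
        "N4": (+1.3861, -2.3551),
        "C1'": (-1.3494, +2.4664),
    },
    "DG": {
        "N1": (-2.0990, +0.6620),
        "C2": (-2.0501, -0.6992),
        "N3": (-0.9100, -1.3527),
        "C4": (+0.2603, -0.7045),
        "C5": (+0.2754, +0.6954),
        "C6": (-0.9589, +1.3863),
        "N7": (+1.5742, +1.0829),
        "C8": (+2.3378, +0.0288),
        "N9": (+1.5704, -1.0988),
        "O6": (-0.9922, +2.6047),
        "N2": (-3.2244, -1.4083),
        "C1'": (+2.0598, -2.4785),
    },
    "DT": {
        "N1": (-0.9925, -0.9763),
        "C2": (-1.3916, +0.3774),
        "N3": (-0.3437, +1.3038),
        "C4": (+1.0150, +1.0264),
        "C5": (+1.3571, -0.4209),
        "C6": (+0.3557, -1.3105),
        "O2": (-2.5677, +0.7458),
        "O4": (+1.8854, +1.8925),
        "C7": (+2.8026, -0.8022),
        "C1'": (-1.9583, -2.0364),
    },
}

#: Watson-Crick pairs (purine, pyrimidine) in the pair frame
PAIR_COORDS = {
    ("DA", "DT"): (
        {
            "N1": (+1.6608, +0.4414),
            "C2": (+0.4215, +0.8938),
            "N3": (+0.1376, +2.1787),
            "C4": (+1.1081, +3.0872),
            "C5": (+2.4456, +2.6558),
            "C6": (+2.6969, +1.2738),
            "N7": (+3.2216, +3.7661),
            "C8": (+2.4646, +4.8244),
            "N9": (+1.1529, +4.4581),
            "N6": (+3.9936, +0.7900),
            "C1'": (+0.0000, +5.3628),
        },
        {
            "N1": (+1.1282, -4.4775),
            "C2": (+0.9591, -3.0763),
            "N3": (+2.1461, -2.3365),
            "C4": (+3.4400, -2.8354),
            "C5": (+3.5374, -4.3194),
            "C6": (+2.4023, -5.0307),
            "O2": (-0.1396, -2.5180),
            "O4": (+4.4419, -2.1257),
            "C7": (+4.8997, -4.9352),
            "C1'": (+0.0000, -5.3628),
        },
    ),
    ("DG", "DC"): (
        {
            "N1": (+1.6851, +0.5080),
            "C2": (+0.4073, +0.9794),
            "N3": (+0.1424, +2.2665),
            "C4": (+1.1236, +3.1759),
            "C5": (+2.4582, +2.7532),
            "C6": (+2.7292, +1.3649),
            "N7": (+3.2318, +3.8661),
            "C8": (+2.4688, +4.9207),
            "N9": (+1.1580, +4.5437),
            "O6": (+3.8763, +0.9529),
            "N2": (-0.6330, +0.0851),
            "C1'": (-0.0000, +5.4393),
        },
        {
            "N1": (+1.1571, -4.5414),
            "C2": (+0.9702, -3.2100),
            "N3": (+2.0045, -2.3706),
            "C4": (+3.2487, -2.8285),
            "C5": (+3.4781, -4.2194),
            "C6": (+2.4171, -5.0595),
            "O2": (-0.1652, -2.7633),
            "N4": (+4.3095, -1.9525),
            "C1'": (+0.0000, -5.4393),
        },
    ),
}
# fmt: on
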
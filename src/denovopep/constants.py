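"""Physical constants and the monoisotopic residue-mass table.

All masses are monoisotopic and in daltons. Every other module takes its
chemistry from here; nothing else defines a mass.
"""

#: Mass of a proton (charge carrier), Da.
PROTON = 1.00728

#: Mass of a water molecule (H2O), Da. A neutral peptide weighs the sum of
#: its residue masses plus one water.
WATER = 18.01056

#: Monoisotopic masses of the 20 standard amino-acid residues, Da.
#: I and L are isobaric (both 113.08406); K and Q differ by only 0.03638 Da.
STANDARD_RESIDUES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}
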
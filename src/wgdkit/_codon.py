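"""Standard genetic code tables shared by the simulator and the Ks estimator.

Site classification follows Nei–Gojobori counting: the synonymous fraction
of a codon position is the share of its three possible nucleotide changes
that preserve the encoded amino acid.  Changes that create a stop codon are
counted as nonsynonymous so that the synonymous and nonsynonymous site
counts of a codon always sum to 3.
"""

from __future__ import annotations

from itertools import product

NUCLEOTIDES = "ACGT"

# Standard (NCBI table 1) genetic code, '*' marks stops.
GENETIC_CODE: dict[str, str] = {}
_BASES_BY_AA = {
    "F": ["TTT", "TTC"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"],
    "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"],
    "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "*": ["TAA", "TAG", "TGA"],
}
for _aa, _codons in _BASES_BY_AA.items():
    for _c in _codons:
        GENETIC_CODE[_c] = _aa

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3))
    if GENETIC_CODE[c] != "*"
)
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


def translate(cds: str) -> str:
    """Translate an in-frame CDS; stops become '*'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def _syn_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of the 3 possible changes that are synonymous."""
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        syn = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:  # stop mutants classify nonsyn
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


# Precomputed synonymous-site fractions for the 61 sense codons.
SYN_FRACTION: dict[str, tuple[float, float, float]] = {
    c: _syn_fractions(c) for c in SENSE_CODONS
}

# Per-codon total synonymous sites (sum over the three positions).
SYN_SITES: dict[str, float] = {c: sum(f) for c, f in SYN_FRACTION.items()}


def codon_sites(cds: str) -> tuple[float, float]:
    """Total (synonymous, nonsynonymous) site counts of an in-frame CDS."""
    s = sum(SYN_SITES[cds[i : i + 3]] for i in range(0, len(cds), 3))
    return s, len(cds) - s


def is_synonymous_change(codon: str, pos: int, alt: str) -> bool:
    mutant = codon[:pos] + alt + codon[pos + 1 :]
    return GENETIC_CODE[mutant] == GENETIC_CODE[codon]
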
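"""Shared fixtures: the published worked-example peptide and helpers."""

import numpy as np
import pytest

# 117-aa peptide encoded by ORF-1 (positions 19-372) of the 1646-nt human
# lncRNA HSALNT0229539, used as a worked example throughout the suite.
EXAMPLE_PEPTIDE = (
    "MKQAVRAARQAADFTLKVEVECSSLQEAVQAAEAGADLVLLDNFKPEELHPTATVLKAQF"
    "PSVAVEASGGITLDNLPQFCGPHIDVISMGMLTQAAPALDFSLKLFAKEVAPVPKIH"
)

# one fixed sense codon per amino acid, for deterministic reverse translation
REVERSE_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def reverse_translate(peptide: str, stop: str = "TAA") -> str:
    """Deterministic coding sequence for a peptide, terminal stop appended."""
    return "".join(REVERSE_CODON[aa] for aa in peptide) + stop


def random_transcript_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def example_orf_transcript():
    """Transcript carrying the worked-example ORF at positions 19-372."""
    from lncorf import Transcript

    seq = "A" * 18 + reverse_translate(EXAMPLE_PEPTIDE) + "C" * 40
    return Transcript(id="HSALNT0229539", sequence=seq, species="human")
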